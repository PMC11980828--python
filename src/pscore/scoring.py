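"""P-score pose ranking: min--max normalized residence time and affinity.

Each binding mode (or screened ligand) i carries a residence time t_i and a
mean interaction energy ΔE_i. With extremes min(ΔE), max(ΔE) taken over the
compared set and T the total simulation time, the composite score is

    P = (1 + max ΔE − ΔE_i) / (1 + max ΔE − min ΔE) × t_i / T

which lies in [0, 1], reaches 1 exactly when t_i = T and ΔE_i = min ΔE, is
strictly monotone in both descriptors, and is invariant to a uniform shift
of all energies and to a common rescaling of all times. The +1 offsets keep
the affinity factor strictly positive at ΔE_i = max ΔE.

Poses are additionally placed in a quadrant diagram: normalized time on x,
normalized affinity on y, split by the set means of the two axes. The
top-right quadrant (long-lived AND strongly bound relative to the set) holds
the prioritized poses; a ligand with no pose there gets the explicit verdict
"NA" rather than a forced pick.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import ComparisonEntry, ComparisonSet, ValidationError

__all__ = [
    "ScoringParams",
    "affinity_factor",
    "p_score",
    "score_comparison_set",
    "quadrant_classify",
    "select_top_pose",
    "NA",
]

#: Verdict value when no pose of a ligand is prioritized.
NA = "NA"

QUADRANTS = ("top_right", "top_left", "bottom_right", "bottom_left")


@dataclass
class ScoringParams:
    """Parameters of a scoring run.

    total_time_T_ns: total simulation time T; must bound every t_i.
    extremes_scope: "campaign" takes min/max ΔE over all entries of the run
        (the default, required for cross-ligand comparability);
        "per_ligand" restricts extremes to each ligand's own poses;
        "fixed" uses externally supplied e_min_kcal/e_max_kcal (e.g. the
        extremes of a wider campaign the entries belong to).
    mean_line_tol: half-width (normalized units) of the border band around
        the quadrant mean lines; entries inside it are flagged border_line.
    """

    total_time_T_ns: float
    extremes_scope: str = "campaign"
    mean_line_tol: float = 0.02
    e_min_kcal: float | None = None
    e_max_kcal: float | None = None

    def __post_init__(self) -> None:
        if self.total_time_T_ns <= 0:
            raise ValidationError("total_time_T_ns must be positive")
        if self.extremes_scope not in ("campaign", "per_ligand", "fixed"):
            raise ValidationError(f"unknown extremes_scope {self.extremes_scope!r}")
        if self.extremes_scope == "fixed" and (
            self.e_min_kcal is None or self.e_max_kcal is None
        ):
            raise ValidationError("fixed extremes_scope needs e_min_kcal and e_max_kcal")
        if self.mean_line_tol < 0:
            raise ValidationError("mean_line_tol must be non-negative")


def affinity_factor(delta_e: float, e_min: float, e_max: float) -> float:
    """Normalized affinity weight in (0, 1]; 1 at the set's lowest energy.

    Degenerate sets (e_min == e_max) score 1 by convention.
    """
    if e_min > e_max:
        raise ValidationError(f"e_min {e_min} > e_max {e_max}")
    if not (e_min <= delta_e <= e_max):
        raise ValidationError(
            f"delta_e {delta_e} outside extremes [{e_min}, {e_max}]"
        )
    return (1.0 + e_max - delta_e) / (1.0 + e_max - e_min)


def p_score(
    t_i_ns: float, T_ns: float, delta_e: float, e_min: float, e_max: float
) -> float:
    """Composite pose priority in [0, 1] (see module docstring for the form)."""
    if T_ns <= 0:
        raise ValidationError("T_ns must be positive")
    if not (0.0 <= t_i_ns <= T_ns):
        raise ValidationError(f"t_i {t_i_ns} outside [0, T={T_ns}]")
    return affinity_factor(delta_e, e_min, e_max) * (t_i_ns / T_ns)


def _minmax_norm(values: np.ndarray) -> np.ndarray:
    """Rescale to [0,1]; a degenerate (constant) axis maps to all-ones."""
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:
        return np.ones_like(values)
    return (values - lo) / (hi - lo)


def score_comparison_set(
    entries: list[ComparisonEntry] | list[tuple],
    params: ScoringParams,
) -> ComparisonSet:
    """Score and classify every (ligand, cluster) entry of a comparison.

    Computes P-scores with extremes per ``params.extremes_scope``, min--max
    normalizes both descriptor axes over the whole set (normalized affinity
    is 1 at the LOWEST energy), stores the two axis means and assigns each
    entry a quadrant and a confidence flag. An empty entry list returns an
    empty set (the "nothing survived filtration" signal).
    """
    norm_entries = [
        e if isinstance(e, ComparisonEntry) else ComparisonEntry(*e) for e in entries
    ]
    cs = ComparisonSet(entries=norm_entries, total_time_T_ns=params.total_time_T_ns)
    if not norm_entries:
        return cs
    t = np.array([e.t_i_ns for e in norm_entries])
    de = np.array([e.delta_e_kcal for e in norm_entries])
    if t.max() > params.total_time_T_ns:
        raise ValidationError(
            f"max residence time {t.max()} exceeds T={params.total_time_T_ns}"
        )
    if params.extremes_scope == "fixed":
        cs.e_min_kcal = float(params.e_min_kcal)  # type: ignore[arg-type]
        cs.e_max_kcal = float(params.e_max_kcal)  # type: ignore[arg-type]
    else:
        cs.e_min_kcal, cs.e_max_kcal = float(de.min()), float(de.max())
    if params.extremes_scope in ("campaign", "fixed"):
        extremes = {e.ligand_id: (cs.e_min_kcal, cs.e_max_kcal) for e in norm_entries}
    else:
        extremes = {}
        for lig in cs.ligands():
            sub = np.array([e.delta_e_kcal for e in cs.entries_for(lig)])
            extremes[lig] = (float(sub.min()), float(sub.max()))
    for e in norm_entries:
        lo, hi = extremes[e.ligand_id]
        e.p_score = p_score(e.t_i_ns, params.total_time_T_ns, e.delta_e_kcal, lo, hi)
    norm_t = _minmax_norm(t)
    e_span = cs.e_max_kcal - cs.e_min_kcal
    if e_span == 0:
        norm_a = np.ones_like(de)
    else:
        norm_a = (cs.e_max_kcal - de) / e_span
    cs.mean_norm_time = float(norm_t.mean())
    cs.mean_norm_affinity = float(norm_a.mean())
    for e, nt, na_ in zip(norm_entries, norm_t, norm_a):
        e.norm_time = float(nt)
        e.norm_affinity = float(na_)
        if len(norm_entries) == 1:
            # nothing to compare against: the lone pose is trivially the
            # best of its set and the border band is meaningless
            e.quadrant, e.confidence = "top_right", "high"
        else:
            e.quadrant, e.confidence = quadrant_classify(
                e, (cs.mean_norm_time, cs.mean_norm_affinity), params.mean_line_tol
            )
    return cs


def quadrant_classify(
    entry: ComparisonEntry,
    set_means: tuple[float, float],
    tol: float = 0.02,
) -> tuple[str, str]:
    """Place an entry in the quadrant diagram relative to the set means.

    Right/top when the coordinate is >= its mean (ties count as the
    favourable side); confidence is "border_line" when either coordinate
    lies within ``tol`` of its mean line — the signal that more sampling is
    recommended before trusting the call.
    """
    mean_t, mean_a = set_means
    horiz = "right" if entry.norm_time >= mean_t else "left"
    vert = "top" if entry.norm_affinity >= mean_a else "bottom"
    border = (
        abs(entry.norm_time - mean_t) <= tol
        or abs(entry.norm_affinity - mean_a) <= tol
    )
    return f"{vert}_{horiz}", ("border_line" if border else "high")


def select_top_pose(
    comparison: ComparisonSet, ligand_id: str
) -> tuple[str, str]:
    """Pick the prioritized pose of one ligand, or NA.

    Only top-right-quadrant entries qualify; the winner has the highest
    P-score (ties: longer residence time, then lower energy, then
    lexicographically smaller cluster id). Returns ``(cluster_id | "NA",
    confidence)`` where the confidence is the winner's border flag, or
    "high" for an unambiguous NA.
    """
    mine = comparison.entries_for(ligand_id)
    if not mine:
        raise KeyError(f"ligand {ligand_id!r} not present in comparison set")
    candidates = [e for e in mine if e.quadrant == "top_right"]
    if not candidates:
        return NA, "high"
    best = min(
        candidates,
        key=lambda e: (-e.p_score, -e.t_i_ns, e.delta_e_kcal, e.cluster_id),
    )
    return best.cluster_id, best.confidence
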