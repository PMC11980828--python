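"""Validation utilities: RMSD to crystal references, descriptor correlation,
and experimental P-scores from measured potencies.

RMSD against a reference is computed on heavy atoms with both structures in
the protein frame and WITHOUT superposition, so a pose that drifted within
the site scores its true displacement. The experimental free energy is
ΔG_exp = R·T·ln(IC50) with IC50 in molar; feeding those ΔG values through
the P-score formula with t_i/T fixed at 1 yields the "experimental P-score"
against which predicted scores can be regressed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    GAS_CONSTANT_KCAL,
    STANDARD_TEMPERATURE_K,
    CorrelationResult,
    ExperimentalAffinity,
    ValidationError,
)
from .scoring import NA, affinity_factor

__all__ = [
    "ReferencePose",
    "rmsd_to_reference",
    "success_call",
    "residence_energy_correlation",
    "delta_g_exp",
    "experimental_pscore",
    "predicted_vs_experimental",
    "read_ic50_table",
]

#: Pose-prediction success threshold (Å): below it a pose reproduces the
#: crystallographic binding mode.
RMSD_SUCCESS_THRESHOLD_A = 2.0


@dataclass
class ReferencePose:
    """Crystallographic (or otherwise trusted) ligand pose in the protein frame."""

    ligand_id: str
    atom_names: list[str]
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if len(self.atom_names) != self.coords.shape[0]:
            raise ValidationError("atom_names length must match coords")
        if len(set(self.atom_names)) != len(self.atom_names):
            raise ValidationError("reference atom names must be unique")
        if self.coords.shape[0] < 3:
            raise ValidationError("reference pose needs at least 3 atoms")


def _resolve_mapping(
    pose_atom_names: Sequence[str],
    ref: ReferencePose,
    mapping: Union[str, list[tuple[str, str]]],
) -> tuple[np.ndarray, np.ndarray]:
    """Indices (pose, ref) of matched atom pairs under the chosen mapping."""
    if mapping == "by_order":
        n = min(len(pose_atom_names), len(ref.atom_names))
        if len(pose_atom_names) != len(ref.atom_names):
            raise ValidationError(
                f"by_order mapping needs equal atom counts "
                f"({len(pose_atom_names)} vs {len(ref.atom_names)})"
            )
        return np.arange(n), np.arange(n)
    if mapping == "by_name":
        pose_pos = {n: i for i, n in enumerate(pose_atom_names)}
        unmatched = [n for n in ref.atom_names if n not in pose_pos]
        if unmatched:
            raise ValidationError(f"unmatched reference atoms: {unmatched}")
        p = np.array([pose_pos[n] for n in ref.atom_names], dtype=int)
        return p, np.arange(len(ref.atom_names))
    # explicit pair list: [(pose_name, ref_name), ...] — partial-scaffold mode
    pose_pos = {n: i for i, n in enumerate(pose_atom_names)}
    ref_pos = {n: i for i, n in enumerate(ref.atom_names)}
    bad = [pair for pair in mapping if pair[0] not in pose_pos or pair[1] not in ref_pos]
    if bad:
        raise ValidationError(f"unresolvable atom pairs: {bad}")
    p = np.array([pose_pos[a] for a, _ in mapping], dtype=int)
    r = np.array([ref_pos[b] for _, b in mapping], dtype=int)
    return p, r


def rmsd_to_reference(
    pose_coords: np.ndarray,
    pose_atom_names: Sequence[str],
    ref: ReferencePose,
    mapping: Union[str, list[tuple[str, str]]] = "by_name",
) -> float:
    """Heavy-atom RMSD (Å) of a pose against a reference, no superposition.

    ``mapping`` is "by_name", "by_order", or an explicit list of
    (pose_atom, ref_atom) pairs for partial-scaffold comparisons.
    """
    pose_coords = np.asarray(pose_coords, dtype=float).reshape(-1, 3)
    p, r = _resolve_mapping(pose_atom_names, ref, mapping)
    diff = pose_coords[p] - ref.coords[r]
    return float(np.sqrt((diff**2).sum(axis=1).mean()))


def success_call(rmsd_A: float, threshold_A: float = RMSD_SUCCESS_THRESHOLD_A) -> str:
    """"success" when rmsd < threshold (strict), else "failure"."""
    if rmsd_A < 0:
        raise ValidationError("rmsd must be non-negative")
    return "success" if rmsd_A < threshold_A else "failure"


def residence_energy_correlation(
    pairs: Sequence[tuple[float, float]],
    ligand_id: str = "",
) -> Optional[CorrelationResult]:
    """Pearson r between residence time and interaction energy of one ligand.

    A well-sampled ligand shows negative r (longer-lived modes bind more
    strongly). Returns None when the correlation is undefined (fewer than 3
    cluster pairs or zero variance on either axis) — the "correlation not
    found" signal, reported as such rather than as an error.
    """
    t = np.array([p[0] for p in pairs], dtype=float)
    de = np.array([p[1] for p in pairs], dtype=float)
    if len(pairs) < 3 or t.std() == 0 or de.std() == 0:
        return None
    res = stats.pearsonr(t, de)
    return CorrelationResult(
        ligand_id=ligand_id,
        r=float(res.statistic),
        p_value=float(res.pvalue),
        n=len(pairs),
    )


def delta_g_exp(
    ic50_molar: float,
    temperature_K: float = STANDARD_TEMPERATURE_K,
    gas_constant_kcal: float = GAS_CONSTANT_KCAL,
) -> float:
    """Experimental binding free energy R·T·ln(IC50) in kcal/mol."""
    if ic50_molar <= 0:
        raise ValidationError("IC50 must be positive")
    return gas_constant_kcal * temperature_K * math.log(ic50_molar)


def experimental_pscore(
    affinities: Sequence[ExperimentalAffinity],
) -> dict[str, float]:
    """P-score of each ligand from experiment alone (t_i/T := 1).

    The affinity extremes are taken over the supplied ligand set, so the
    most potent ligand scores exactly 1.0.
    """
    if not affinities:
        raise ValidationError("no affinities supplied")
    dg = np.array([a.delta_g_exp_kcal for a in affinities])
    lo, hi = float(dg.min()), float(dg.max())
    return {
        a.ligand_id: affinity_factor(a.delta_g_exp_kcal, lo, hi) for a in affinities
    }


def predicted_vs_experimental(
    table: Sequence[tuple[str, Union[float, str, None], float]],
) -> tuple[pd.DataFrame, Optional[float]]:
    """Pair predicted with experimental P-scores and fit their relation.

    ``table`` rows are (ligand_id, predicted score | NA | None, experimental
    score). Returns the paired DataFrame (NA predictions retained, excluded
    from the fit) and the ordinary-least-squares R², or None with fewer
    than 2 usable pairs.
    """
    rows = []
    for lig, pred, exp in table:
        is_na = pred is None or (isinstance(pred, str) and pred == NA)
        rows.append(
            {
                "ligand_id": lig,
                "predicted": float("nan") if is_na else float(pred),
                "experimental": float(exp),
            }
        )
    df = pd.DataFrame(rows, columns=["ligand_id", "predicted", "experimental"])
    usable = df.dropna(subset=["predicted"])
    if len(usable) < 2 or usable["predicted"].std() == 0:
        return df, None
    fit = stats.linregress(usable["predicted"], usable["experimental"])
    return df, float(fit.rvalue**2)


def read_ic50_table(
    path,
    temperature_K: float = STANDARD_TEMPERATURE_K,
) -> list[ExperimentalAffinity]:
    """Read an IC50 CSV (ligand_id, ic50[, unit]) into affinities.

    Values are converted to molar from an optional unit column supporting
    M, mM, uM/µM/μM and nM; without a unit column values must be molar.
    """
    df = pd.read_csv(path)
    for col in ("ligand_id", "ic50"):
        if col not in df.columns:
            raise ValidationError(f"{path}: IC50 table missing column {col!r}")
    scale = {"m": 1.0, "mm": 1e-3, "um": 1e-6, "µm": 1e-6, "μm": 1e-6, "nm": 1e-9}
    out = []
    for row in df.itertuples():
        factor = 1.0
        if "unit" in df.columns:
            unit = str(row.unit).strip().lower()
            if unit not in scale:
                raise ValidationError(f"unknown IC50 unit {row.unit!r}")
            factor = scale[unit]
        out.append(
            ExperimentalAffinity(
                ligand_id=str(row.ligand_id),
                ic50_molar=float(row.ic50) * factor,
                temperature_K=temperature_K,
            )
        )
    return out
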