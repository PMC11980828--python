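"""Core domain types for the pose-prioritization pipeline.

All coordinates are in Å and expressed in the protein (binding-site) frame;
energies are in kcal/mol; times are in ns except raw frame spacing, which is
given in ps. Hydrogens are excluded everywhere: trajectories, references and
RMSD calculations operate on heavy atoms only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "DEFAULT_FRAME_DT_PS",
    "DEFAULT_SITE_CUTOFF_A",
    "GAS_CONSTANT_KCAL",
    "STANDARD_TEMPERATURE_K",
    "ValidationError",
    "PoseTrajectory",
    "concatenate_replicates",
    "SiteDefinition",
    "PiedaComponents",
    "EnergySeries",
    "ClusterRecord",
    "ComparisonEntry",
    "ComparisonSet",
    "ExperimentalAffinity",
    "CorrelationResult",
]

#: Simulation time represented by one trajectory frame (ps).
DEFAULT_FRAME_DT_PS = 20.0
#: Ligand--site distance beyond which a frame is considered unbound (Å).
DEFAULT_SITE_CUTOFF_A = 9.0
#: Gas constant in kcal·mol⁻¹·K⁻¹.
GAS_CONSTANT_KCAL = 1.9872e-3
#: Default absolute temperature (K) for experimental free energies.
STANDARD_TEMPERATURE_K = 298.15


class ValidationError(ValueError):
    """Raised when input data violates a documented invariant."""


@dataclass
class PoseTrajectory:
    """Ligand heavy-atom poses over time, already in the protein frame.

    Frames from several independent replicates may be concatenated
    (replicate-major order); each frame keeps its ``(replicate_id,
    frame_index)`` identity so filtering never renumbers frames.

    Attributes
    ----------
    coords : ndarray, shape (n_frames, n_atoms, 3)
        Heavy-atom coordinates in Å.
    atom_names : list of str
        Atom identifiers, one per atom, order matching ``coords``.
    frame_indices : ndarray of int
        Original frame index of each frame, strictly increasing within a
        replicate.
    times_ps : ndarray of float
        Simulation timestamp of each frame (ps); derived as
        ``frame_index * frame_dt_ps`` when the input carries no timestamps.
    replicate_ids : ndarray of int
        Replicate of origin for each frame.
    frame_dt_ps : float
        Simulation time per frame in ps (default 20).
    """

    coords: np.ndarray
    atom_names: list[str]
    frame_indices: np.ndarray
    times_ps: np.ndarray
    replicate_ids: np.ndarray
    frame_dt_ps: float = DEFAULT_FRAME_DT_PS

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValidationError(
                f"coords must have shape (n_frames, n_atoms, 3), got {self.coords.shape}"
            )
        n = self.coords.shape[0]
        self.frame_indices = np.asarray(self.frame_indices, dtype=int)
        self.replicate_ids = np.asarray(self.replicate_ids, dtype=int)
        self.times_ps = np.asarray(self.times_ps, dtype=float)
        for name, arr in (
            ("frame_indices", self.frame_indices),
            ("times_ps", self.times_ps),
            ("replicate_ids", self.replicate_ids),
        ):
            if arr.shape != (n,):
                raise ValidationError(f"{name} must have length {n}, got {arr.shape}")
        if len(self.atom_names) != self.coords.shape[1]:
            raise ValidationError(
                f"atom_names length {len(self.atom_names)} does not match "
                f"atom count {self.coords.shape[1]}"
            )
        if self.frame_dt_ps <= 0:
            raise ValidationError("frame_dt_ps must be positive")
        for rep in np.unique(self.replicate_ids):
            idx = self.frame_indices[self.replicate_ids == rep]
            if np.any(np.diff(idx) <= 0):
                raise ValidationError(
                    f"frame_index not strictly increasing within replicate {rep}"
                )
        if len(np.unique(self.frame_indices)) != len(self.frame_indices):
            raise ValidationError(
                "frame_index values must be globally unique; offset replicates "
                "before concatenation (see concatenate_replicates)"
            )

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def centroids(self) -> np.ndarray:
        """Per-frame heavy-atom centroid, shape (n_frames, 3)."""
        return self.coords.mean(axis=1)

    def select(self, mask: np.ndarray) -> "PoseTrajectory":
        """Subset of frames by boolean mask or index array; identities kept."""
        return PoseTrajectory(
            coords=self.coords[mask],
            atom_names=list(self.atom_names),
            frame_indices=self.frame_indices[mask],
            times_ps=self.times_ps[mask],
            replicate_ids=self.replicate_ids[mask],
            frame_dt_ps=self.frame_dt_ps,
        )

    @classmethod
    def from_coords(
        cls,
        coords: np.ndarray,
        atom_names: Optional[Sequence[str]] = None,
        frame_dt_ps: float = DEFAULT_FRAME_DT_PS,
        replicate_id: int = 0,
        frame_indices: Optional[np.ndarray] = None,
        times_ps: Optional[np.ndarray] = None,
    ) -> "PoseTrajectory":
        """Build a single-replicate trajectory from a coordinate array."""
        coords = np.asarray(coords, dtype=float)
        n = coords.shape[0]
        if atom_names is None:
            atom_names = [f"C{i + 1}" for i in range(coords.shape[1])]
        if frame_indices is None:
            frame_indices = np.arange(n)
        frame_indices = np.asarray(frame_indices, dtype=int)
        if times_ps is None:
            times_ps = frame_indices * float(frame_dt_ps)
        return cls(
            coords=coords,
            atom_names=list(atom_names),
            frame_indices=frame_indices,
            times_ps=np.asarray(times_ps, dtype=float),
            replicate_ids=np.full(n, replicate_id, dtype=int),
            frame_dt_ps=frame_dt_ps,
        )


def concatenate_replicates(trajs: Sequence[PoseTrajectory]) -> PoseTrajectory:
    """Concatenate per-replicate trajectories in replicate-major order.

    Each input is assigned its positional replicate id. Frame ids are
    offset per replicate so they stay globally unique (the numbering that
    energy tables for the concatenated run must use); per-replicate
    timestamps are kept as-is so time intervals are never measured across
    the concatenation seam. Atom naming must agree across replicates.
    """
    if not trajs:
        raise ValidationError("no trajectories to concatenate")
    names = trajs[0].atom_names
    dt = trajs[0].frame_dt_ps
    for k, t in enumerate(trajs[1:], start=1):
        if t.atom_names != names:
            raise ValidationError(f"replicate {k} atom names differ from replicate 0")
    indices = []
    offset = 0
    for t in trajs:
        indices.append(t.frame_indices - t.frame_indices.min() + offset)
        offset = int(indices[-1].max()) + 1
    return PoseTrajectory(
        coords=np.concatenate([t.coords for t in trajs], axis=0),
        atom_names=list(names),
        frame_indices=np.concatenate(indices),
        times_ps=np.concatenate([t.times_ps for t in trajs]),
        replicate_ids=np.concatenate(
            [np.full(t.n_frames, k, dtype=int) for k, t in enumerate(trajs)]
        ),
        frame_dt_ps=dt,
    )


@dataclass
class SiteDefinition:
    """Binding-site reference: explicit site atoms or a single site center.

    Exactly one of ``site_coords`` / ``site_center`` is required; when site
    atoms are given the center is their centroid. ``cutoff_A`` is the
    ligand--site distance beyond which frames are discarded as unbound.
    """

    site_coords: Optional[np.ndarray] = None
    site_center: Optional[np.ndarray] = None
    cutoff_A: float = DEFAULT_SITE_CUTOFF_A

    def __post_init__(self) -> None:
        if self.cutoff_A <= 0:
            raise ValidationError("cutoff_A must be positive")
        if self.site_coords is None and self.site_center is None:
            raise ValidationError("one of site_coords / site_center must be set")
        if self.site_coords is not None:
            self.site_coords = np.asarray(self.site_coords, dtype=float).reshape(-1, 3)
            if self.site_center is None:
                self.site_center = self.site_coords.mean(axis=0)
        self.site_center = np.asarray(self.site_center, dtype=float).reshape(3)

    @property
    def center(self) -> np.ndarray:
        return self.site_center


@dataclass(frozen=True)
class PiedaComponents:
    """PIEDA decomposition of one snapshot's interaction energy (kcal/mol).

    es: electrostatic; ex: exchange repulsion; ct_mix: charge transfer plus
    higher-order mixed terms; di: dispersion; g_sol: solvation free energy.
    """

    es: float
    ex: float
    ct_mix: float
    di: float
    g_sol: float

    def __post_init__(self) -> None:
        for f in ("es", "ex", "ct_mix", "di", "g_sol"):
            if not math.isfinite(getattr(self, f)):
                raise ValidationError(f"PIEDA component {f!r} is not finite")

    def total(self) -> float:
        """Total interaction energy as the sum of the five components."""
        return self.es + self.ex + self.ct_mix + self.di + self.g_sol


@dataclass
class EnergySeries:
    """Per-snapshot interaction energies keyed by frame index.

    ``source_kind`` records which upstream engine produced the table (fmo,
    mmpbsa, other); the pipeline treats all sources identically.
    """

    frame_indices: np.ndarray
    energies: np.ndarray
    components: Optional[list[PiedaComponents]] = None
    source_kind: str = "other"

    def __post_init__(self) -> None:
        self.frame_indices = np.asarray(self.frame_indices, dtype=int)
        self.energies = np.asarray(self.energies, dtype=float)
        if self.frame_indices.shape != self.energies.shape:
            raise ValidationError("frame_indices and energies must have equal length")
        vals, counts = np.unique(self.frame_indices, return_counts=True)
        if np.any(counts > 1):
            dupes = [int(v) for v in vals[counts > 1]]
            raise ValidationError(f"duplicate frame_index values: {dupes}")
        if self.source_kind not in ("fmo", "mmpbsa", "other"):
            raise ValidationError(f"unknown source_kind {self.source_kind!r}")
        if self.components is not None:
            if len(self.components) != len(self.energies):
                raise ValidationError("components length must match energies")
            for e, c in zip(self.energies, self.components):
                if abs(e - c.total()) > 1e-9:
                    raise ValidationError(
                        "energy_total does not equal PIEDA component sum"
                    )
        self._lookup = {int(i): float(e) for i, e in zip(self.frame_indices, self.energies)}

    def __len__(self) -> int:
        return len(self.frame_indices)

    def energy_for(self, frame_index: int) -> float:
        return self._lookup[int(frame_index)]

    def has_frame(self, frame_index: int) -> bool:
        return int(frame_index) in self._lookup


@dataclass
class ClusterRecord:
    """One binding mode: a DBSCAN cluster of similar ligand poses.

    ``cluster_id`` labels ("C-01", "C-02", ...) are ordered by descending
    residence time, ties broken by the smaller representative frame index.
    ``residence_time_ns`` is member count × frame spacing.
    """

    cluster_id: str
    member_frames: np.ndarray
    residence_time_ns: float
    representative_frame: int
    mean_energy_kcal: Optional[float] = None
    n_energy_snapshots: int = 0

    def __post_init__(self) -> None:
        self.member_frames = np.asarray(self.member_frames, dtype=int)
        if self.member_frames.size == 0:
            raise ValidationError("cluster must have at least one member frame")
        if self.residence_time_ns < 0:
            raise ValidationError("residence_time_ns must be non-negative")

    @property
    def size(self) -> int:
        return int(self.member_frames.size)


@dataclass
class ComparisonEntry:
    """One scored (ligand, binding-mode) pair in a comparison set."""

    ligand_id: str
    cluster_id: str
    t_i_ns: float
    delta_e_kcal: float
    p_score: float = float("nan")
    norm_time: float = float("nan")
    norm_affinity: float = float("nan")
    quadrant: str = ""
    confidence: str = ""


@dataclass
class ComparisonSet:
    """The scored ensemble over which normalization extremes are taken."""

    entries: list[ComparisonEntry]
    total_time_T_ns: float
    e_min_kcal: float = float("nan")
    e_max_kcal: float = float("nan")
    mean_norm_time: float = float("nan")
    mean_norm_affinity: float = float("nan")

    def ligands(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.ligand_id, None)
        return list(seen)

    def entries_for(self, ligand_id: str) -> list[ComparisonEntry]:
        return [e for e in self.entries if e.ligand_id == ligand_id]


@dataclass
class ExperimentalAffinity:
    """Measured potency of a ligand and the derived free energy.

    ΔG_exp = R·T·ln(IC50) with IC50 in molar units; negative for
    sub-molar IC50.
    """

    ligand_id: str
    ic50_molar: float
    temperature_K: float = STANDARD_TEMPERATURE_K
    gas_constant_kcal: float = GAS_CONSTANT_KCAL
    delta_g_exp_kcal: float = field(init=False)

    def __post_init__(self) -> None:
        if self.ic50_molar <= 0:
            raise ValidationError("ic50_molar must be positive")
        if self.temperature_K <= 0:
            raise ValidationError("temperature_K must be positive")
        self.delta_g_exp_kcal = (
            self.gas_constant_kcal * self.temperature_K * math.log(self.ic50_molar)
        )


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation between residence time and interaction energy."""

    ligand_id: str
    r: float
    p_value: float
    n: int
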