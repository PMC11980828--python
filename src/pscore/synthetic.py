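"""Synthetic pose trajectories with planted ground truth.

The generator emulates the statistical structure the clustering pipeline
assumes in real supervised-MD output: a handful of metastable binding modes
(well-separated ligand poses inside the site, each populated with a target
dwell fraction), excursions to an unbound region beyond the proximity
cutoff, and per-snapshot interaction energies drawn around a per-mode mean.
State switching is a sticky first-order Markov chain whose stationary
distribution equals the requested occupancies, so dwell sojourns are
contiguous (geometric) and the snapshot-subsampling interval logic is
exercised. No chemistry or kinetics is simulated: the ligand is a rigid
pseudo-atom template plus isotropic Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import linear_sum_assignment

from .datatypes import (
    DEFAULT_FRAME_DT_PS,
    DEFAULT_SITE_CUTOFF_A,
    ClusterRecord,
    EnergySeries,
    PoseTrajectory,
    SiteDefinition,
    ValidationError,
)

__all__ = [
    "PoseSpec",
    "SyntheticSpec",
    "GroundTruth",
    "RecoveryMetrics",
    "make_ligand_template",
    "generate",
    "evaluate_recovery",
    "two_pose_spec",
]

#: Truth label for frames in the unbound region.
UNBOUND = -1


def make_ligand_template(n_atoms: int = 8, spread_A: float = 2.5) -> np.ndarray:
    """Deterministic rigid pseudo-ligand: n_atoms points on a coarse helix.

    Centered at the origin; ``spread_A`` sets the radius. 5--20 atoms is the
    intended range.
    """
    if not 3 <= n_atoms <= 50:
        raise ValidationError("template needs 3..50 atoms")
    k = np.arange(n_atoms)
    theta = 2.2 * k
    coords = np.stack(
        [
            spread_A * np.cos(theta),
            spread_A * np.sin(theta),
            0.8 * (k - k.mean()),
        ],
        axis=1,
    )
    return coords - coords.mean(axis=0)


@dataclass
class PoseSpec:
    """One planted binding mode."""

    pose_id: str
    center_coords: np.ndarray  # (n_atoms, 3) template in the site frame
    dwell_fraction: float
    energy_mean_kcal: float
    energy_sd_kcal: float = 3.0
    coord_noise_A: float = 0.25

    def __post_init__(self) -> None:
        self.center_coords = np.asarray(self.center_coords, dtype=float).reshape(-1, 3)
        if not 0.0 <= self.dwell_fraction <= 1.0:
            raise ValidationError("dwell_fraction must lie in [0, 1]")
        if self.energy_sd_kcal < 0 or self.coord_noise_A < 0:
            raise ValidationError("sd / noise must be non-negative")


@dataclass
class SyntheticSpec:
    """Full recipe for one synthetic run.

    switch_prob is the per-frame probability of re-drawing the state from
    the stationary occupancy distribution (first-order sticky chain; mean
    sojourn 1/switch_prob frames). unbound_energy_mean_kcal parameterises
    the weak energies of unbound frames (they are filtered out before
    scoring and only matter for table completeness).
    """

    n_frames: int
    poses: list[PoseSpec]
    unbound_fraction: float = 0.0
    frame_dt_ps: float = DEFAULT_FRAME_DT_PS
    switch_prob: float = 0.02
    cutoff_A: float = DEFAULT_SITE_CUTOFF_A
    eps_check_A: float = 1.0
    unbound_energy_mean_kcal: float = -5.0
    unbound_energy_sd_kcal: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValidationError("n_frames must be >= 1")
        if not self.poses:
            raise ValidationError("at least one pose is required")
        total = sum(p.dwell_fraction for p in self.poses) + self.unbound_fraction
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(
                f"dwell fractions + unbound_fraction must sum to 1, got {total}"
            )
        if not 0.0 < self.switch_prob <= 1.0:
            raise ValidationError("switch_prob must lie in (0, 1]")
        n_at = {p.center_coords.shape[0] for p in self.poses}
        if len(n_at) != 1:
            raise ValidationError("all poses must share the ligand template size")


@dataclass
class GroundTruth:
    """Planted per-frame state labels plus the generating spec."""

    spec: SyntheticSpec
    state_labels: np.ndarray  # per frame: pose index 0..K-1, or UNBOUND
    pose_ids: list[str]

    def dwell_fractions(self) -> dict[str, float]:
        return {p.pose_id: p.dwell_fraction for p in self.spec.poses}


def _template_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(((a - b) ** 2).sum(axis=1).mean()))


def _check_feasibility(spec: SyntheticSpec, rng: np.random.Generator) -> None:
    """Empirical generation-time guards.

    (a) within-pose frame pairs must fall below the clustering eps with
    probability > 0.99 (1000 sampled noise pairs per pose); (b) pose
    templates must be separated by more than 2x eps so modes cannot merge.
    """
    n_at = spec.poses[0].center_coords.shape[0]
    for p in spec.poses:
        if p.coord_noise_A == 0:
            continue
        a = rng.normal(0.0, p.coord_noise_A, size=(1000, n_at, 3))
        b = rng.normal(0.0, p.coord_noise_A, size=(1000, n_at, 3))
        rmsd = np.sqrt(((a - b) ** 2).sum(axis=2).mean(axis=1))
        if (rmsd < spec.eps_check_A).mean() <= 0.99:
            raise ValidationError(
                f"pose {p.pose_id}: coord_noise_A={p.coord_noise_A} puts "
                f"within-pose RMSD above eps={spec.eps_check_A} too often"
            )
    for i, a in enumerate(spec.poses):
        for b in spec.poses[i + 1 :]:
            sep = _template_rmsd(a.center_coords, b.center_coords)
            if sep <= 2.0 * spec.eps_check_A:
                raise ValidationError(
                    f"poses {a.pose_id}/{b.pose_id} separated by only "
                    f"{sep:.2f} Å RMSD (need > {2 * spec.eps_check_A} Å)"
                )


def generate(
    spec: SyntheticSpec,
) -> tuple[PoseTrajectory, EnergySeries, SiteDefinition, GroundTruth]:
    """Generate one synthetic run; fully reproducible for a fixed seed."""
    rng = np.random.default_rng(spec.seed)
    _check_feasibility(spec, rng)
    k = len(spec.poses)
    pi = np.array([p.dwell_fraction for p in spec.poses] + [spec.unbound_fraction])
    pi = pi / pi.sum()
    states = np.empty(spec.n_frames, dtype=int)
    states[0] = rng.choice(k + 1, p=pi)
    switches = rng.random(spec.n_frames) < spec.switch_prob
    redraws = rng.choice(k + 1, size=spec.n_frames, p=pi)
    for i in range(1, spec.n_frames):
        states[i] = redraws[i] if switches[i] else states[i - 1]

    n_at = spec.poses[0].center_coords.shape[0]
    coords = np.empty((spec.n_frames, n_at, 3))
    energies = np.empty(spec.n_frames)
    # unbound placement: centroid at 2x cutoff in a per-frame random direction
    for s in range(k + 1):
        mask = states == s
        m = int(mask.sum())
        if m == 0:
            continue
        if s < k:
            p = spec.poses[s]
            coords[mask] = p.center_coords + rng.normal(
                0.0, p.coord_noise_A, size=(m, n_at, 3)
            )
            energies[mask] = rng.normal(p.energy_mean_kcal, p.energy_sd_kcal, size=m)
        else:
            dirs = rng.normal(size=(m, 3))
            dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
            centers = 2.0 * spec.cutoff_A * dirs
            base = spec.poses[0].center_coords - spec.poses[0].center_coords.mean(axis=0)
            coords[mask] = centers[:, None, :] + base + rng.normal(
                0.0, spec.poses[0].coord_noise_A, size=(m, n_at, 3)
            )
            energies[mask] = rng.normal(
                spec.unbound_energy_mean_kcal, spec.unbound_energy_sd_kcal, size=m
            )

    traj = PoseTrajectory.from_coords(
        coords, frame_dt_ps=spec.frame_dt_ps, replicate_id=0
    )
    series = EnergySeries(
        frame_indices=np.arange(spec.n_frames),
        energies=energies,
        source_kind="other",
    )
    site = SiteDefinition(site_center=np.zeros(3), cutoff_A=spec.cutoff_A)
    truth = GroundTruth(
        spec=spec,
        state_labels=np.where(states == k, UNBOUND, states),
        pose_ids=[p.pose_id for p in spec.poses],
    )
    return traj, series, site, truth


@dataclass
class RecoveryMetrics:
    """How well a pipeline run recovered the planted structure."""

    cluster_to_pose: dict[str, str]
    assignment_accuracy: float
    residence_fraction_error: dict[str, float]
    energy_mean_error: dict[str, float]
    n_clusters: int
    top_pose_correct: Optional[bool] = None
    dominant_pose_id: Optional[str] = None


def _dominant_pose(spec: SyntheticSpec) -> Optional[str]:
    """Pose that wins BOTH axes (longest dwell and lowest energy), if any."""
    by_dwell = max(spec.poses, key=lambda p: p.dwell_fraction)
    by_energy = min(spec.poses, key=lambda p: p.energy_mean_kcal)
    return by_dwell.pose_id if by_dwell.pose_id == by_energy.pose_id else None


def evaluate_recovery(
    truth: GroundTruth,
    clusters: list[ClusterRecord],
    top_pose_cluster: Optional[str] = None,
) -> RecoveryMetrics:
    """Compare pipeline clusters against the planted states.

    Clusters are matched to poses by Hungarian assignment maximising frame
    overlap; assignment accuracy is the fraction of planted bound frames
    landing in their matched cluster. Residence-fraction error is
    |cluster size / n_frames − planted dwell|; energy error is the absolute
    deviation of the cluster's attached mean from the planted mean. When
    ``top_pose_cluster`` is given, top-pose correctness checks it maps to
    the planted pose that dominates both axes (None when no pose does).
    """
    spec = truth.spec
    k = len(spec.poses)
    overlap = np.zeros((len(clusters), k))
    for ci, cl in enumerate(clusters):
        st = truth.state_labels[cl.member_frames]
        for s in range(k):
            overlap[ci, s] = int((st == s).sum())
    cluster_to_pose: dict[str, str] = {}
    matched = 0
    if clusters:
        rows, cols = linear_sum_assignment(-overlap)
        for r, c in zip(rows, cols):
            if overlap[r, c] > 0:
                cluster_to_pose[clusters[r].cluster_id] = spec.poses[c].pose_id
                matched += int(overlap[r, c])
    bound_total = int((truth.state_labels != UNBOUND).sum())
    accuracy = matched / bound_total if bound_total else float("nan")

    pose_by_id = {p.pose_id: p for p in spec.poses}
    res_err: dict[str, float] = {}
    e_err: dict[str, float] = {}
    for cl in clusters:
        pid = cluster_to_pose.get(cl.cluster_id)
        if pid is None:
            continue
        p = pose_by_id[pid]
        res_err[pid] = abs(cl.size / spec.n_frames - p.dwell_fraction)
        if cl.mean_energy_kcal is not None:
            e_err[pid] = abs(cl.mean_energy_kcal - p.energy_mean_kcal)

    dominant = _dominant_pose(spec)
    top_ok: Optional[bool] = None
    if top_pose_cluster is not None and dominant is not None:
        top_ok = cluster_to_pose.get(top_pose_cluster) == dominant
    return RecoveryMetrics(
        cluster_to_pose=cluster_to_pose,
        assignment_accuracy=accuracy,
        residence_fraction_error=res_err,
        energy_mean_error=e_err,
        n_clusters=len(clusters),
        top_pose_correct=top_ok,
        dominant_pose_id=dominant,
    )


def two_pose_spec(
    n_frames: int = 30_000,
    seed: int = 0,
    dwell_major: float = 0.6,
    dwell_minor: float = 0.3,
    unbound_fraction: float = 0.1,
    energy_major: float = -120.0,
    energy_minor: float = -100.0,
    n_atoms: int = 8,
) -> SyntheticSpec:
    """The canonical two-mode benchmark: a dominant long-lived, strongly
    bound pose against a minor pose, with unbound excursions."""
    template = make_ligand_template(n_atoms)
    offset = np.array([6.0, 0.0, 0.0])
    return SyntheticSpec(
        n_frames=n_frames,
        poses=[
            PoseSpec("pose-A", template, dwell_major, energy_major),
            PoseSpec("pose-B", template + offset, dwell_minor, energy_minor),
        ],
        unbound_fraction=unbound_fraction,
        seed=seed,
    )
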