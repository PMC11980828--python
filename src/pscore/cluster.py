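"""Proximity filtration, ligand RMSD, density clustering, residence times.

Binding modes are found by DBSCAN over pairwise ligand RMSD computed in the
binding-site frame WITHOUT superposition: a pose is a position+orientation of
the ligand relative to the site, so frames are never re-fitted onto each
other. This makes the RMSD between two frames an exact Euclidean distance on
flattened coordinates scaled by 1/sqrt(n_atoms), which the large-trajectory
path exploits to avoid materialising the full pairwise matrix.

Defaults follow the standard pose-clustering protocol: eps 1.0 Å, at least
100 member conformations per mode, 9 Å ligand--site cutoff, 20 ps per frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .datatypes import (
    ClusterRecord,
    PoseTrajectory,
    SiteDefinition,
    ValidationError,
)

__all__ = [
    "ClusteringParams",
    "NOISE",
    "proximity_filter",
    "pairwise_rmsd",
    "dbscan_cluster",
    "build_clusters",
    "cluster_poses",
    "subsample_snapshots",
]

#: Label assigned to frames not belonging to any binding mode.
NOISE = -1

#: Above this frame count, clustering runs on flattened coordinates instead
#: of a materialised pairwise matrix (identical metric, O(n^2) memory saved).
_MATRIX_PATH_MAX_FRAMES = 4000


@dataclass
class ClusteringParams:
    """DBSCAN parameters for binding-mode detection.

    eps_A: maximum ligand RMSD (Å) between neighbouring poses (default 1.0).
    min_pts: minimum similar conformations per mode, counting the point
        itself (default 100).
    cutoff_A: ligand--site distance (Å) beyond which frames are discarded
        before clustering (default 9.0).
    """

    eps_A: float = 1.0
    min_pts: int = 100
    cutoff_A: float = 9.0

    def __post_init__(self) -> None:
        if self.eps_A <= 0:
            raise ValidationError("eps_A must be positive")
        if self.min_pts < 1:
            raise ValidationError("min_pts must be >= 1")
        if self.cutoff_A <= 0:
            raise ValidationError("cutoff_A must be positive")


def proximity_filter(
    traj: PoseTrajectory,
    site: SiteDefinition,
    mode: str = "centroid",
) -> PoseTrajectory:
    """Drop frames where the ligand sits more than ``cutoff_A`` from the site.

    A frame is retained when its distance is <= cutoff (strictly beyond the
    cutoff means unbound). ``mode="centroid"`` measures ligand-centroid to
    site-center distance; ``mode="min_atom"`` uses the minimum heavy-atom
    distance to any site atom (requires site_coords). Original frame
    identities are preserved; all frames removed yields an empty trajectory,
    which downstream stages must report as "NA" rather than fail on.
    """
    if traj.n_frames == 0:
        raise ValidationError("trajectory is empty")
    if mode == "centroid":
        d = np.linalg.norm(traj.centroids() - site.center, axis=1)
    elif mode == "min_atom":
        if site.site_coords is None:
            raise ValidationError("min_atom mode requires site_coords")
        diff = traj.coords[:, :, None, :] - site.site_coords[None, None, :, :]
        d = np.sqrt((diff**2).sum(axis=-1)).min(axis=(1, 2))
    else:
        raise ValidationError(f"unknown proximity mode {mode!r}")
    return traj.select(d <= site.cutoff_A)


def _flatten_scaled(traj: PoseTrajectory) -> np.ndarray:
    """Coordinates flattened so Euclidean distance equals ligand RMSD."""
    n = traj.n_atoms
    return traj.coords.reshape(traj.n_frames, 3 * n) / np.sqrt(n)


def pairwise_rmsd(traj: PoseTrajectory) -> np.ndarray:
    """Symmetric matrix of unsuperposed heavy-atom RMSD between all frames.

    M[i, j] = sqrt(mean over atoms of squared coordinate difference); the
    diagonal is exactly zero.
    """
    if traj.n_frames < 2:
        raise ValidationError("pairwise RMSD needs at least 2 frames")
    x = _flatten_scaled(traj)
    n = x.shape[0]
    m = np.empty((n, n))
    chunk = max(1, int(4e6 // max(x.shape[1] * n, 1)))
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        diff = x[start:stop, None, :] - x[None, :, :]
        m[start:stop] = np.sqrt((diff**2).sum(axis=2))
    np.fill_diagonal(m, 0.0)
    return m


def dbscan_cluster(dist: np.ndarray, params: ClusteringParams) -> np.ndarray:
    """Density-based clustering of a precomputed distance matrix.

    Classic semantics: a point is a core point iff its eps-neighbourhood
    (including itself, boundary distance == eps inside) holds at least
    ``min_pts`` points; clusters are connected components of core points
    under <=eps reachability; border points join the cluster of their
    lowest-indexed core neighbour; everything else is noise (label -1).
    Cluster labels are 0..k-1 in order of each cluster's smallest core index,
    so the output is deterministic for a fixed input.
    """
    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValidationError(f"distance matrix must be square, got {dist.shape}")
    n = dist.shape[0]
    within = dist <= params.eps_A
    core = within.sum(axis=1) >= params.min_pts
    labels = np.full(n, NOISE, dtype=int)
    if not core.any():
        return labels
    core_idx = np.flatnonzero(core)
    adj = csr_matrix(within[np.ix_(core_idx, core_idx)])
    n_comp, comp = connected_components(adj, directed=False)
    # relabel components by smallest core index for determinism
    order = np.full(n_comp, -1, dtype=int)
    next_label = 0
    for pos, c in enumerate(comp):
        if order[c] == -1:
            order[c] = next_label
            next_label += 1
    labels[core_idx] = order[comp]
    # border points: non-core within eps of a core point -> lowest-indexed core neighbour
    non_core = np.flatnonzero(~core)
    if non_core.size:
        reach = within[np.ix_(non_core, core_idx)]
        has = reach.any(axis=1)
        first = reach.argmax(axis=1)
        borders = non_core[has]
        labels[borders] = labels[core_idx[first[has]]]
    return labels


def _medoid(traj: PoseTrajectory, members: np.ndarray) -> int:
    """Positional index (within ``members``) of the frame minimising summed
    RMSD to the other members; ties broken by the smaller frame position."""
    x = _flatten_scaled(traj.select(members))
    m = x.shape[0]
    if m == 1:
        return 0
    xf = np.ascontiguousarray(x, dtype=np.float32)
    sq = np.sum(xf.astype(np.float64) ** 2, axis=1).astype(np.float32)
    sums = np.zeros(m)
    rows, cols = 512, 8192
    for a in range(0, m, rows):
        b = min(a + rows, m)
        xa = xf[a:b]
        for c0 in range(0, m, cols):
            c1 = min(c0 + cols, m)
            d2 = sq[a:b, None] + sq[None, c0:c1] - 2.0 * (xa @ xf[c0:c1].T)
            np.maximum(d2, 0.0, out=d2)
            sums[a:b] += np.sqrt(d2, out=d2).sum(axis=1, dtype=np.float64)
    return int(np.argmin(sums))


def build_clusters(
    labels: np.ndarray,
    traj: PoseTrajectory,
    params: ClusteringParams | None = None,
) -> list[ClusterRecord]:
    """Assemble ClusterRecords from frame labels.

    Residence time of a mode is member count × frame spacing (ns); the
    representative is the medoid. Ids C-01, C-02, ... are assigned by
    descending residence time, ties by the smaller representative frame
    index.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.shape[0] != traj.n_frames:
        raise ValidationError("labels must align with trajectory frames")
    raw: list[tuple[float, int, np.ndarray]] = []
    for lab in np.unique(labels):
        if lab == NOISE:
            continue
        pos = np.flatnonzero(labels == lab)
        members = traj.frame_indices[pos]
        t_ns = pos.size * traj.frame_dt_ps / 1000.0
        rep = int(members[_medoid(traj, pos)])
        raw.append((t_ns, rep, members))
    raw.sort(key=lambda r: (-r[0], r[1]))
    return [
        ClusterRecord(
            cluster_id=f"C-{k + 1:02d}",
            member_frames=members,
            residence_time_ns=t_ns,
            representative_frame=rep,
        )
        for k, (t_ns, rep, members) in enumerate(raw)
    ]


def cluster_poses(
    traj: PoseTrajectory,
    params: ClusteringParams,
    site: SiteDefinition | None = None,
) -> tuple[list[ClusterRecord], np.ndarray, PoseTrajectory]:
    """Filter (optionally), cluster and assemble binding modes in one call.

    Returns ``(clusters, labels, filtered_traj)`` with labels aligned to the
    filtered trajectory. Small trajectories go through the explicit pairwise
    matrix; larger ones use the equivalent Euclidean-metric path on scaled
    flattened coordinates (no pairwise matrix), which yields the same
    clusters for any input whose border points are unambiguous.
    """
    filtered = proximity_filter(traj, site) if site is not None else traj
    if filtered.n_frames == 0:
        return [], np.empty(0, dtype=int), filtered
    if filtered.n_frames == 1:
        labels = (
            np.zeros(1, dtype=int) if params.min_pts <= 1
            else np.full(1, NOISE, dtype=int)
        )
    elif filtered.n_frames <= _MATRIX_PATH_MAX_FRAMES:
        labels = dbscan_cluster(pairwise_rmsd(filtered), params)
    else:
        labels = _dbscan_features(_flatten_scaled(filtered), params)
    clusters = build_clusters(labels, filtered, params)
    return clusters, labels, filtered


def _neighbour_counts(x: np.ndarray, eps: float) -> np.ndarray:
    """Exact eps-neighbourhood sizes (self included) by tiled brute force.

    Float32 Gram-trick distances with cache-sized tiles; a 1e-6 slack on the
    squared radius absorbs the reduced precision at the boundary.
    """
    n = x.shape[0]
    xf = np.ascontiguousarray(x, dtype=np.float32)
    sq = np.sum(xf.astype(np.float64) ** 2, axis=1).astype(np.float32)
    eps2 = np.float32(eps * eps + 1e-6)
    counts = np.zeros(n, dtype=np.int64)
    rows, cols = 512, 8192
    for a in range(0, n, rows):
        b = min(a + rows, n)
        xa = xf[a:b]
        for c0 in range(0, n, cols):
            c1 = min(c0 + cols, n)
            d2 = sq[a:b, None] + sq[None, c0:c1] - 2.0 * (xa @ xf[c0:c1].T)
            counts[a:b] += (d2 <= eps2).sum(axis=1)
    return counts


def _dbscan_features(x: np.ndarray, params: ClusteringParams) -> np.ndarray:
    """Density clustering on coordinate features with the exact semantics of
    :func:`dbscan_cluster` (Euclidean distance == scaled-flattened RMSD),
    without materialising a pairwise matrix: tiled brute-force neighbour
    counts, then frontier expansion for the core components."""
    n = x.shape[0]
    core = _neighbour_counts(x, params.eps_A) >= params.min_pts
    labels = np.full(n, NOISE, dtype=int)
    if not core.any():
        return labels
    core_idx = np.flatnonzero(core)
    xf = np.ascontiguousarray(x, dtype=np.float32)
    sq = np.sum(xf.astype(np.float64) ** 2, axis=1).astype(np.float32)
    eps2 = np.float32(params.eps_A * params.eps_A + 1e-6)

    def _reached(open_idx: np.ndarray, frontier: np.ndarray) -> np.ndarray:
        """Boolean per open point: any frontier member within eps."""
        out = np.zeros(open_idx.size, dtype=bool)
        rows, cols = 512, 8192
        xo, xr = xf[open_idx], xf[frontier]
        for a in range(0, open_idx.size, rows):
            b = min(a + rows, open_idx.size)
            for c0 in range(0, frontier.size, cols):
                c1 = min(c0 + cols, frontier.size)
                d2 = (
                    sq[open_idx[a:b], None]
                    + sq[frontier[c0:c1]][None, :]
                    - 2.0 * (xo[a:b] @ xr[c0:c1].T)
                )
                out[a:b] |= (d2 <= eps2).any(axis=1)
        return out

    # connected components of core points: repeatedly attach every unvisited
    # core within eps of the current frontier
    comp = np.full(core_idx.size, -1, dtype=int)
    next_label = 0
    for seed_pos in range(core_idx.size):
        if comp[seed_pos] != -1:
            continue
        comp[seed_pos] = next_label
        frontier = core_idx[[seed_pos]]
        while frontier.size:
            open_pos = np.flatnonzero(comp == -1)
            if open_pos.size == 0:
                break
            hit = open_pos[_reached(core_idx[open_pos], frontier)]
            comp[hit] = next_label
            frontier = core_idx[hit]
        next_label += 1
    labels[core_idx] = comp
    # border points -> cluster of the lowest-indexed core neighbour
    non_core = np.flatnonzero(~core)
    for start in range(0, non_core.size, 512):
        blk = non_core[start : start + 512]
        d2 = (
            sq[blk, None]
            + sq[core_idx][None, :]
            - 2.0 * (xf[blk] @ xf[core_idx].T)
        )
        within = d2 <= eps2
        has = within.any(axis=1)
        first = within.argmax(axis=1)
        labels[blk[has]] = labels[core_idx[first[has]]]
    return labels


def subsample_snapshots(
    cluster: ClusterRecord,
    traj: PoseTrajectory,
    interval_ns: float = 2.0,
) -> list[int]:
    """Pick energy-calculation snapshots from a cluster every ``interval_ns``.

    Member frames are walked in simulation-time order within each replicate;
    the first member of each replicate is always included and a member is
    added whenever it lies at least ``interval_ns`` after the last included
    one on that replicate's timeline. Intervals are never measured across
    the replicate concatenation seam. The result is non-empty.
    """
    if interval_ns <= 0:
        raise ValidationError("interval_ns must be positive")
    pos_by_frame = {int(f): i for i, f in enumerate(traj.frame_indices)}
    try:
        member_pos = np.array(
            [pos_by_frame[int(f)] for f in cluster.member_frames], dtype=int
        )
    except KeyError as exc:
        raise ValidationError(f"member frame {exc} not present in trajectory")
    out: list[int] = []
    for rep in np.unique(traj.replicate_ids[member_pos]):
        pos = member_pos[traj.replicate_ids[member_pos] == rep]
        times = traj.times_ps[pos] / 1000.0
        order = np.argsort(times, kind="stable")
        last = -np.inf
        for p, t in zip(pos[order], times[order]):
            if t - last >= interval_ns or not np.isfinite(last):
                out.append(int(traj.frame_indices[p]))
                last = t
    return out
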