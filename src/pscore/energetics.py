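"""Per-snapshot interaction energies and their dynamical average per cluster.

A snapshot's interaction energy is either taken directly from a table
(MM-PBSA or any end-point estimate) or assembled as the PIEDA sum of five
terms: electrostatic, exchange repulsion, charge transfer + mixed, dispersion
and solvation. A binding mode's energy is the arithmetic mean over the
snapshots extracted from its cluster (dynamical averaging), or the single
representative-frame energy when the quicker single-snapshot mode is chosen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .cluster import subsample_snapshots
from .datatypes import (
    ClusterRecord,
    EnergySeries,
    PiedaComponents,
    PoseTrajectory,
    ValidationError,
)

__all__ = ["ClusterEnergySummary", "pieda_total", "da_average", "attach_energies"]


@dataclass
class ClusterEnergySummary:
    """Dynamically averaged interaction energy of one binding mode."""

    cluster_id: str
    snapshot_frames: list[int]
    snapshot_energies: list[float]
    mean_energy_kcal: float
    n: int
    sd_kcal: float

    def __post_init__(self) -> None:
        if self.n != len(self.snapshot_energies) or self.n < 1:
            raise ValidationError("n must equal the number of snapshot energies (>=1)")


def pieda_total(c: PiedaComponents) -> float:
    """Total interaction energy as the sum of the five PIEDA terms (kcal/mol)."""
    total = c.total()
    if not math.isfinite(total):
        raise ValidationError("PIEDA total is not finite")
    return total


def da_average(
    cluster: ClusterRecord,
    energies: EnergySeries,
    snapshots: list[int],
) -> ClusterEnergySummary:
    """Average the interaction energy over a cluster's extracted snapshots.

    The mean is the plain arithmetic mean over the N snapshot energies; the
    standard deviation (ddof=0) is reported for diagnostics only and plays
    no role in scoring.
    """
    if not snapshots:
        raise ValidationError(f"cluster {cluster.cluster_id}: no snapshots given")
    missing = [int(f) for f in snapshots if not energies.has_frame(f)]
    if missing:
        raise ValidationError(
            f"cluster {cluster.cluster_id}: no energy record for frames {missing}"
        )
    vals = [energies.energy_for(f) for f in snapshots]
    arr = np.asarray(vals, dtype=float)
    summary = ClusterEnergySummary(
        cluster_id=cluster.cluster_id,
        snapshot_frames=[int(f) for f in snapshots],
        snapshot_energies=vals,
        mean_energy_kcal=float(arr.mean()),
        n=len(vals),
        sd_kcal=float(arr.std()),
    )
    cluster.mean_energy_kcal = summary.mean_energy_kcal
    cluster.n_energy_snapshots = summary.n
    return summary


def attach_energies(
    clusters: list[ClusterRecord],
    energies: EnergySeries,
    traj: PoseTrajectory,
    mode: str = "da",
    interval_ns: float = 2.0,
) -> list[ClusterEnergySummary]:
    """Assign a mean interaction energy to every cluster.

    mode="da": dynamical averaging over snapshots subsampled every
    ``interval_ns`` from each cluster. mode="single": the representative
    (medoid) frame's energy alone. The two modes coincide when a cluster
    yields exactly one snapshot or has zero within-cluster energy variance.
    """
    if mode not in ("da", "single"):
        raise ValidationError(f"unknown energy mode {mode!r}")
    summaries = []
    for cl in clusters:
        if mode == "da":
            snaps = subsample_snapshots(cl, traj, interval_ns=interval_ns)
        else:
            snaps = [int(cl.representative_frame)]
        summaries.append(da_average(cl, energies, snaps))
    return summaries
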