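"""Readers and writers for trajectories, energy tables, sites and results.

File conventions across the package: CSV is comma-separated, "." decimal,
UTF-8, header mandatory; energies kcal/mol, times ns, distances Å.

Coordinates are assumed to be ALREADY ALIGNED to the protein frame (poses are
defined relative to the binding site); no superposition is ever performed on
read. Hydrogens are dropped on input, with the element inferred from the
leading characters of the atom name when no element field is present.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

from .datatypes import (
    DEFAULT_FRAME_DT_PS,
    ComparisonSet,
    EnergySeries,
    PiedaComponents,
    PoseTrajectory,
    SiteDefinition,
    ValidationError,
)

__all__ = [
    "FormatError",
    "read_pose_trajectory",
    "write_pose_trajectory",
    "read_energy_series",
    "write_energy_series",
    "read_site_definition",
    "read_rmsd_matrix",
    "write_results",
    "load_run_config",
]

PIEDA_COLUMNS = ("es", "ex", "ct_mix", "di", "g_sol")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


_ELEMENT_2CHAR = {
    "CL", "BR", "NA", "MG", "ZN", "FE", "MN", "CA", "CU", "SE", "SI", "AL", "LI", "K",
}


def element_from_atom_name(name: str) -> str:
    """Infer the element from a PDB-style atom name.

    Leading digits are stripped (e.g. ``1HB`` -> hydrogen); two-character
    elements such as CL/BR/ZN are recognised when the name starts with them.
    """
    s = re.sub(r"^[0-9 ]+", "", name.strip()).upper()
    if not s:
        raise FormatError(f"cannot infer element from atom name {name!r}")
    if s[:2] in _ELEMENT_2CHAR:
        return s[:2].capitalize()
    return s[0]


def _is_hydrogen(atom_name: str, element: str = "") -> bool:
    el = element.strip().upper() or element_from_atom_name(atom_name).upper()
    return el in ("H", "D")


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def _scan_pdb_model_atom_counts(path: Path) -> list[int]:
    """Per-MODEL ATOM/HETATM record counts; single implicit model if no MODEL."""
    counts: list[int] = []
    current: Optional[int] = None
    saw_model = False
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            rec = line[:6].strip()
            if rec == "MODEL":
                saw_model = True
                if current is not None:
                    counts.append(current)
                current = 0
            elif rec in ("ATOM", "HETATM"):
                if current is None:
                    current = 0
                current += 1
            elif rec == "ENDMDL":
                if current is not None:
                    counts.append(current)
                    current = None
    if current is not None:
        counts.append(current)
    if not saw_model and counts and counts[0] == 0:
        counts = []
    return counts


def _read_pdb_frames(path: Path) -> tuple[np.ndarray, list[str]]:
    counts = _scan_pdb_model_atom_counts(path)
    if not counts or sum(counts) == 0:
        raise FormatError(f"{path}: no models with atoms found")
    ref = counts[0]
    for m, c in enumerate(counts, start=1):
        if c != ref:
            raise FormatError(
                f"{path}: model {m} has {c} atoms while model 1 has {ref}"
            )
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(model=None)
    if isinstance(stack, bst.AtomArray):  # single model
        stack = bst.stack([stack])
    names = [str(n) for n in stack.atom_name]
    elements = [str(e) for e in stack.element]
    heavy = np.array(
        [not _is_hydrogen(n, e) for n, e in zip(names, elements)], dtype=bool
    )
    coords = np.asarray(stack.coord, dtype=float)[:, heavy, :]
    atom_names = [n for n, h in zip(names, heavy) if h]
    return coords, atom_names


_XYZ_KV = re.compile(r"(\w+)=([-+0-9.eE]+)")


def _read_xyz_frames(
    path: Path,
) -> tuple[np.ndarray, list[str], list[dict[str, float]]]:
    """Parse (extended) XYZ; returns coords, names and per-frame comment keys.

    The comment line may carry ``frame_index=I time_ps=T replicate=R``.
    """
    frames: list[np.ndarray] = []
    metas: list[dict[str, float]] = []
    names_ref: Optional[list[str]] = None
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    pos = 0
    model = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        model += 1
        try:
            nat = int(lines[pos].split()[0])
        except (ValueError, IndexError):
            raise FormatError(f"{path}: model {model}: bad atom-count line {pos + 1}")
        comment = lines[pos + 1] if pos + 1 < len(lines) else ""
        meta = {k: float(v) for k, v in _XYZ_KV.findall(comment)}
        body = lines[pos + 2 : pos + 2 + nat]
        if len(body) < nat:
            raise FormatError(f"{path}: model {model}: truncated frame")
        names, xyz = [], []
        for ln in body:
            parts = ln.split()
            if len(parts) < 4:
                raise FormatError(f"{path}: model {model}: bad atom line {ln!r}")
            names.append(parts[0])
            xyz.append([float(parts[1]), float(parts[2]), float(parts[3])])
        heavy = [not _is_hydrogen(n) for n in names]
        names = [n for n, h in zip(names, heavy) if h]
        xyz = np.asarray(xyz, dtype=float)[np.asarray(heavy, dtype=bool)]
        if names_ref is None:
            names_ref = names
        elif len(names) != len(names_ref):
            raise FormatError(
                f"{path}: model {model} has {len(names)} heavy atoms while "
                f"model 1 has {len(names_ref)}"
            )
        frames.append(xyz)
        metas.append(meta)
        pos += 2 + nat
    if not frames:
        raise FormatError(f"{path}: no models found")
    return np.stack(frames), list(names_ref or []), metas


def read_pose_trajectory(
    path: Union[str, Path],
    format: Optional[str] = None,
    frame_dt_ps: float = DEFAULT_FRAME_DT_PS,
) -> PoseTrajectory:
    """Read a multi-model PDB or (extended) XYZ ligand pose trajectory.

    Hydrogens are dropped. Timestamps absent from the file are filled as
    ``frame_index * frame_dt_ps``. Extended-XYZ comment-line keys
    ``frame_index`` / ``time_ps`` / ``replicate`` are honoured when present.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or ("xyz" if path.suffix.lower() in (".xyz", ".exyz") else "pdb")
    if fmt == "pdb":
        coords, names = _read_pdb_frames(path)
        metas: list[dict[str, float]] = [{} for _ in range(coords.shape[0])]
    elif fmt == "xyz":
        coords, names, metas = _read_xyz_frames(path)
    else:
        raise FormatError(f"unknown trajectory format {fmt!r}")
    n = coords.shape[0]
    frame_indices = np.array(
        [int(m.get("frame_index", i)) for i, m in enumerate(metas)], dtype=int
    )
    times = np.array(
        [m.get("time_ps", fi * frame_dt_ps) for fi, m in zip(frame_indices, metas)],
        dtype=float,
    )
    reps = np.array([int(m.get("replicate", 0)) for m in metas], dtype=int)
    return PoseTrajectory(
        coords=coords,
        atom_names=names,
        frame_indices=frame_indices,
        times_ps=times,
        replicate_ids=reps,
        frame_dt_ps=frame_dt_ps,
    )


def write_pose_trajectory(
    traj: PoseTrajectory, path: Union[str, Path], format: Optional[str] = None
) -> None:
    """Write a trajectory as multi-model PDB or extended XYZ.

    XYZ preserves all frame identities (frame_index, time_ps, replicate) on
    the comment line; PDB carries coordinates and atom names only.
    """
    path = Path(path)
    fmt = format or ("xyz" if path.suffix.lower() in (".xyz", ".exyz") else "pdb")
    if fmt == "xyz":
        with open(path, "w", encoding="utf-8") as fh:
            for f in range(traj.n_frames):
                fh.write(f"{traj.n_atoms}\n")
                fh.write(
                    f"frame_index={traj.frame_indices[f]} "
                    f"time_ps={traj.times_ps[f]:.6f} "
                    f"replicate={traj.replicate_ids[f]}\n"
                )
                for a in range(traj.n_atoms):
                    x, y, z = traj.coords[f, a]
                    fh.write(
                        f"{traj.atom_names[a]} {x:.6f} {y:.6f} {z:.6f}\n"
                    )
        return
    if fmt != "pdb":
        raise FormatError(f"unknown trajectory format {fmt!r}")
    n_at = traj.n_atoms
    array = bst.AtomArray(n_at)
    array.coord = np.zeros((n_at, 3))
    array.atom_name = np.array(traj.atom_names)
    array.res_name = np.full(n_at, "LIG")
    array.res_id = np.ones(n_at, dtype=int)
    array.chain_id = np.full(n_at, "A")
    array.hetero = np.ones(n_at, dtype=bool)
    array.element = np.array([element_from_atom_name(n) for n in traj.atom_names])
    stack = bst.stack([array] * traj.n_frames)
    stack.coord = np.asarray(traj.coords, dtype=float)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# energy tables
# ---------------------------------------------------------------------------

def read_energy_series(
    path: Union[str, Path],
    schema: str = "auto",
    source_kind: str = "other",
) -> EnergySeries:
    """Read a per-snapshot energy CSV.

    schema="total" expects columns ``frame_index, energy_total``;
    schema="pieda" expects ``frame_index, es, ex, ct_mix, di, g_sol`` and
    stores the per-row total as the component sum. schema="auto" picks by
    the columns present.
    """
    df = pd.read_csv(path)
    if "frame_index" not in df.columns:
        raise FormatError(f"{path}: missing required column 'frame_index'")
    if schema == "auto":
        schema = "pieda" if all(c in df.columns for c in PIEDA_COLUMNS) else "total"
    if schema == "pieda":
        missing = [c for c in PIEDA_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: pieda schema missing columns {missing}")
        comps = [
            PiedaComponents(
                es=row.es, ex=row.ex, ct_mix=row.ct_mix, di=row.di, g_sol=row.g_sol
            )
            for row in df.itertuples()
        ]
        energies = np.array([c.total() for c in comps])
        return EnergySeries(
            frame_indices=df["frame_index"].to_numpy(),
            energies=energies,
            components=comps,
            source_kind=source_kind,
        )
    if schema == "total":
        if "energy_total" not in df.columns:
            raise FormatError(f"{path}: total schema missing column 'energy_total'")
        return EnergySeries(
            frame_indices=df["frame_index"].to_numpy(),
            energies=df["energy_total"].to_numpy(dtype=float),
            source_kind=source_kind,
        )
    raise FormatError(f"unknown energy schema {schema!r}")


def write_energy_series(series: EnergySeries, path: Union[str, Path]) -> None:
    """Write an energy table as CSV (components included when present)."""
    cols: dict[str, Sequence] = {"frame_index": series.frame_indices}
    if series.components is not None:
        for name in PIEDA_COLUMNS:
            cols[name] = [getattr(c, name) for c in series.components]
    cols["energy_total"] = series.energies
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# sites, matrices, results, config
# ---------------------------------------------------------------------------

def read_site_definition(
    path: Union[str, Path], cutoff_A: float = 9.0
) -> SiteDefinition:
    """Read a binding-site definition from CSV (x,y,z rows) or PDB."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path)
        cols = [c for c in ("x", "y", "z") if c in df.columns]
        if len(cols) != 3:
            raise FormatError(f"{path}: site CSV must have x,y,z columns")
        coords = df[["x", "y", "z"]].to_numpy(dtype=float)
    else:
        coords, _ = _read_pdb_frames(path)
        coords = coords[0]
    if coords.shape[0] == 1:
        return SiteDefinition(site_center=coords[0], cutoff_A=cutoff_A)
    return SiteDefinition(site_coords=coords, cutoff_A=cutoff_A)


def read_rmsd_matrix(path: Union[str, Path]) -> tuple[np.ndarray, np.ndarray]:
    """Read a precomputed square RMSD matrix CSV (header row = frame indices).

    Returns ``(matrix, frame_indices)``.
    """
    df = pd.read_csv(path, index_col=0)
    mat = df.to_numpy(dtype=float)
    if mat.shape[0] != mat.shape[1]:
        raise FormatError(f"{path}: RMSD matrix is not square: {mat.shape}")
    idx = np.array([int(c) for c in df.columns], dtype=int)
    return mat, idx


RESULT_COLUMNS = [
    "ligand_id",
    "cluster_id",
    "t_i_ns",
    "delta_e_kcal",
    "p_score",
    "norm_time",
    "norm_affinity",
    "quadrant",
    "confidence",
]


def write_results(
    comparison: ComparisonSet,
    path: Union[str, Path],
    parameters: Optional[dict] = None,
    seed: Optional[int] = None,
) -> tuple[Path, Path]:
    """Write a scored comparison set: entries CSV plus JSON run metadata.

    Output is deterministic: entries sorted by ligand_id then p_score
    descending (cluster_id as final key), fixed float formatting, sorted JSON
    keys. Returns the two paths written.
    """
    from . import __version__

    path = Path(path)
    csv_path = path.with_suffix(".csv")
    json_path = path.with_suffix(".json")
    rows = sorted(
        comparison.entries,
        key=lambda e: (e.ligand_id, -e.p_score if np.isfinite(e.p_score) else 0.0,
                       e.cluster_id),
    )
    df = pd.DataFrame(
        [
            {
                "ligand_id": e.ligand_id,
                "cluster_id": e.cluster_id,
                "t_i_ns": e.t_i_ns,
                "delta_e_kcal": e.delta_e_kcal,
                "p_score": e.p_score,
                "norm_time": e.norm_time,
                "norm_affinity": e.norm_affinity,
                "quadrant": e.quadrant,
                "confidence": e.confidence,
            }
            for e in rows
        ],
        columns=RESULT_COLUMNS,
    )
    df.to_csv(csv_path, index=False, float_format="%.10g", lineterminator="\n")
    meta = {
        "version": __version__,
        "n_entries": len(comparison.entries),
        "total_time_T_ns": comparison.total_time_T_ns,
        "e_min_kcal": _json_num(comparison.e_min_kcal),
        "e_max_kcal": _json_num(comparison.e_max_kcal),
        "mean_norm_time": _json_num(comparison.mean_norm_time),
        "mean_norm_affinity": _json_num(comparison.mean_norm_affinity),
        "parameters": parameters or {},
        "seed": seed,
        "warnings": [] if comparison.entries else ["comparison set is empty"],
    }
    with open(json_path, "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return csv_path, json_path


def _json_num(x: float):
    return None if not np.isfinite(x) else float(x)


def load_run_config(path: Union[str, Path]) -> dict:
    """Load a YAML run configuration into a flat dict."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: run config must be a mapping")
    return cfg
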