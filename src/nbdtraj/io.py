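"""Structure and trajectory containers plus PDB/DCD/CSV input-output.

Coordinates are stored in Å throughout, residue numbering is 1-based as in
the source PDB entry, and atom order is always preserved from the file.
Times are in ps; the default time base is an MD integration step of 1.5 fs
with coordinates saved every 5000 steps (7.5 ps per frame).

PDB records are handled through :mod:`biotite`, DCD through :mod:`mdtraj`'s
low-level reader; both are wrapped so that the rest of the toolkit only ever
sees the two containers defined here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, NamedTuple, Sequence

import numpy as np
import pandas as pd
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile
from mdtraj.formats import DCDTrajectoryFile

from .errors import FormatError

logger = logging.getLogger(__name__)

#: default integration timestep (fs) and save interval (steps)
DEFAULT_STEP_FS = 1.5
DEFAULT_SAVE_INTERVAL_STEPS = 5000


class AtomRecord(NamedTuple):
    chain_id: str
    residue_number: int
    residue_name: str
    atom_name: str
    element: str
    position: np.ndarray  # 3-vector, Å


@dataclass
class Structure:
    """A single-model structure: parallel per-atom annotation arrays + coordinates.

    Invariants: ``(chain_id, residue_number, atom_name)`` unique, all
    coordinates finite, atom order as in the source.
    """

    chain_ids: np.ndarray        # (n,) str
    residue_numbers: np.ndarray  # (n,) int
    residue_names: np.ndarray    # (n,) str
    atom_names: np.ndarray       # (n,) str
    elements: np.ndarray         # (n,) str
    coords: np.ndarray           # (n, 3) float, Å
    title: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.coords)
        for name in ("chain_ids", "residue_numbers", "residue_names",
                     "atom_names", "elements"):
            arr = np.asarray(getattr(self, name))
            if len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != {n} atoms")
            setattr(self, name, arr)
        if n and not np.isfinite(self.coords).all():
            raise FormatError("non-finite coordinates in structure")
        keys = list(zip(self.chain_ids, self.residue_numbers, self.atom_names))
        if len(set(keys)) != n:
            seen: set = set()
            for k in keys:
                if k in seen:
                    raise FormatError(f"duplicate atom identity {k}")
                seen.add(k)

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def atoms(self) -> Iterator[AtomRecord]:
        for i in range(self.n_atoms):
            yield AtomRecord(
                str(self.chain_ids[i]), int(self.residue_numbers[i]),
                str(self.residue_names[i]), str(self.atom_names[i]),
                str(self.elements[i]), self.coords[i],
            )

    def with_coords(self, coords: np.ndarray, title: str | None = None) -> "Structure":
        """Copy of this structure with replaced coordinates (same atoms)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != self.coords.shape:
            raise ValueError(f"coordinate shape {coords.shape} != {self.coords.shape}")
        return Structure(self.chain_ids, self.residue_numbers, self.residue_names,
                         self.atom_names, self.elements, coords,
                         self.title if title is None else title)

    def subset(self, indices: Sequence[int], title: str | None = None) -> "Structure":
        idx = np.asarray(indices, dtype=int)
        return Structure(self.chain_ids[idx], self.residue_numbers[idx],
                         self.residue_names[idx], self.atom_names[idx],
                         self.elements[idx], self.coords[idx],
                         self.title if title is None else title)

    def identity_tuples(self) -> list[tuple[str, int, str]]:
        return list(zip((str(c) for c in self.chain_ids),
                        (int(r) for r in self.residue_numbers),
                        (str(a) for a in self.atom_names)))


@dataclass
class Trajectory:
    """Fixed-topology coordinate trajectory with a ps time axis."""

    topology: Structure
    frames: np.ndarray  # (n_frames, n_atoms, 3) Å
    times: np.ndarray   # (n_frames,) ps, strictly increasing
    step_fs: float = DEFAULT_STEP_FS
    save_interval_steps: int = DEFAULT_SAVE_INTERVAL_STEPS

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError(f"frames must be (n_frames, n_atoms, 3), got {self.frames.shape}")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise FormatError(
                f"frame atom count {self.frames.shape[1]} != topology "
                f"atom count {self.topology.n_atoms}")
        if self.n_frames < 1:
            raise FormatError("trajectory must contain at least one frame")
        if len(self.times) != self.n_frames:
            raise ValueError("times length != frame count")
        if self.n_frames > 1 and not (np.diff(self.times) > 0).all():
            raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def frame_structure(self, i: int) -> Structure:
        """Frame ``i`` as a Structure on the trajectory topology."""
        return self.topology.with_coords(self.frames[i])


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def _atom_array_to_structure(arr: bst.AtomArray, title: str) -> Structure:
    return Structure(
        chain_ids=arr.chain_id.astype(str),
        residue_numbers=arr.res_id.astype(int),
        residue_names=arr.res_name.astype(str),
        atom_names=arr.atom_name.astype(str),
        elements=arr.element.astype(str),
        coords=np.asarray(arr.coord, dtype=float),
        title=title,
    )


def _filter_altloc(arr: bst.AtomArray, path: str) -> bst.AtomArray:
    """Keep blank/'A' alternate locations only; warn when any are dropped."""
    altloc = getattr(arr, "altloc_id", None)
    if altloc is None:
        return arr
    keep = np.isin(altloc, ("", " ", ".", "A"))
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("%s: dropped %d atoms with altLoc other than blank/'A'",
                       path, n_dropped)
        arr = arr[keep]
    return arr


def read_pdb(path: str | Path) -> Structure | Trajectory:
    """Read a PDB file: one MODEL gives a Structure, several a Trajectory.

    Multi-model files must carry identical atom lists in every model; the
    resulting trajectory has unit-spaced times (1 ps) since PDB stores no
    time axis. Insertion codes are rejected; alternate locations other than
    blank/'A' are dropped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    pdb = PDBFile.read(str(path))
    n_models = pdb.get_model_count()
    if n_models == 0:
        raise FormatError(f"{path}: no ATOM records")

    def _model(i: int) -> bst.AtomArray:
        arr = pdb.get_structure(model=i, altloc="all",
                                extra_fields=["occupancy"])
        if arr.array_length() == 0:
            raise FormatError(f"{path}: no ATOM records")
        if (arr.ins_code != "").any():
            bad = arr[arr.ins_code != ""][0]
            raise FormatError(
                f"{path}: insertion codes are not supported "
                f"(first at {bad.chain_id}/{bad.res_id}{bad.ins_code})")
        return _filter_altloc(arr, str(path))

    first = _model(1)
    title = " ".join(pdb.lines[0].split()[1:]) if pdb.lines and pdb.lines[0].startswith("TITLE") else ""
    struct = _atom_array_to_structure(first, title)
    if n_models == 1:
        return struct

    frames = np.empty((n_models, struct.n_atoms, 3))
    frames[0] = struct.coords
    ref_ids = struct.identity_tuples()
    for m in range(2, n_models + 1):
        arr = _model(m)
        s = _atom_array_to_structure(arr, title)
        if s.identity_tuples() != ref_ids:
            ids = s.identity_tuples()
            for j, ref in enumerate(ref_ids):
                if j >= len(ids) or ids[j] != ref:
                    got = ids[j] if j < len(ids) else "missing"
                    raise FormatError(
                        f"{path}: model {m} atom list differs from model 1 "
                        f"at position {j}: expected {ref}, got {got}")
            raise FormatError(f"{path}: model {m} has extra trailing atoms")
        frames[m - 1] = s.coords
    times = np.arange(n_models, dtype=float)  # unit-spaced placeholder
    return Trajectory(struct, frames, times)


def _structure_to_atom_array(struct: Structure) -> bst.AtomArray:
    arr = bst.AtomArray(struct.n_atoms)
    arr.chain_id = struct.chain_ids.astype("U4")
    arr.res_id = struct.residue_numbers.astype(int)
    arr.res_name = struct.residue_names.astype("U5")
    arr.atom_name = struct.atom_names.astype("U6")
    arr.element = struct.elements.astype("U2")
    arr.coord = np.asarray(struct.coords, dtype=np.float32)
    # ligand/pseudo-residues (ADP, PO4, ...) go out as HETATM records
    standard = bst.info.amino_acid_names() if hasattr(bst.info, "amino_acid_names") else ()
    if standard:
        arr.hetero = ~np.isin(struct.residue_names, list(standard))
    else:
        arr.hetero = np.zeros(struct.n_atoms, dtype=bool)
    return arr


def write_pdb(path: str | Path, structures: Structure | Sequence[Structure]) -> None:
    """Write one Structure (single model) or several (multi-model PDB)."""
    if isinstance(structures, Structure):
        models = [structures]
    else:
        models = list(structures)
    if not models:
        raise ValueError("no structures to write")
    pdb = PDBFile()
    if len(models) == 1:
        pdb.set_structure(_structure_to_atom_array(models[0]))
    else:
        ref = models[0].identity_tuples()
        for m in models[1:]:
            if m.identity_tuples() != ref:
                raise FormatError("multi-model write requires identical atom lists")
        stack = bst.stack([_structure_to_atom_array(m) for m in models])
        pdb.set_structure(stack)
    pdb.write(str(path))


def write_trajectory_pdb(path: str | Path, traj: Trajectory) -> None:
    write_pdb(path, [traj.frame_structure(i) for i in range(traj.n_frames)])


# ---------------------------------------------------------------------------
# DCD
# ---------------------------------------------------------------------------

def read_dcd(path: str | Path, topology: Structure, *,
             step_fs: float = DEFAULT_STEP_FS,
             save_interval_steps: int = DEFAULT_SAVE_INTERVAL_STEPS) -> Trajectory:
    """Read a DCD coordinate file against ``topology``.

    DCD headers carry no trustworthy time base, so frame times are computed
    as ``step_fs * save_interval_steps`` ps spacing starting at 0.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with DCDTrajectoryFile(str(path)) as f:
            xyz, _, _ = f.read()
    except Exception as exc:  # truncated/corrupt file
        raise FormatError(f"{path}: cannot read DCD ({exc})") from exc
    if xyz is None or len(xyz) == 0:
        raise FormatError(f"{path}: no frames in DCD")
    xyz = np.asarray(xyz, dtype=float)
    if xyz.shape[1] != topology.n_atoms:
        raise FormatError(
            f"{path}: DCD atom count {xyz.shape[1]} != topology atom count "
            f"{topology.n_atoms}")
    interval_ps = step_fs * save_interval_steps * 1e-3
    times = np.arange(len(xyz)) * interval_ps
    return Trajectory(topology, xyz, times,
                      step_fs=step_fs, save_interval_steps=save_interval_steps)


def write_dcd(path: str | Path, traj: Trajectory) -> None:
    with DCDTrajectoryFile(str(path), "w") as f:
        f.write(np.asarray(traj.frames, dtype=np.float32))


# ---------------------------------------------------------------------------
# Time axis
# ---------------------------------------------------------------------------

def time_axis(n_steps: float, step_fs: float,
              save_interval_steps: int) -> tuple[float, float]:
    """Total simulated time (ns) and frame spacing (ps) from run bookkeeping.

    ``total_ns = n_steps * step_fs * 1e-6``;
    ``frame_interval_ps = save_interval_steps * step_fs * 1e-3``.
    """
    if n_steps <= 0 or step_fs <= 0 or save_interval_steps <= 0:
        raise ValueError("n_steps, step_fs and save_interval_steps must be positive")
    total_ns = n_steps * step_fs * 1e-6
    frame_interval_ps = save_interval_steps * step_fs * 1e-3
    return total_ns, frame_interval_ps


def subsample(traj: Trajectory, interval_ps: float) -> Trajectory:
    """Keep frames at (multiples of) ``interval_ps``; frame 0 always survives.

    A frame survives when its time lies within half a native frame spacing
    of a multiple of the interval, so exact multiples are kept and nothing
    is double-counted. Times are preserved from the source.
    """
    if traj.n_frames > 1:
        native = float(np.min(np.diff(traj.times)))
    else:
        native = interval_ps
    if interval_ps < native - 1e-9:
        raise ValueError(
            f"subsample interval {interval_ps} ps is below the native frame "
            f"spacing {native} ps")
    t = traj.times
    k = np.round(t / interval_ps)
    keep = np.abs(t - k * interval_ps) <= native / 2 + 1e-9
    keep[0] = True
    return Trajectory(traj.topology, traj.frames[keep], t[keep],
                      step_fs=traj.step_fs,
                      save_interval_steps=traj.save_interval_steps)


# ---------------------------------------------------------------------------
# CSV time series
# ---------------------------------------------------------------------------

def write_timeseries_csv(path: str | Path, times: np.ndarray,
                         columns: dict[str, np.ndarray]) -> None:
    """Write a headered CSV with columns frame,time_ps,<value columns...>."""
    times = np.asarray(times, dtype=float)
    data = {"frame": np.arange(len(times)), "time_ps": times}
    for label, values in columns.items():
        values = np.asarray(values, dtype=float)
        if len(values) != len(times):
            raise ValueError(f"column {label!r} length {len(values)} != {len(times)}")
        data[label] = values
    pd.DataFrame(data).to_csv(path, index=False)


def read_timeseries_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
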