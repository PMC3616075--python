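"""Essential dynamics: Cα covariance PCA and everything built on it.

Each trajectory frame is least-squares aligned (over the analysis
selection) to a fixed reference structure; the 3N-dimensional covariance of
the aligned coordinates about their trajectory mean is then diagonalised.
The leading eigenvectors ("modes") are the dominant collective motions; the
eigenvalue fraction of a mode is its share of total Cα fluctuation.

Projections are of deviations *from the trajectory mean* along a mode, in Å
— also for cross-projection, where a trajectory from a different run is
projected onto a model fitted elsewhere (atom correspondence permitting).
Subspace overlap between a mode and the leading modes of another model is
the root-sum-of-squares of inner products, which reduces to |cos θ| for a
single mode.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateGeometryError, SelectionError
from .geometry import kabsch_fit
from .io import Structure, Trajectory
from .scheme import AtomSelection

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PCAModel:
    """Essential-dynamics model: alignment frame, mean, modes, eigenvalues.

    ``modes`` has shape (n_modes, 3N) with orthonormal rows, eigenvalues (Å²)
    sorted descending. ``mean`` is the trajectory mean of the aligned
    coordinates, flattened to 3N.
    """

    selection: AtomSelection
    reference: Structure
    mean: np.ndarray          # (3N,)
    modes: np.ndarray         # (n_modes, 3N)
    eigenvalues: np.ndarray   # (n_modes,)
    source_label: str = ""

    @property
    def n_atoms(self) -> int:
        return len(self.mean) // 3

    @property
    def fractions(self) -> np.ndarray:
        """Eigenvalue fraction of each mode (shares of total fluctuation)."""
        total = self.eigenvalues.sum()
        if total <= 0:
            return np.zeros_like(self.eigenvalues)
        return self.eigenvalues / total


def _aligned_coordinates(traj: Trajectory, sel: AtomSelection,
                         reference: Structure) -> np.ndarray:
    """(n_frames, 3N) selection coordinates after per-frame Kabsch alignment."""
    ref = sel.coords(reference.coords)
    out = np.empty((traj.n_frames, len(sel) * 3))
    for i in range(traj.n_frames):
        fit = kabsch_fit(sel.coords(traj.frames[i]), ref)
        out[i] = fit.apply(sel.coords(traj.frames[i])).ravel()
    return out


def _canonical_sign(mode: np.ndarray) -> np.ndarray:
    """Fix the arbitrary eigenvector sign: largest-magnitude component positive."""
    k = int(np.argmax(np.abs(mode)))
    return -mode if mode[k] < 0 else mode


def fit_pca(traj: Trajectory, sel: AtomSelection, reference: Structure,
            source_label: str = "") -> PCAModel:
    """Fit the essential-dynamics model on an aligned Cα trajectory.

    The covariance is unweighted (no masses); the eigendecomposition is the
    full symmetric one, adequate for NBD-dimer-sized selections (~460 Cα).
    """
    if traj.n_frames < 2:
        raise ValueError("PCA needs at least 2 frames")
    if len(sel) < 3:
        raise DegenerateGeometryError("PCA selection needs >= 3 atoms")
    X = _aligned_coordinates(traj, sel, reference)
    mean = X.mean(axis=0)
    Xc = X - mean
    cov = (Xc.T @ Xc) / X.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    modes = np.stack([_canonical_sign(evecs[:, j]) for j in order])
    return PCAModel(sel, reference, mean, modes, evals, source_label)


@dataclass(frozen=True)
class ProjectionSeries:
    """Signed per-frame amplitude (Å) along one mode of a PCA model."""

    times: np.ndarray
    values: np.ndarray
    mode_index: int          # 1-based
    source_model: str = ""

    def __post_init__(self) -> None:
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have equal length")


def project(traj: Trajectory, model: PCAModel, mode: int,
            flip_sign: bool = False) -> ProjectionSeries:
    """Project a trajectory onto mode ``mode`` (1-based) of a PCA model.

    Works identically for cross-projection of another run, provided the atom
    correspondence of the model's selection holds on that trajectory.
    """
    if not 1 <= mode <= len(model.modes):
        raise ValueError(f"mode {mode} out of range (model has {len(model.modes)})")
    if model.selection.index_array.max() >= traj.n_atoms:
        raise SelectionError("model selection exceeds trajectory atom count")
    X = _aligned_coordinates(traj, model.selection, model.reference)
    v = model.modes[mode - 1]
    values = (X - model.mean) @ v
    if flip_sign:
        values = -values
    return ProjectionSeries(traj.times, values, mode, model.source_label)


def project_structure(struct: Structure, model: PCAModel, mode: int,
                      align: bool = True) -> float:
    """Projection of a single structure onto a mode.

    With ``align=True`` the structure is Kabsch-aligned onto the model
    reference first; pass ``align=False`` for coordinates already expressed
    in the model frame (e.g. structures built by :func:`interpolate_mode`).
    A structure holding exactly the selection's atoms is used as-is.
    """
    sel = model.selection
    if struct.n_atoms == model.n_atoms:
        coords = struct.coords
    else:
        coords = sel.coords(struct.coords)
    if align:
        fit = kabsch_fit(coords, sel.coords(model.reference.coords))
        coords = fit.apply(coords)
    return float((coords.ravel() - model.mean) @ model.modes[mode - 1])


def subspace_overlap(vector: np.ndarray, model: PCAModel, k: int) -> float:
    """Root-sum-of-squares overlap of a unit 3N vector with modes 1..k.

    1 means the vector lies inside the span of the first k modes, 0 that it
    is orthogonal to all of them. Non-unit vectors are normalised with a
    warning.
    """
    v = np.asarray(vector, dtype=float).ravel()
    norm = np.linalg.norm(v)
    if norm == 0:
        raise ValueError("zero vector has no direction")
    if abs(norm - 1.0) > 1e-8:
        warnings.warn("subspace_overlap: normalising non-unit vector")
        v = v / norm
    if not 1 <= k <= len(model.modes):
        raise ValueError(f"k={k} exceeds available modes ({len(model.modes)})")
    dots = model.modes[:k] @ v
    return float(np.sqrt((dots ** 2).sum()))


def pearson_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson product-moment correlation of two equal-length series."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    if len(a) < 3:
        raise ValueError("need at least 3 samples")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero-variance series has no correlation")
    return float(stats.pearsonr(a, b).statistic)


def extreme_frames(proj: ProjectionSeries, traj: Trajectory,
                   model: PCAModel) -> tuple[Structure, Structure, tuple[float, float]]:
    """Aligned frames attaining the minimum and maximum projection.

    Returns (min_frame, max_frame, (t_min, t_max)); ties resolve to the
    earliest time. Frames are returned as full structures with the frame's
    alignment (onto the model reference over the model selection) applied to
    all atoms.
    """
    if len(proj.values) == 0:
        raise ValueError("empty projection series")
    if len(proj.values) != traj.n_frames:
        raise ValueError("projection length != trajectory frame count")
    i_min = int(np.argmin(proj.values))  # argmin/argmax return first hit
    i_max = int(np.argmax(proj.values))
    sel = model.selection
    ref = sel.coords(model.reference.coords)

    def _aligned(i: int) -> Structure:
        fit = kabsch_fit(sel.coords(traj.frames[i]), ref)
        return traj.topology.with_coords(
            fit.apply(traj.frames[i]),
            title=f"frame {i} (t={traj.times[i]:g} ps)")

    return _aligned(i_min), _aligned(i_max), (float(proj.times[i_min]),
                                              float(proj.times[i_max]))


def save_modes_txt(model: PCAModel, path, n_modes: int = 10) -> None:
    """Write the leading modes as a plain-text matrix, one 3N row per mode.

    A header line records the eigenvalue (Å²) of each exported mode.
    """
    n_modes = min(n_modes, len(model.modes))
    header = "eigenvalues_A2: " + " ".join(
        f"{v:.6g}" for v in model.eigenvalues[:n_modes])
    np.savetxt(path, model.modes[:n_modes], header=header)


def interpolate_mode(model: PCAModel, mode: int, p_lo: float, p_hi: float,
                     n_inner: int = 8) -> Trajectory:
    """Structures at evenly spaced projections along a mode.

    ``n_inner + 2`` models from ``p_lo`` to ``p_hi``: coordinates are
    ``mean + p * mode`` on the model's selection atoms, returned as a
    multi-model trajectory ready for PDB export. With the default
    ``n_inner=8`` the endpoints plus 8 interpolated structures are produced.
    """
    if not 1 <= mode <= len(model.modes):
        raise ValueError(f"mode {mode} out of range")
    if p_lo >= p_hi:
        raise ValueError("p_lo must be < p_hi")
    if n_inner < 0:
        raise ValueError("n_inner must be >= 0")
    ps = np.linspace(p_lo, p_hi, n_inner + 2)
    v = model.modes[mode - 1]
    topo = model.reference.subset(model.selection.indices,
                                  title=f"mode {mode} interpolation")
    frames = np.stack([(model.mean + p * v).reshape(-1, 3) for p in ps])
    return Trajectory(topo, frames, np.arange(len(ps), dtype=float))
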