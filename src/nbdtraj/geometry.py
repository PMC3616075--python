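"""Rigid-body superposition, RMSD time series, and screw-axis decomposition.

A rigid motion ``x -> R x + t`` is characterised either as a least-squares
superposition (Kabsch) or, once obtained, as a *screw transform*: rotation
by an angle about an axis through a pivot point, plus a pitch translation
along that axis (Chasles' theorem). Axes and pivots are what hinge analysis
reports for each quasi-rigid domain.

All fits are unweighted over the supplied atoms (the analyses here use Cα
coordinates only).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError
from .io import Structure, Trajectory
from .scheme import AtomSelection

#: rotations smaller than this (degrees) have no well-conditioned axis
ANGLE_MIN_DEG = 1.0


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal proper rotation + translation of mobile onto target, and the
    residual RMSD (Å). ``apply`` maps mobile-frame coordinates onto the
    target frame: ``x -> R x + t``."""

    rotation: np.ndarray   # (3, 3), det = +1
    translation: np.ndarray  # (3,)
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


@dataclass(frozen=True)
class ScrewTransform:
    """Screw parameters of a rigid motion.

    ``angle_deg`` in [0, 180]; ``axis`` is a unit vector (meaningless when
    ``axis_defined`` is False, i.e. the rotation is below ``ANGLE_MIN_DEG``);
    ``pivot`` is the point of the axis line closest to the moving domain's
    geometric centre; ``pitch`` is the translation along the axis (Å);
    ``centre_displacement`` is how far the domain's geometric centre moved.
    """

    angle_deg: float
    axis: np.ndarray
    pivot: np.ndarray
    pitch: float
    centre_displacement: float
    axis_defined: bool = True


def kabsch_fit(mobile: np.ndarray, target: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Requires >= 3 non-collinear point pairs. The rotation is proper
    (det = +1); reflections are never returned.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(target, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError(f"point sets must share shape (n, 3); got {P.shape} vs {Q.shape}")
    n = P.shape[0]
    if n < 3:
        raise DegenerateGeometryError(f"need >= 3 points for a rigid fit, got {n}")
    pbar = P.mean(axis=0)
    qbar = Q.mean(axis=0)
    Pc = P - pbar
    Qc = Q - qbar
    # collinear point sets leave a rotation about the line undetermined
    sv = np.linalg.svd(Pc, compute_uv=False)
    if sv[1] <= 1e-8 * max(sv[0], 1.0):
        raise DegenerateGeometryError("mobile points are (nearly) collinear")
    H = Pc.T @ Qc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qbar - R @ pbar
    diff = Pc @ R.T + qbar - Q
    rmsd = float(np.sqrt((diff ** 2).sum() / n))
    return SuperpositionResult(R, t, rmsd)


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain (no-fit) RMSD between two matched coordinate sets."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.sqrt(((a - b) ** 2).sum(axis=-1).mean()))


def rmsd_series(traj: Trajectory, fit_sel: AtomSelection,
                calc_sel: AtomSelection, reference: Structure) -> np.ndarray:
    """Per-frame RMSD from a reference after superposition.

    Each frame is Kabsch-fitted onto the reference over ``fit_sel``; the
    RMSD is then evaluated over ``calc_sel``. With ``fit_sel == calc_sel``
    this is the ordinary fitted RMSD.
    """
    for sel in (fit_sel, calc_sel):
        if sel.index_array.max() >= traj.n_atoms or sel.index_array.max() >= reference.n_atoms:
            raise ValueError(f"selection {sel.label!r} exceeds atom count")
    ref_fit = fit_sel.coords(reference.coords)
    ref_calc = calc_sel.coords(reference.coords)
    out = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        frame = traj.frames[i]
        fit = kabsch_fit(fit_sel.coords(frame), ref_fit)
        out[i] = rmsd(fit.apply(calc_sel.coords(frame)), ref_calc)
    return out


def moving_average(series: np.ndarray, period: int) -> np.ndarray:
    """Trailing moving average: mean over each window of ``period`` samples.

    Output length is ``len(series) - period + 1``; sample ``i`` averages
    input samples ``i .. i+period-1``.
    """
    series = np.asarray(series, dtype=float)
    if period < 1:
        raise ValueError("period must be >= 1")
    if period > len(series):
        raise ValueError(f"period {period} exceeds series length {len(series)}")
    kernel = np.full(period, 1.0 / period)
    return np.convolve(series, kernel, mode="valid")


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix for a right-handed rotation about a unit axis."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    theta = np.deg2rad(angle_deg)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * (K @ K)


def screw_compose(angle_deg: float, axis: np.ndarray, pivot: np.ndarray,
                  pitch: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """(R, t) of the screw: rotate about ``axis`` through ``pivot``, then
    translate by ``pitch`` along the axis."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    pivot = np.asarray(pivot, dtype=float)
    R = rotation_about_axis(axis, angle_deg)
    t = pivot - R @ pivot + pitch * axis
    return R, t


def screw_decomposition(R: np.ndarray, t: np.ndarray,
                        domain_coords: np.ndarray,
                        angle_min_deg: float = ANGLE_MIN_DEG) -> ScrewTransform:
    """Decompose a rigid motion into screw parameters.

    The angle comes from the rotation trace; the axis from the antisymmetric
    part of R (or, near 180°, from the +1 eigenvector). The pivot solves
    ``(I - R) p = t - pitch * axis`` in the plane perpendicular to the axis
    and is then slid along the axis to the point nearest the domain's
    geometric centre, which makes the reported pivot unique. Rotations below
    ``angle_min_deg`` have no well-conditioned axis: the axis/pivot are
    flagged undefined while angle and centre displacement are still reported.
    """
    R = np.asarray(R, dtype=float)
    t = np.asarray(t, dtype=float)
    if not np.allclose(R @ R.T, np.eye(3), atol=1e-6) or np.linalg.det(R) < 0:
        raise ValueError("R must be a proper rotation matrix")
    centre = np.asarray(domain_coords, dtype=float).reshape(-1, 3).mean(axis=0)
    centre_displacement = float(np.linalg.norm(R @ centre + t - centre))

    cos_theta = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
    angle = float(np.rad2deg(np.arccos(cos_theta)))
    if angle < angle_min_deg:
        return ScrewTransform(angle, np.zeros(3), np.zeros(3), 0.0,
                              centre_displacement, axis_defined=False)

    if angle < 179.0:
        w = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
        axis = w / np.linalg.norm(w)
    else:
        # near 180° the antisymmetric part vanishes; use the +1 eigenvector
        vals, vecs = np.linalg.eigh((R + R.T) / 2.0)
        axis = vecs[:, np.argmax(vals)]
        axis = axis / np.linalg.norm(axis)
        # sign convention: largest-magnitude component positive
        k = int(np.argmax(np.abs(axis)))
        if axis[k] < 0:
            axis = -axis

    pitch = float(t @ axis)
    t_perp = t - pitch * axis
    # minimum-norm solution is perpendicular to the axis (null space of I - R)
    p0, *_ = np.linalg.lstsq(np.eye(3) - R, t_perp, rcond=None)
    pivot = p0 + ((centre - p0) @ axis) * axis
    return ScrewTransform(angle, axis, pivot, pitch, centre_displacement)


def axis_pseudoatoms(screw: ScrewTransform, half_length: float = 25.0,
                     chain_id: str = "X", residue_number: int = 1) -> Structure:
    """Two pseudo-atom endpoints of a hinge axis, for visualisation.

    Returns a 2-atom Structure (dummy residue ``AXS``) whose atoms sit at
    ``pivot ± half_length * axis``.
    """
    if not screw.axis_defined:
        raise ValueError("axis undefined for near-identity rotation")
    ends = np.stack([screw.pivot - half_length * screw.axis,
                     screw.pivot + half_length * screw.axis])
    return Structure(
        chain_ids=np.array([chain_id, chain_id]),
        residue_numbers=np.array([residue_number, residue_number]),
        residue_names=np.array(["AXS", "AXS"]),
        atom_names=np.array(["AX1", "AX2"]),
        elements=np.array(["X", "X"]),
        coords=ends,
        title=f"hinge axis, angle {screw.angle_deg:.1f} deg",
    )
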