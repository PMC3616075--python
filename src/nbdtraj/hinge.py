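"""Quasi-rigid-domain partitioning between two conformers and screw reports.

Given two conformations of the same molecule, residues are partitioned into
domains that each move as one rigid body between the conformers, plus an
unassigned remainder (hinges, flexible loops). Each domain's motion is then
characterised as a screw transform: rotation angle, hinge axis, pivot
point, pitch, and the displacement of the domain's geometric centre.

The partitioning is a deterministic greedy seeded-growth scheme:

1. globally superpose conformer y onto x over the analysed Cα selection and
   let D be the mean per-residue displacement that remains;
2. rank all windows of ``seed_length`` consecutive residues by their
   internal fit RMSD (most rigid first);
3. grow the best fully-unassigned seed to a fixed point: fit the current
   domain, admit unassigned residues whose post-fit displacement is at most
   ``tolerance * D``, drop members that exceed it;
4. keep the domain if it reaches ``min_domain_size``, else discard the
   seed; repeat until no seed qualifies.

The tolerance (default 0.4, i.e. 40%) is a fraction of D. There is no
randomness anywhere; ties break toward the lowest residue number. Domains
may be discontinuous in sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import SelectionError
from .geometry import ScrewTransform, kabsch_fit, screw_decomposition
from .io import Structure, Trajectory
from .scheme import AtomSelection

logger = logging.getLogger(__name__)

DEFAULT_TOLERANCE = 0.4
DEFAULT_SEED_LENGTH = 12
DEFAULT_MIN_DOMAIN_SIZE = 15
#: below this mean displacement (Å) the pair is treated as "all rigid"
RIGID_EPS = 1e-9


@dataclass(frozen=True)
class DomainPartition:
    """Residue partition of a conformer pair into quasi-rigid domains.

    ``domains`` holds per-domain residue identity lists ``[(chain, resnum),
    ...]`` in decreasing size order; ``unassigned`` the leftover residues.
    """

    domains: tuple[tuple[tuple[str, int], ...], ...]
    unassigned: tuple[tuple[str, int], ...]
    tolerance: float
    mean_displacement: float

    @property
    def n_domains(self) -> int:
        return len(self.domains)


@dataclass(frozen=True)
class DomainMotion:
    residues: tuple[tuple[str, int], ...]
    screw: ScrewTransform
    fit_rmsd: float


@dataclass(frozen=True)
class HingeReport:
    """One screw transform per rigid domain, plus the global-fit residual.

    ``anchor_index`` marks the static reference domain whose frame the
    screws are expressed in (-1 when the partition is empty).
    """

    motions: tuple[DomainMotion, ...]
    global_rmsd: float
    partition: DomainPartition
    anchor_index: int = 0

    def by_angle(self) -> tuple[DomainMotion, ...]:
        return tuple(sorted(self.motions, key=lambda m: -m.screw.angle_deg))


def _residue_keys(struct: Structure, sel: AtomSelection) -> list[tuple[str, int]]:
    return [(str(struct.chain_ids[i]), int(struct.residue_numbers[i]))
            for i in sel.indices]


def partition_rigid_domains(x: Structure, y: Structure, sel: AtomSelection,
                            tolerance: float = DEFAULT_TOLERANCE,
                            min_domain_size: int = DEFAULT_MIN_DOMAIN_SIZE,
                            seed_length: int = DEFAULT_SEED_LENGTH,
                            max_growth_iter: int = 50) -> DomainPartition:
    """Partition the selection's residues into quasi-rigid domains.

    ``sel`` must be a one-atom-per-residue (Cα) selection valid on both
    structures; ``tolerance`` is the admission threshold as a fraction of
    the global mean per-residue displacement.
    """
    if not 0 < tolerance <= 1:
        raise ValueError("tolerance must be in (0, 1]")
    n = len(sel)
    if n < min_domain_size:
        raise SelectionError(
            f"selection has {n} residues, fewer than min_domain_size={min_domain_size}")
    if x.n_atoms != y.n_atoms:
        raise SelectionError("structures have different atom counts")

    keys = _residue_keys(x, sel)
    X = sel.coords(x.coords)
    Y = sel.coords(y.coords)

    gfit = kabsch_fit(Y, X)
    Yg = gfit.apply(Y)
    disp = np.linalg.norm(Yg - X, axis=1)
    D = float(disp.mean())
    if D < RIGID_EPS:
        return DomainPartition((tuple(keys),), (), tolerance, D)
    thresh = tolerance * D

    # seed windows of consecutive residues within one chain, ranked by how
    # rigidly the window itself moves between the conformers
    chains = [k[0] for k in keys]
    seeds: list[tuple[float, int]] = []
    for start in range(n - seed_length + 1):
        window = list(range(start, start + seed_length))
        if len({chains[i] for i in window}) > 1:
            continue
        r = kabsch_fit(Y[window], X[window]).rmsd
        seeds.append((r, start))
    seeds.sort()  # ascending rmsd, then lowest start index

    assigned = np.zeros(n, dtype=bool)
    domains: list[list[int]] = []
    for _, start in seeds:
        window = list(range(start, start + seed_length))
        if assigned[window].any():
            continue
        members = set(window)
        for _ in range(max_growth_iter):
            idx = sorted(members)
            if len(idx) < 3:
                break
            fit = kabsch_fit(Y[idx], X[idx])
            d_all = np.linalg.norm(fit.apply(Y) - X, axis=1)
            new_members = {i for i in range(n)
                           if d_all[i] <= thresh and (not assigned[i] or i in members)}
            if new_members == members:
                break
            members = new_members
        if len(members) >= min_domain_size:
            idx = sorted(members)
            assigned[idx] = True
            domains.append(idx)

    domains.sort(key=lambda d: (-len(d), d[0]))
    unassigned = [i for i in range(n) if not assigned[i]]
    return DomainPartition(
        tuple(tuple(keys[i] for i in d) for d in domains),
        tuple(keys[i] for i in unassigned),
        tolerance, D)


def hinge_report(x: Structure, y: Structure, sel: AtomSelection,
                 partition: DomainPartition) -> HingeReport:
    """Screw transform of each rotating domain relative to a static reference.

    The reference (anchor) domain is the one that moves least between the
    globally superposed conformers (smallest rotation angle; ties resolve
    to the largest domain, then the lowest first residue). The pair is then
    superposed over the anchor alone, and every domain's motion x -> y is
    fitted and decomposed into a screw in that frame — so a two-body hinge
    reports its full relative angle on the moving arm while the reference
    reports its (near-zero) residual. The domain geometric centre (pivot
    anchoring, centre displacement) is taken in x.
    """
    keys = _residue_keys(x, sel)
    pos = {k: i for i, k in enumerate(keys)}
    X = sel.coords(x.coords)
    Y = sel.coords(y.coords)
    gfit = kabsch_fit(Y, X)
    if not partition.domains:
        return HingeReport((), gfit.rmsd, partition, anchor_index=-1)
    for residues in partition.domains:
        if not residues:
            raise ValueError("empty domain in partition")
    idx_sets = [[pos[k] for k in residues] for residues in partition.domains]

    # anchor = least-rotating domain in the global frame
    Yg = gfit.apply(Y)
    candidates = []
    for j, idx in enumerate(idx_sets):
        fit = kabsch_fit(X[idx], Yg[idx])
        screw = screw_decomposition(fit.rotation, fit.translation, X[idx])
        candidates.append((screw.angle_deg, -len(idx), partition.domains[j][0], j))
    anchor_index = min(candidates)[3]

    afit = kabsch_fit(Y[idx_sets[anchor_index]], X[idx_sets[anchor_index]])
    Ya = afit.apply(Y)
    motions = []
    for residues, idx in zip(partition.domains, idx_sets):
        fit = kabsch_fit(X[idx], Ya[idx])  # motion of the domain x -> y
        screw = screw_decomposition(fit.rotation, fit.translation, X[idx])
        motions.append(DomainMotion(residues, screw, fit.rmsd))
    return HingeReport(tuple(motions), gfit.rmsd, partition, anchor_index)


def analyse_conformer_pair(x: Structure, y: Structure, sel: AtomSelection,
                           tolerance: float = DEFAULT_TOLERANCE,
                           min_domain_size: int = DEFAULT_MIN_DOMAIN_SIZE
                           ) -> HingeReport:
    """Convenience: partition then report in one call."""
    part = partition_rigid_domains(x, y, sel, tolerance, min_domain_size)
    return hinge_report(x, y, sel, part)


def analyse_mode_extremes(traj: Trajectory, model, mode: int = 1,
                          tolerance: float = DEFAULT_TOLERANCE,
                          min_domain_size: int = DEFAULT_MIN_DOMAIN_SIZE
                          ) -> HingeReport:
    """Hinge analysis between the min- and max-projection structures of a mode.

    The minimum-projection structure is the reference (x); a zero-variance
    trajectory degenerates to an identity pair and a single rigid domain.
    """
    from .pca import extreme_frames, project  # local import to avoid a cycle

    proj = project(traj, model, mode)
    lo, hi, _ = extreme_frames(proj, traj, model)
    return analyse_conformer_pair(lo, hi, model.selection,
                                  tolerance, min_domain_size)


def report_to_dict(report: HingeReport) -> dict:
    """JSON-ready representation of a hinge report."""
    return {
        "global_rmsd": report.global_rmsd,
        "anchor_index": report.anchor_index,
        "tolerance": report.partition.tolerance,
        "mean_displacement": report.partition.mean_displacement,
        "unassigned": [list(k) for k in report.partition.unassigned],
        "domains": [
            {
                "residues": [list(k) for k in m.residues],
                "n_residues": len(m.residues),
                "angle_deg": m.screw.angle_deg,
                "axis": m.screw.axis.tolist() if m.screw.axis_defined else None,
                "pivot": m.screw.pivot.tolist() if m.screw.axis_defined else None,
                "pitch": m.screw.pitch if m.screw.axis_defined else None,
                "centre_displacement": m.screw.centre_displacement,
                "fit_rmsd": m.fit_rmsd,
            }
            for m in report.motions
        ],
    }
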