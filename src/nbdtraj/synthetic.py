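"""Synthetic NBD-dimer structures and trajectories with known ground truth.

The generator emulates the statistical structure the downstream analyses
assume: a two-chain Cα dimer, each chain split into a core and a helical
block, whose chain-B core rotates outward about a prescribed hinge axis
over time, under iid Gaussian coordinate noise. Every planted quantity
(axis, pivot, per-frame angle, analytic opening distance) is returned as
ground truth, so RMSD, opening-distance, PCA and hinge results can all be
checked against closed forms without any external data.

Geometry is Cα-only; a few explicitly named pseudo-atoms (nucleotide
β-phosphate oxygens, a Pi group, the C-motif serine OG, the D-loop backbone
carbonyl O) are planted at configured offsets so the contact-distance
observables exercise their real selection logic. The toy dimer is built
with an exact two-fold symmetry (chain B is a 180° rotation of chain A), so
the two composite active sites start at identical opening distances.

All randomness flows from a single integer seed; regeneration with the same
seed is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import rotation_about_axis, screw_compose
from .io import Structure, Trajectory
from .scheme import ResidueScheme

#: frame spacing used for generated trajectories (ps)
FRAME_INTERVAL_PS = 7.5

_WALKER_A_NAMES = {43: "GLY", 44: "LYS", 45: "SER", 46: "THR"}
_C_MOTIF_NAMES = {147: "SER", 148: "GLY", 149: "GLY", 150: "GLN"}


@dataclass(frozen=True)
class SyntheticGroundTruth:
    """Everything planted into a generated trajectory or conformer pair."""

    hinge_axis: np.ndarray                  # unit 3-vector
    pivot: np.ndarray                       # Å
    angle_schedule: np.ndarray              # per-frame degrees
    moving_residues: tuple[tuple[str, int], ...]
    noise_sigma: float
    seed: int
    expected_opening: np.ndarray            # per-frame Å, analytic
    screws: tuple = ()                      # for rigid pairs: planted screws


def _two_fold(coords: np.ndarray) -> np.ndarray:
    """The dimer's exact C2: 180° about the y-parallel axis through (0,0,5)."""
    out = np.array(coords, dtype=float, copy=True)
    out[..., 0] *= -1
    out[..., 2] = 10.0 - out[..., 2]
    return out


def _monomer_coords(core_len: int, helical_len: int) -> dict[int, np.ndarray]:
    """Cα positions of one monomer, keyed by residue number.

    Core residues lie on a compact solenoid left of the origin, helical
    residues on one to the right; the Walker A (43-46) and C-motif
    (147-150) Cα are placed explicitly on the interface-facing face.
    """
    if core_len < 46 or helical_len < 57:
        raise ValueError(
            "core_len must reach the Walker A motif (>=46) and helical_len "
            "the C-motif (>=57 so residue 150 exists)")
    if core_len > 155 or helical_len > 68:
        raise ValueError("core_len <= 155 and helical_len <= 68 required by the "
                         "default residue numbering")
    pos: dict[int, np.ndarray] = {}

    core_res = list(range(1, min(core_len, 90) + 1))
    if core_len > 90:
        core_res += list(range(164, 164 + core_len - 90))
    for j, r in enumerate(core_res):
        pos[r] = np.array([
            -10.0 + 9.0 * np.cos(0.5 * j),
            9.0 * np.sin(0.5 * j),
            -8.0 + 5.0 * np.sin(0.13 * j),
        ])
    helical_res = list(range(94, 94 + helical_len))
    for j, r in enumerate(helical_res):
        pos[r] = np.array([
            12.0 + 7.0 * np.cos(0.55 * j),
            7.0 * np.sin(0.55 * j),
            -8.0 + 5.0 * np.cos(0.17 * j),
        ])
    # Q-loop bridges core part 1 to the helical block
    a, b = pos[core_res[min(89, len(core_res) - 1)]], pos[94]
    for k, r in enumerate((91, 92, 93), start=1):
        pos[r] = a + (b - a) * k / 4.0
    # Pro-loop bridges the helical block to core part 2 (if present)
    if 164 in pos:
        a, b = pos[helical_res[-1]], pos[164]
        for k, r in enumerate((162, 163), start=1):
            pos[r] = a + (b - a) * k / 3.0
        if 161 not in pos:  # short helical block: keep 161 for the Pro-loop
            pos[161] = a + (b - a) / 6.0
    # unstructured C-terminal tail
    last = max(pos)
    d = np.array([0.0, -1.0, -0.5])
    d /= np.linalg.norm(d)
    for k, r in enumerate(range(229, 236), start=1):
        pos[r] = pos[last] + 3.8 * k * d
    # motif Cα on the interface-facing (high-z) face of each lobe
    for j, r in enumerate(range(43, 47)):
        pos[r] = np.array([-6.0 + 1.5 * j, 0.0, -2.5])
    for j, r in enumerate(range(147, 151)):
        pos[r] = np.array([8.0 + 1.5 * j, 0.0, -2.5])
    return pos


def _residue_name(r: int) -> str:
    return _WALKER_A_NAMES.get(r) or _C_MOTIF_NAMES.get(r) or \
        ("ALA" if r == 175 else "GLY")


def build_toy_dimer(core_len: int = 155, helical_len: int = 68,
                    with_ligand: bool = True) -> Structure:
    """Two-chain Cα toy NBD dimer on the default residue numbering.

    Chain B is an exact 180° rotation of chain A, so both composite
    active-site distances are equal at build time. With ``with_ligand``,
    pseudo-atoms for a bound nucleotide (β-phosphate oxygens), a Pi group,
    the chain-B C-motif serine OG (planted 3.0 Å from the nearest
    β-phosphate oxygen) and the chain-B D-loop carbonyl O (planted 2.7 Å
    from the nearest Pi oxygen — the crystal-contact geometry of the real
    starting structure) are included. All pseudo-atom geometry is synthetic.
    """
    mono = _monomer_coords(core_len, helical_len)
    residues = sorted(mono)

    chain_ids, res_nums, res_names, atom_names, elements, coords = \
        [], [], [], [], [], []

    def add(chain: str, rnum: int, rname: str, aname: str, element: str,
            xyz: np.ndarray) -> None:
        chain_ids.append(chain)
        res_nums.append(rnum)
        res_names.append(rname)
        atom_names.append(aname)
        elements.append(element)
        coords.append(np.asarray(xyz, dtype=float))

    for r in residues:
        add("A", r, _residue_name(r), "CA", "C", mono[r])

    # ligand pseudo-atoms sit in chain A's active site, which chain B's
    # C-motif and D-loop reach across the interface
    lig: list[tuple[int, str, str, str, np.ndarray]] = []
    b_extra: list[tuple[int, str, str, str, np.ndarray]] = []
    if with_ligand:
        wa_a = np.mean([mono[r] for r in range(43, 47)], axis=0)
        cm_b = _two_fold(np.mean([mono[r] for r in range(147, 151)], axis=0))
        m = wa_a + 0.5 * (cm_b - wa_a)  # site midpoint
        pb = m
        o1b, o2b, o3b = (m + np.array([1.5, 0.0, 0.0]),
                         m + np.array([-0.75, 1.3, 0.0]),
                         m + np.array([-0.75, -1.3, 0.0]))
        lig += [(301, "ADP", "PB", "P", pb), (301, "ADP", "O1B", "O", o1b),
                (301, "ADP", "O2B", "O", o2b), (301, "ADP", "O3B", "O", o3b)]
        p = m + np.array([0.0, 0.0, 2.5])
        pi_ox = [p + np.array(v) for v in
                 ([1.5, 0, 0], [-1.5, 0, 0], [0, 1.5, 0], [0, 0, -1.5])]
        lig += [(302, "PO4", "P", "P", p)]
        lig += [(302, "PO4", f"O{k}", "O", q) for k, q in enumerate(pi_ox, 1)]

        # chain-B serine OG: exactly 3.0 Å from O2B, pointing back at its CA
        ca_b147 = _two_fold(mono[147])
        u = ca_b147 - o2b
        og = o2b + 3.0 * u / np.linalg.norm(u)
        b_extra.append((147, "SER", "OG", "O", og))
        # chain-B D-loop A175 carbonyl O: exactly 2.7 Å from the nearest Pi O
        ca_b175 = _two_fold(mono[175])
        j = int(np.argmin([np.linalg.norm(ca_b175 - q) for q in pi_ox]))
        u = ca_b175 - pi_ox[j]
        o_175 = pi_ox[j] + 2.7 * u / np.linalg.norm(u)
        b_extra.append((175, "ALA", "O", "O", o_175))

    for rnum, rname, aname, element, xyz in lig:
        add("A", rnum, rname, aname, element, xyz)

    extra_by_res: dict[int, list] = {}
    for rec in b_extra:
        extra_by_res.setdefault(rec[0], []).append(rec)
    for r in residues:
        add("B", r, _residue_name(r), "CA", "C", _two_fold(mono[r]))
        for rnum, rname, aname, element, xyz in extra_by_res.get(r, ()):
            add("B", rnum, rname, aname, element, xyz)

    return Structure(np.array(chain_ids), np.array(res_nums),
                     np.array(res_names), np.array(atom_names),
                     np.array(elements), np.stack(coords),
                     title="synthetic toy NBD dimer")


def build_hinge_chain(n_fixed: int = 60, n_moving: int = 60,
                      elbow_angle_deg: float = 50.0
                      ) -> tuple[Structure, np.ndarray, np.ndarray]:
    """Single-chain elbow fixture for hinge analysis: two arms, one pivot.

    Residues ``1..n_fixed`` run along one arm towards the elbow at the
    origin, ``n_fixed+1..n_fixed+n_moving`` along the second arm; both arms
    carry a helical wiggle so neither is collinear. Returns the structure,
    the pivot (the elbow) and the natural hinge axis (z, perpendicular to
    both arm directions) about which the second arm can be rotated with
    :func:`generate_rigid_pair`.
    """
    if n_fixed < 20 or n_moving < 20:
        raise ValueError("each arm needs >= 20 residues")
    alpha = np.deg2rad(elbow_angle_deg)
    u1 = np.array([-1.0, 0.0, 0.0])
    u2 = np.array([np.cos(alpha), np.sin(alpha), 0.0])
    # both arms start 12 Å from the hinge axis so no residue sits inside the
    # near-axis band where domain membership is geometrically ambiguous
    coords = []
    for i in range(1, n_fixed + 1):
        j = n_fixed - i  # residue n_fixed sits nearest the elbow
        coords.append(u1 * (12.0 + 1.0 * j)
                      + 4.0 * np.array([0.0, np.cos(0.7 * j), np.sin(0.7 * j)]))
    for k in range(n_moving):
        coords.append(u2 * (12.0 + 1.0 * k)
                      + 4.0 * np.array([0.0, np.sin(0.7 * k) * np.sin(alpha),
                                        np.cos(0.7 * k)]))
    n = n_fixed + n_moving
    struct = Structure(
        chain_ids=np.array(["A"] * n),
        residue_numbers=np.arange(1, n + 1),
        residue_names=np.array(["GLY"] * n),
        atom_names=np.array(["CA"] * n),
        elements=np.array(["C"] * n),
        coords=np.stack(coords),
        title="synthetic hinge elbow chain")
    return struct, np.zeros(3), np.array([0.0, 0.0, 1.0])


def _moving_mask(dimer: Structure, chain: str, residues: set[int]) -> np.ndarray:
    return ((dimer.chain_ids.astype(str) == chain)
            & np.isin(dimer.residue_numbers.astype(int), sorted(residues)))


def _angle_schedule(theta_max: float, n_frames: int, schedule: str) -> np.ndarray:
    u = np.linspace(0.0, 1.0, n_frames)
    if schedule == "linear":
        s = u
    elif schedule == "sigmoid":
        raw = 1.0 / (1.0 + np.exp(-10.0 * (u - 0.5)))
        s = (raw - raw[0]) / (raw[-1] - raw[0])
    else:
        raise ValueError(f"unknown schedule {schedule!r} (use 'linear' or 'sigmoid')")
    return theta_max * s


def generate_opening_trajectory(dimer: Structure, theta_max: float = 20.0,
                                n_frames: int = 500, noise_sigma: float = 0.2,
                                schedule: str = "linear", seed: int = 0,
                                scheme: ResidueScheme | None = None
                                ) -> tuple[Trajectory, SyntheticGroundTruth]:
    """Trajectory in which the apo monomer's core rotates the empty site open.

    Frame t rotates the chain-B core block (all its atoms, pseudo-atoms
    included) by θ(t) about a hinge axis through a pivot at the core/helical
    junction; iid Gaussian noise of ``noise_sigma`` Å is added to every atom
    of every frame. The analytic opening distance of the empty site (the
    noise-free rotated Walker A centroid to the static opposing C-motif
    centroid) is recorded per frame. The axis sign is chosen so the site
    opens (distance grows) from frame 0.
    """
    if not 0.0 < theta_max <= 60.0:
        raise ValueError("theta_max must be in (0, 60] degrees")
    if n_frames < 50:
        raise ValueError("n_frames must be >= 50")
    scheme = scheme or ResidueScheme()
    chain = scheme.apo_monomer
    core_set = set(scheme.residues("core"))
    mask = _moving_mask(dimer, chain, core_set)
    if not mask.any():
        raise ValueError(f"no atoms in the moving block (chain {chain} core)")

    ca = (dimer.atom_names.astype(str) == "CA") & (dimer.chain_ids.astype(str) == chain)
    res = dimer.residue_numbers.astype(int)

    def _ca_of(r: int) -> np.ndarray:
        idx = np.flatnonzero(ca & (res == r))
        if len(idx) == 0:
            raise ValueError(f"residue {r} missing from chain {chain}")
        return dimer.coords[idx[0]]

    # pivot at the core/helical junction, axis along the dimer two-fold (y)
    helical_start = scheme.helical_domain[0][0]
    below = [hi for lo, hi in scheme.core if hi < helical_start]
    core_edge = max(below) if below else scheme.core[0][1]
    pivot = 0.5 * (_ca_of(core_edge) + _ca_of(helical_start))
    axis = np.array([0.0, 1.0, 0.0])

    # the empty site: this chain's Walker A vs the opposite chain's C-motif
    wa_idx = np.flatnonzero(ca & np.isin(res, scheme.residues("walker_a_centre")))
    other = scheme.nucleotide_monomer
    cm_mask = ((dimer.chain_ids.astype(str) == other)
               & (dimer.atom_names.astype(str) == "CA")
               & np.isin(res, scheme.residues("c_motif_centre")))
    wa_centroid = dimer.coords[wa_idx].mean(axis=0)
    cm_centroid = dimer.coords[np.flatnonzero(cm_mask)].mean(axis=0)

    # orient the axis so the initial tangential motion opens the site
    tangent = np.cross(axis, wa_centroid - pivot)
    if tangent @ (wa_centroid - cm_centroid) < 0:
        axis = -axis

    angles = _angle_schedule(theta_max, n_frames, schedule)
    rng = np.random.default_rng(seed)
    frames = np.empty((n_frames, dimer.n_atoms, 3))
    expected = np.empty(n_frames)
    for i, theta in enumerate(angles):
        R = rotation_about_axis(axis, theta)
        coords = dimer.coords.copy()
        coords[mask] = (coords[mask] - pivot) @ R.T + pivot
        expected[i] = np.linalg.norm((wa_centroid - pivot) @ R.T + pivot
                                     - cm_centroid)
        if noise_sigma > 0:
            coords += rng.normal(0.0, noise_sigma, coords.shape)
        frames[i] = coords

    times = np.arange(n_frames) * FRAME_INTERVAL_PS
    truth = SyntheticGroundTruth(
        hinge_axis=axis, pivot=pivot, angle_schedule=angles,
        moving_residues=tuple((chain, int(r))
                              for r in sorted(set(res[mask].tolist()))),
        noise_sigma=noise_sigma, seed=seed, expected_opening=expected)
    return Trajectory(dimer, frames, times), truth


def generate_control_trajectory(dimer: Structure, n_frames: int = 500,
                                noise_sigma: float = 0.2, seed: int = 0
                                ) -> tuple[Trajectory, SyntheticGroundTruth]:
    """A "closed" control run: pure coordinate noise, no planted motion.

    The stability counterpart to :func:`generate_opening_trajectory` — both
    active sites stay at their starting distance up to noise, so its PCA
    modes are noise modes with no preferred collective direction.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    rng = np.random.default_rng(seed)
    frames = (dimer.coords[None] +
              rng.normal(0.0, noise_sigma, (n_frames, dimer.n_atoms, 3)))
    times = np.arange(n_frames) * FRAME_INTERVAL_PS
    truth = SyntheticGroundTruth(
        hinge_axis=np.zeros(3), pivot=np.zeros(3),
        angle_schedule=np.zeros(n_frames), moving_residues=(),
        noise_sigma=noise_sigma, seed=seed,
        expected_opening=np.full(n_frames, np.nan))
    return Trajectory(dimer, frames, times), truth


def generate_rigid_pair(dimer: Structure,
                        rotations: list[tuple[str, set[int], np.ndarray,
                                              float, np.ndarray]],
                        noise_sigma: float = 0.0, seed: int = 0
                        ) -> tuple[Structure, Structure, SyntheticGroundTruth]:
    """A conformer pair in which listed residue blocks move as rigid bodies.

    ``rotations`` is a list of ``(chain, residue_set, axis, angle_deg,
    pivot)``; blocks must not overlap. The second conformer applies each
    rotation; independent Gaussian noise (if any) is added to both
    conformers. Planted screws are recorded in the ground truth.
    """
    masks = []
    for chain, residues, axis, angle, pivot in rotations:
        masks.append(_moving_mask(dimer, chain, set(residues)))
    for i in range(len(masks)):
        for j in range(i + 1, len(masks)):
            if (masks[i] & masks[j]).any():
                raise ValueError(f"rotation blocks {i} and {j} overlap")

    y = dimer.coords.copy()
    screws = []
    for (chain, residues, axis, angle, pivot), mask in zip(rotations, masks):
        axis = np.asarray(axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        pivot = np.asarray(pivot, dtype=float)
        R, t = screw_compose(angle, axis, pivot)
        y[mask] = y[mask] @ R.T + t
        screws.append((chain, tuple(sorted(residues)), axis, float(angle), pivot))

    rng = np.random.default_rng(seed)
    xc = dimer.coords.copy()
    if noise_sigma > 0:
        xc = xc + rng.normal(0.0, noise_sigma, xc.shape)
        y = y + rng.normal(0.0, noise_sigma, y.shape)
    x = dimer.with_coords(xc, title="rigid pair, conformer x")
    moving = tuple((chain, int(r)) for chain, residues, *_ in rotations
                   for r in sorted(residues))
    truth = SyntheticGroundTruth(
        hinge_axis=screws[0][2] if screws else np.zeros(3),
        pivot=screws[0][4] if screws else np.zeros(3),
        angle_schedule=np.array([s[3] for s in screws]),
        moving_residues=moving, noise_sigma=noise_sigma, seed=seed,
        expected_opening=np.empty(0), screws=tuple(screws))
    return x, dimer.with_coords(y, title="rigid pair, conformer y"), truth


def ground_truth_to_dict(truth: SyntheticGroundTruth) -> dict:
    """JSON-ready sidecar representation of the planted ground truth."""
    return {
        "hinge_axis": truth.hinge_axis.tolist(),
        "pivot": truth.pivot.tolist(),
        "angle_schedule_deg": truth.angle_schedule.tolist(),
        "moving_residues": [list(k) for k in truth.moving_residues],
        "noise_sigma": truth.noise_sigma,
        "seed": truth.seed,
        "expected_opening": truth.expected_opening.tolist(),
        "screws": [
            {"chain": c, "residues": list(rs), "axis": a.tolist(),
             "angle_deg": ang, "pivot": p.tolist()}
            for c, rs, a, ang, p in truth.screws
        ],
    }
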