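"""Collective-variable time series over a trajectory.

Two kinds of observable are computed, both frame-internal (no superposition
is ever applied, so every series is invariant under global rigid motion):

* *opening distances* — the distance between the geometric centres (plain
  unweighted means) of the Cα atoms of a Walker A motif and the opposing
  monomer's C-motif, one series per composite active site. This is the gauge
  of active-site closure for a sandwich NBD dimer.
* *contact distances* — per-frame minimum distance between two atom groups,
  e.g. the C-motif serine hydroxyl oxygen versus the nucleotide β-phosphate
  oxygens, or a D-loop backbone carbonyl oxygen versus the Pi oxygens.
  "Proximal" partners are resolved as the per-frame minimum rather than a
  fixed atom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .errors import SelectionError
from .io import Structure, Trajectory
from .scheme import AtomSelection, ResidueScheme, paired_site_selections

logger = logging.getLogger(__name__)

#: PDB component atom-name synonyms for nucleotide β-phosphate oxygens
BETA_PHOSPHATE_OXYGENS = ("O1B", "O2B", "O3B")
#: residue names recognised as the bound nucleotide
NUCLEOTIDE_RESIDUES = ("ADP", "ATP", "ANP", "ADX")


@dataclass(frozen=True)
class DistanceSeries:
    label: str
    times: np.ndarray  # ps
    values: np.ndarray  # Å

    def __post_init__(self) -> None:
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have equal length")
        if len(self.values) and (np.asarray(self.values) < 0).any():
            raise ValueError("distances must be non-negative")


def _centroid_distance(frame: np.ndarray, a: AtomSelection, b: AtomSelection) -> float:
    return float(np.linalg.norm(a.coords(frame).mean(axis=0)
                                - b.coords(frame).mean(axis=0)))


def opening_distance_series(
    traj: Trajectory, scheme: ResidueScheme
) -> dict[str, DistanceSeries]:
    """Active-site opening distances, one series per composite site.

    ``site_nuc`` is the nucleotide-bound site (Walker A of the nucleotide
    monomer vs the apo monomer's C-motif); ``site_apo`` the empty one.
    """
    sites = paired_site_selections(traj.topology, scheme)
    out: dict[str, DistanceSeries] = {}
    for site, (wa, cm) in sites.items():
        values = np.array([_centroid_distance(traj.frames[i], wa, cm)
                           for i in range(traj.n_frames)])
        out[site] = DistanceSeries(site, traj.times, values)
    return out


def opening_distance(struct: Structure, scheme: ResidueScheme) -> dict[str, float]:
    """Single-structure version of :func:`opening_distance_series`."""
    sites = paired_site_selections(struct, scheme)
    return {site: _centroid_distance(struct.coords, wa, cm)
            for site, (wa, cm) in sites.items()}


def pair_min_distance_series(traj: Trajectory, sel_a: AtomSelection,
                             sel_b: AtomSelection,
                             label: str = "min_distance") -> DistanceSeries:
    """Per-frame minimum over all cross pairs of atom-atom distances."""
    if len(sel_a) == 0 or len(sel_b) == 0:
        raise SelectionError("both selections must be non-empty")
    values = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        frame = traj.frames[i]
        values[i] = cdist(sel_a.coords(frame), sel_b.coords(frame)).min()
    return DistanceSeries(label, traj.times, values)


def select_named_atoms(struct: Structure, *, chain: str | None = None,
                       residue_numbers: tuple[int, ...] | None = None,
                       residue_names: tuple[str, ...] | None = None,
                       atom_names: tuple[str, ...] | None = None,
                       label: str = "atoms") -> AtomSelection:
    """Select atoms by any combination of chain / residue / atom-name filters."""
    mask = np.ones(struct.n_atoms, dtype=bool)
    if chain is not None:
        mask &= struct.chain_ids.astype(str) == chain
    if residue_numbers is not None:
        mask &= np.isin(struct.residue_numbers.astype(int), residue_numbers)
    if residue_names is not None:
        mask &= np.isin(struct.residue_names.astype(str), residue_names)
    if atom_names is not None:
        mask &= np.isin(struct.atom_names.astype(str), atom_names)
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        raise SelectionError(
            f"{label}: no atoms match (chain={chain}, residues={residue_numbers}, "
            f"resnames={residue_names}, atoms={atom_names})")
    return AtomSelection(label, tuple(int(i) for i in idx))


def serine_phosphate_series(traj: Trajectory, scheme: ResidueScheme,
                            beta_oxygens: tuple[str, ...] = BETA_PHOSPHATE_OXYGENS
                            ) -> DistanceSeries:
    """C-motif serine OG to nearest nucleotide β-phosphate oxygen, per frame.

    The serine is the first residue of the C-motif on the apo monomer (the
    signature that engages the nucleotide bound to the opposite Walker A).
    """
    top = traj.topology
    serine_residue = scheme.residues("c_motif_centre")[0]
    try:
        og = select_named_atoms(top, chain=scheme.apo_monomer,
                                residue_numbers=(serine_residue,),
                                atom_names=("OG",), label="serine_OG")
    except SelectionError as exc:
        raise SelectionError(f"C-motif serine OG not found: {exc}") from exc
    try:
        phos = select_named_atoms(top, residue_names=NUCLEOTIDE_RESIDUES,
                                  atom_names=beta_oxygens, label="beta_phosphate_O")
    except SelectionError as exc:
        raise SelectionError(
            f"nucleotide β-phosphate oxygens {beta_oxygens} not found: {exc}"
        ) from exc
    series = pair_min_distance_series(traj, og, phos, label="serine_OG_betaP")
    return series


def dloop_pi_min_distance(struct: Structure, scheme: ResidueScheme,
                          pi_residue_names: tuple[str, ...] = ("PO4", "PI", "2HP")
                          ) -> tuple[float, str]:
    """Minimum distance from the trans D-loop backbone carbonyl O to a Pi oxygen.

    Returns the distance and the name of the Pi oxygen atom attaining it
    (the "proximal hydroxyl oxygen" is defined by this very proximity).
    The D-loop carbonyl belongs to the apo monomer, which reaches across the
    interface into the nucleotide-bound site.
    """
    o = select_named_atoms(struct, chain=scheme.apo_monomer,
                           residue_numbers=(scheme.d_loop_ref_residue,),
                           atom_names=("O",), label="dloop_carbonyl_O")
    pi = select_named_atoms(struct, residue_names=pi_residue_names,
                            label="pi_oxygens")
    # restrict the Pi residue to oxygen atoms
    ox = [i for i in pi.indices if str(struct.elements[i]).upper() == "O"
          or str(struct.atom_names[i]).startswith("O")]
    if not ox:
        raise SelectionError("Pi residue contains no oxygen atoms")
    pi = AtomSelection("pi_oxygens", tuple(ox))
    d = cdist(o.coords(struct.coords), pi.coords(struct.coords))
    j = int(np.argmin(d.min(axis=0)))
    chosen = str(struct.atom_names[pi.indices[j]])
    logger.info("proximal Pi oxygen resolved as %s at %.2f Å", chosen, d.min())
    return float(d.min()), chosen
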