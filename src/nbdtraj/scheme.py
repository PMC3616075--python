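"""Residue scheme for the NBD dimer and Cα atom selections.

The default numbering is for the MJ0796 NBD (228 structured residues plus a
short C-terminal tail). Each monomer splits into a RecA-like *core*
subdomain carrying the Walker A/B motifs and an ABC-specific *helical*
subdomain carrying the LSGGQ signature (C-motif); the Q-loop and Pro-loop
connecting them belong to neither. Two helical selections are exposed:

* ``helical_domain`` (94-161) — the full lobe, for rigid-domain/hinge work;
* ``helical_rmsd`` (94-111 ∪ 117-161) — excludes the mobile α3-4 loop
  (112-116), for RMSD series.

Likewise the core RMSD selection (1-90 ∪ 164-228) excludes the unstructured
C-terminal tail (229-235). All numbers are overridable so the toolkit
applies to other NBDs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import SelectionError
from .io import Structure

logger = logging.getLogger(__name__)

#: inclusive 1-based residue ranges
Ranges = tuple[tuple[int, int], ...]


def _expand(ranges: Ranges) -> list[int]:
    out: list[int] = []
    for lo, hi in ranges:
        if lo > hi:
            raise ValueError(f"malformed residue range {lo}-{hi}")
        out.extend(range(lo, hi + 1))
    return out


@dataclass(frozen=True)
class ResidueScheme:
    """Named residue ranges (per monomer) and the two chain identifiers."""

    core: Ranges = ((1, 90), (164, 228))
    helical_rmsd: Ranges = ((94, 111), (117, 161))
    helical_domain: Ranges = ((94, 161),)
    q_loop: Ranges = ((91, 93),)
    pro_loop: Ranges = ((161, 163),)
    a34_loop: Ranges = ((112, 116),)
    c_term_tail: Ranges = ((229, 235),)
    walker_a_centre: Ranges = ((43, 46),)
    c_motif_centre: Ranges = ((147, 150),)
    d_loop_ref_residue: int = 175
    nucleotide_monomer: str = "A"
    apo_monomer: str = "B"

    def __post_init__(self) -> None:
        for name in ("core", "helical_rmsd", "helical_domain", "q_loop",
                     "pro_loop", "a34_loop", "c_term_tail",
                     "walker_a_centre", "c_motif_centre"):
            _expand(getattr(self, name))  # validates lo <= hi
        core = set(_expand(self.core))
        if not set(_expand(self.walker_a_centre)) <= core:
            raise ValueError("walker_a_centre must lie within the core subdomain")
        helical = set(_expand(self.helical_domain))
        if not set(_expand(self.c_motif_centre)) <= helical:
            raise ValueError("c_motif_centre must lie within the helical subdomain")
        if set(_expand(self.a34_loop)) & set(_expand(self.helical_rmsd)):
            raise ValueError("helical_rmsd must exclude the a34_loop")
        if set(_expand(self.c_term_tail)) & core:
            raise ValueError("core must exclude the C-terminal tail")

    @property
    def chains(self) -> tuple[str, str]:
        return (self.nucleotide_monomer, self.apo_monomer)

    def residues(self, name: str) -> list[int]:
        """Expanded residue list for a named range set."""
        return _expand(getattr(self, name))


@dataclass(frozen=True)
class AtomSelection:
    """An ordered, duplicate-free set of atom indices into a Structure."""

    label: str
    indices: tuple[int, ...]

    def __post_init__(self) -> None:
        idx = self.indices
        if any(idx[i] >= idx[i + 1] for i in range(len(idx) - 1)):
            raise SelectionError(f"{self.label}: indices must be strictly ascending")
        if idx and idx[0] < 0:
            raise SelectionError(f"{self.label}: negative atom index")

    def __len__(self) -> int:
        return len(self.indices)

    @property
    def index_array(self) -> np.ndarray:
        return np.asarray(self.indices, dtype=int)

    def coords(self, coords: np.ndarray) -> np.ndarray:
        """Gather this selection from an (n_atoms, 3) coordinate array."""
        return np.asarray(coords)[self.index_array]


def select_calpha(struct: Structure, chain: str,
                  ranges: Ranges | Sequence[int],
                  label: str | None = None) -> AtomSelection:
    """CA atoms of the listed residues on one chain, in residue order.

    Residues absent from the structure are tolerated (their count is
    logged); an entirely empty selection or an absent chain is an error.
    """
    if chain not in set(str(c) for c in struct.chain_ids):
        raise SelectionError(f"chain {chain!r} not present in structure")
    if ranges and isinstance(ranges[0], (tuple, list)):
        wanted = _expand(tuple(tuple(r) for r in ranges))  # type: ignore[arg-type]
    else:
        wanted = [int(r) for r in ranges]  # explicit residue list
    on_chain = (struct.chain_ids.astype(str) == chain) & (struct.atom_names.astype(str) == "CA")
    by_residue = {int(r): i for i, r in enumerate(struct.residue_numbers) if on_chain[i]}
    indices = [by_residue[r] for r in wanted if r in by_residue]
    missing = sum(1 for r in wanted if r not in by_residue)
    if missing:
        logger.warning("chain %s: %d of %d requested residues missing from structure",
                       chain, missing, len(wanted))
    if not indices:
        raise SelectionError(f"empty CA selection for chain {chain!r}")
    # residue order == structure order for a sane PDB; enforce ascending indices
    indices = sorted(indices)
    return AtomSelection(label or f"CA:{chain}", tuple(indices))


def select_dimer_calpha(struct: Structure, scheme: ResidueScheme,
                        ranges: Ranges | None = None,
                        label: str = "CA:dimer") -> AtomSelection:
    """CA atoms of both chains, optionally restricted to residue ranges."""
    parts = []
    for chain in scheme.chains:
        if ranges is None:
            on_chain = ((struct.chain_ids.astype(str) == chain)
                        & (struct.atom_names.astype(str) == "CA"))
            parts.extend(np.flatnonzero(on_chain).tolist())
        else:
            parts.extend(select_calpha(struct, chain, ranges).indices)
    if not parts:
        raise SelectionError("empty dimer CA selection")
    return AtomSelection(label, tuple(sorted(parts)))


def paired_site_selections(
    struct: Structure, scheme: ResidueScheme
) -> dict[str, tuple[AtomSelection, AtomSelection]]:
    """The two composite active sites as (Walker A, trans C-motif) pairs.

    ``site_nuc`` pairs the nucleotide monomer's Walker A with the apo
    monomer's C-motif; ``site_apo`` is the mirror pairing. Each selection
    must resolve all four motif residues.
    """
    sites: dict[str, tuple[AtomSelection, AtomSelection]] = {}
    pairs = {
        "site_nuc": (scheme.nucleotide_monomer, scheme.apo_monomer),
        "site_apo": (scheme.apo_monomer, scheme.nucleotide_monomer),
    }
    n_wa = len(_expand(scheme.walker_a_centre))
    n_cm = len(_expand(scheme.c_motif_centre))
    for site, (wa_chain, cm_chain) in pairs.items():
        try:
            wa = select_calpha(struct, wa_chain, scheme.walker_a_centre,
                               label=f"{site}:walkerA:{wa_chain}")
            cm = select_calpha(struct, cm_chain, scheme.c_motif_centre,
                               label=f"{site}:cmotif:{cm_chain}")
        except SelectionError as exc:
            raise SelectionError(f"{site}: {exc}") from exc
        if len(wa) != n_wa or len(cm) != n_cm:
            raise SelectionError(
                f"{site}: incomplete motif (WalkerA {len(wa)}/{n_wa}, "
                f"C-motif {len(cm)}/{n_cm})")
        sites[site] = (wa, cm)
    return sites
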