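"""Shared fixtures: toy structures and trajectories with planted ground truth.

Expensive trajectory fixtures are session-scoped; every test that mutates
coordinates works on copies.
"""

from __future__ import annotations

import numpy as np
import pytest

import nbdtraj as nt
from nbdtraj.synthetic import build_hinge_chain, generate_control_trajectory


@pytest.fixture(scope="session")
def scheme() -> nt.ResidueScheme:
    return nt.ResidueScheme()


@pytest.fixture(scope="session")
def dimer() -> nt.Structure:
    return nt.build_toy_dimer()


@pytest.fixture(scope="session")
def dimer_bare() -> nt.Structure:
    """Toy dimer without ligand pseudo-atoms (Cα only)."""
    return nt.build_toy_dimer(with_ligand=False)


@pytest.fixture(scope="session")
def opening_run(dimer) -> tuple[nt.Trajectory, object]:
    """The standard opening study condition: 20° over 500 frames, σ=0.2 Å."""
    return nt.generate_opening_trajectory(
        dimer, theta_max=20.0, n_frames=500, noise_sigma=0.2, seed=11)


@pytest.fixture(scope="session")
def control_run(dimer) -> tuple[nt.Trajectory, object]:
    """No-motion control at the same noise level."""
    return generate_control_trajectory(dimer, n_frames=500, noise_sigma=0.2,
                                       seed=13)


@pytest.fixture(scope="session")
def dimer_ca_selection(dimer, scheme) -> nt.AtomSelection:
    return nt.select_dimer_calpha(dimer, scheme)


@pytest.fixture(scope="session")
def opening_model(opening_run, dimer, dimer_ca_selection) -> nt.PCAModel:
    traj, _ = opening_run
    return nt.fit_pca(traj, dimer_ca_selection, dimer, source_label="open-1")


@pytest.fixture(scope="session")
def hinge_pair():
    """Noise-free two-body 20° hinge pair with its planted geometry."""
    chain, pivot, axis = build_hinge_chain()
    moving = set(range(61, 121))
    x, y, truth = nt.generate_rigid_pair(
        chain, [("A", moving, axis, 20.0, pivot)])
    sel = nt.select_calpha(chain, "A", ((1, 120),))
    return {"chain": chain, "pivot": pivot, "axis": axis, "moving": moving,
            "x": x, "y": y, "sel": sel, "truth": truth}
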