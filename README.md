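# nbdtraj

Trajectory analysis for ABC-transporter nucleotide-binding-domain (NBD)
dimers: subdomain-resolved RMSD, active-site opening distances,
essential-dynamics PCA with cross-run projection and subspace overlap, and
rigid-domain / screw-axis hinge decomposition — plus a synthetic-trajectory
generator with analytic ground truth so the whole battery can be validated
end to end without any external data.

## Who this is for

ABC transporters hydrolyse ATP at two composite sites buried in the
interface of an NBD "sandwich" dimer: the LSGGQ signature (C-motif) of one
monomer engages the nucleotide bound to the Walker A/B motifs of the other.
Each NBD splits into a RecA-like **core** subdomain and an ABC-specific
**helical** subdomain, and relative rotations between them are how the
dimer opens one site while keeping the other occluded. This package is for
structural biophysicists who have MD trajectories of such a dimer (or any
two-lobe, two-chain system) and want the standard collective-motion
analysis battery as a tested, scriptable library.

## What it computes

With frames `x(t)` least-squares superposed (Kabsch) onto a reference:

- **RMSD series** per selection, with self-fit per monomer/subdomain and a
  trailing moving average (default period 20).
- **Opening distance** per composite site: the distance between the
  geometric centres of the Cα atoms of a Walker A motif (residues 43–46,
  GKST, in the default MJ0796 numbering) and the opposing monomer's C-motif
  (147–150, SGGQ) — the per-site gauge of active-site closure.
- **Essential dynamics**: the covariance `C = ⟨(x−⟨x⟩)(x−⟨x⟩)ᵀ⟩` of the
  aligned 3N Cα coordinates, its eigenmodes `v_i` and eigenvalue fractions
  `λ_i/Σλ`; projections `p_i(t) = v_i·(x(t)−⟨x⟩)` in Å, also onto modes
  fitted on a *different* run (cross-projection); the subspace overlap
  `√(Σ_{j≤k}(v·u_j)²)` of a mode with another model's leading k modes; and
  structures interpolated along a mode between its projection extremes.
- **Hinge decomposition**: residues partitioned into quasi-rigid domains
  between two conformers (deterministic seeded growth, admission threshold
  = tolerance × mean per-residue displacement, default 40%), then each
  domain's motion relative to the most static domain expressed as a screw:
  rotation angle about a hinge axis through a pivot, pitch along the axis,
  and the displacement of the domain's geometric centre.

Default residue scheme (MJ0796 numbering, overridable): core = 1–90 ∪
164–228, helical = 94–161 (94–111 ∪ 117–161 for RMSD, excluding the mobile
α3-4 loop 112–116), Q-loop 91–93 and Pro-loop 161–163 assigned to neither,
C-terminal tail 229–235 excluded from the core RMSD.

## Worked example

```sh
python examples/02_essential_dynamics.py
```

builds the toy dimer, plants a 20° outward rotation of the apo monomer's
core subdomain over 500 frames with 0.2 Å coordinate noise, and prints:

```
eigenvalue fractions of the first three modes: 85.0%, 0.1%, 0.1%
(a single dominant mode means one collective motion carries most of the fluctuation)
Pearson r between the PC1 projection and the empty-site opening distance: 0.991
(|r| near 1: PC1 is the global motion by which the empty site opens)
projection extremes at t = 7.5 ps and t = 3742.5 ps
wrote mode1_interpolation.pdb (10 models along PC1) and modes.txt
```

The first line says 85% of all Cα fluctuation lives in one collective mode;
the second that this mode *is* the opening of the empty active site (the
planted motion). The other examples cover the RMSD/opening panels (`01`),
hinge analysis (`03`, which recovers the planted 20.000° rotation and its
axis), active-site contact distances (`04`, including the 2.7 Å D-loop
carbonyl-O⋯Pi hydrogen-bond geometry), and the full config-driven pipeline
with an opening run versus a no-motion control (`05`).

A thin CLI wraps the same calls:

```sh
nbdtraj simulate --out-prefix run --n-frames 500 --seed 1
nbdtraj analyze --config config.yaml --output-dir out
nbdtraj hinge --topology run_topology.pdb --trajectory run.dcd --out hinge.json
```

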