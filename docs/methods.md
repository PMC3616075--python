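# Methods

This note records the models and procedures the package implements, the
parameters that matter, what the synthetic generator does and does not
emulate, and the numerical and design choices made where more than one
convention exists.

## Superposition and RMSD

All fits are unweighted least-squares rigid superpositions of Cα
coordinates (Kabsch, via SVD of the cross-covariance with the determinant
correction, so reflections are never returned). Point sets with fewer than
three points, or whose second singular value is below 1e-8 of the first
(collinear), raise a degenerate-geometry error rather than returning an
arbitrary rotation.

RMSD series fit each frame on a *fit selection* and evaluate on a *calc
selection*; per-monomer and per-subdomain series use self-fit (fit and
evaluate on the same selection), which measures internal deformation only —
the quantity that distinguishes "the monomers are internally stable" from
"the dimer rearranges". Dimer-wide RMSD fits on all Cα.

The RMSD moving average is a trailing window (output sample *i* averages
input samples *i* … *i+period−1*), period 20 by default. Nothing in the
analyses depends on the centring convention; trailing is the common
spreadsheet one and keeps the output causal.

## Time axis

Frame times are never trusted from DCD headers. They are derived from the
integration timestep (default 1.5 fs) and save interval (default 5000
steps, i.e. 7.5 ps per frame), both overridable per run. Subsampling to an
interval keeps frames whose time is within half a native spacing of a
multiple of the interval, always keeping frame 0; it is idempotent at a
fixed interval.

## Active-site observables

The opening distance of a composite site is the Euclidean distance between
the unweighted mean Cα positions ("geometric centres") of a 4-residue
Walker A motif and the opposing monomer's 4-residue C-motif. No
superposition is applied — the distance is frame-internal, hence exactly
invariant under global rigid motion. Contact observables (C-motif serine
OG to β-phosphate oxygens; D-loop backbone carbonyl O to Pi oxygens) take
the per-frame minimum over all cross pairs: the "proximal" partner is
defined by proximity itself, not by a fixed atom name, and the chosen atom
is logged.

## Essential dynamics

Frames are aligned to a fixed reference structure over the analysis
selection; the covariance of the aligned 3N coordinates about their
trajectory mean is diagonalised with a full symmetric eigendecomposition
(adequate up to ~2000 atoms; an NBD dimer has ~460 Cα). Choices:

- **Unweighted covariance** (no masses). For a Cα-only selection mass
  weighting is a near-constant factor; unweighted keeps eigenvalues in Å².
- **Projections are about the trajectory mean**, not the alignment
  reference — the convention under which the self-projection variance of
  mode *i* equals λ_i exactly.
- **Eigenvector sign is arbitrary** and fixed by making the
  largest-magnitude component positive; a `flip_sign` option exists for
  plotting two runs on a common axis.
- Cross-projection applies the model of one run to the frames of another;
  it requires only that the atom correspondence of the model's selection
  holds on the other trajectory.
- Subspace overlap between a unit 3N vector and the first k modes of a
  model is the root-sum-of-squares of inner products, which reduces to
  |cos θ| at k = 1 and equals 1 whenever the vector lies in the span.

Mode interpolation writes structures `mean + p·v` at evenly spaced
projections p between two bounds (default: the observed extremes with 8
interior structures). These live in the model's aligned frame, so
re-projecting them (without re-alignment) returns the construction value
identically.

## Hinge analysis

Between two conformers, residues are partitioned into quasi-rigid domains
by a deterministic greedy seeded-growth scheme:

1. superpose conformer y onto x over the whole selection; let D be the
   resulting mean per-residue Cα displacement (D below 1e-9 Å short-cuts
   to a single all-rigid domain);
2. rank all windows of 12 consecutive same-chain residues by their internal
   fit RMSD, most rigid first;
3. grow the best fully-unassigned window to a fixed point (≤ 50
   iterations): fit the current members, admit any unassigned residue whose
   displacement under the fitted transform is ≤ tolerance × D, drop members
   that exceed it;
4. keep domains of ≥ 15 residues; leftovers are unassigned. Ties break
   toward the lowest residue number everywhere, so the procedure has no
   randomness; domains may be discontinuous in sequence.

The tolerance (default 0.4) is deliberately *relative* to D: it scales with
the size of the conformational change being partitioned, so the same
setting works for a 3° wobble and a 20° opening. The flip side is that
residues whose motion is small compared to D — those near the hinge axis —
are intrinsically ambiguous: they fit either neighbouring domain within the
threshold, and the greedy order decides. On constructions whose moving
blocks keep a healthy distance from the axis, recovery is exact.

Screws are reported in the frame of the most static domain: the pair is
superposed over the domain with the smallest rotation angle in the global
frame (ties: largest domain, then lowest residue), and each domain's motion
x→y is then fitted and decomposed. This is the convention in which a
two-body hinge reports its full relative angle on the moving arm and ~0° on
the reference, and planted multi-body angles are recovered exactly when a
truly static block exists. (Measuring against the *global* compromise fit
instead would split a two-body angle across both domains roughly by their
inertia, reporting ~10°+~10° for a 20° hinge — a frame that matches no
planted quantity.)

Screw decomposition itself: angle from the rotation trace; axis from the
antisymmetric part of R (from the symmetric part's +1 eigenvector above
179°, where the sign is fixed by making the largest component positive);
pitch = t·axis; the pivot solves (I−R)p = t−pitch·axis in the plane
perpendicular to the axis and is then slid along the axis to the point
nearest the domain's geometric centre, making the reported point unique
(any point of the axis line solves the equation). Rotations below 1° have
no well-conditioned axis: angle and centre displacement are still reported,
axis/pivot/pitch are flagged undefined.

## Synthetic data: what it emulates, and what it does not

The generator produces the statistical structure the analyses assume — and
nothing more:

- a two-chain Cα dimer with core/helical lobes on the default residue
  numbering, chain B an exact 180° rotation of chain A (so both composite
  sites start at identical distances);
- an opening trajectory in which the apo monomer's core block rotates by
  θ(t) (linear or sigmoid schedule, default 20° over 500 frames at 7.5 ps
  spacing) about a hinge through the core/helical junction, oriented so the
  empty site's distance grows; the nucleotide-bound site is untouched;
- iid Gaussian coordinate noise (default σ = 0.2 Å per coordinate per
  frame) on every atom;
- named pseudo-atoms for the contact observables: β-phosphate oxygens and a
  Pi group in the bound site, the C-motif serine OG planted 3.0 Å from the
  nearest β-phosphate oxygen, and the trans D-loop carbonyl O planted 2.7 Å
  from the nearest Pi oxygen — the hydrogen-bond geometry of the
  crystallographic starting structure, planted synthetically;
- rigid conformer pairs (arbitrary residue blocks, axes, angles, pivots)
  and an elbow-shaped single chain whose two arms stay ≥ 12 Å from the
  hinge axis, used for hinge recovery under noise;
- a no-motion control run (pure noise) as the stability counterpart.

Every planted quantity is returned as ground truth, including the
closed-form opening distance per frame, and all randomness flows from one
integer seed (bit-identical regeneration).

What the generator does **not** emulate: force-field dynamics, solvent,
side chains, time-correlated thermal motion (the noise is white), partial
or transient openings, and any coupling between the two sites. Passing
tests therefore demonstrate that the *algorithms* recover planted
collective motions under realistic noise magnitudes — not that any
particular biological system behaves this way. Headline statistics from
real µs-scale trajectories (mode fractions, overlap coefficients,
opening times) are not reproducible from synthetic data and are treated as
qualitative signatures only: a dominant first mode, a near-unit projection/
opening correlation, and a clear overlap contrast between an opening run
and a static control.

## Problem sizes and run times

The test and acceptance workloads use the package's standard study
conditions: 500-frame runs of the 481-atom toy dimer (470 Cα in the PCA
selection, 3N = 1410), a 120-residue elbow chain for hinge recovery with 20
noise seeds, 200k+60k-sample quaternion searches for the superposition
oracle, and 100-frame windows for the SVD factorisation check. The full
suite runs in well under a minute of CPU apart from trajectory generation;
the acceptance script completes in a few seconds.

## Known limitations

- The greedy partition is order-dependent by construction; determinism is
  guaranteed, global optimality is not. Near-hinge residues can land in
  either adjacent domain (see above).
- PDB round-trips are exact only to format precision (1e-3 Å); DCD to
  single precision (1e-4 Å).
- The residue scheme assumes one Cα per residue per chain; insertion codes
  are rejected rather than resolved, and alternate locations other than
  blank/'A' are dropped with a warning.
- Cross-projection assumes identical atom ordering between runs; no
  sequence alignment is attempted.
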