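# Methods

This note documents the models, algorithms, parameter choices, and known
limitations of `basinavg`.

## Model and assumptions

A flexible solute sampled by constant-temperature MD visits a small number
of metastable conformations.  Within one conformational basin the internal
coordinates oscillate quasi-harmonically around a single reference, so the
basin is well represented by the structure whose internal coordinates are
the basin means; across basins no single structure is representative.  The
package therefore estimates an ensemble observable as the population-
weighted mean of per-basin values,

    ⟨ε̃⟩ = Σₖ N_k ε̃_k / Σₖ N_k ,

where ε̃_k is computed once on basin k's averaged structure in its averaged
environment.  The weighting divides by the sum over *used* basins, not the
raw trajectory length: frames discarded with under-populated basins must
not dilute the average (this is also what makes the published weighted
tables reproducible from their per-basin rows, whose populations do not
always sum to the trajectory length).  When basins exactly partition a
frame set, weighting the subensemble means reproduces the full mean to
machine precision; this identity is asserted in the tests.

The environment is assumed to follow the solute's conformation.  All
environment averaging is done per basin, in the frame defined by the
solute's Kabsch alignment, so conformer-coupled solvent displacement is
retained instead of being smeared into a half-occupied average.

Boltzmann weights w_k ∝ exp(−G_k/kT) are provided for the case where basin
populations come from free energies rather than frame counts; nothing in
the pipeline computes G_k itself.

## Basin detection

Detection is deliberately per-coordinate, not a clustering of whole
structures in an n-dimensional space: results of structure-space clustering
depend strongly on the metric and atom selection, while individual internal
coordinates are directly interpretable and independently checkable.  The
tooling is a toolbox for an informed operator; every threshold is a user
parameter.

1. **Alignment and conversion.**  Frames are Kabsch-aligned (proper
   rotations only, so chirality is preserved) to the first trajectory frame
   and converted to a Z-matrix under a connectivity that is auto-generated
   (covalent radii, greedy earlier-atom references) but fully overridable.
   Internal coordinates are rototranslation invariant, so alignment matters
   only for the Cartesian environment averaging that reuses its transforms.
2. **Dihedral ranges.**  Each dihedral series is analysed in whichever of
   (−180, 180] / [0, 360) has the smaller standard deviation (ties keep the
   conventional range); averages are mapped back to (−180, 180].
3. **σ screening.**  Per-kind thresholds classify coordinates as stable
   (small σ), free (large σ — freely rotating groups), or ambiguous.
   Defaults: dihedrals (25°, 80°), angles (8°, 30°), bonds (0.05 Å, 0.2 Å).
   A three-well methyl has σ ≈ 100°, a clean two-state switcher ≈ 40–60°,
   thermal noise ≈ 5°.
4. **Clustering.**  Ambiguous coordinates are clustered either from time
   domains (default for time-ordered sampling: a new domain opens when the
   trailing n_t-frame running mean departs from the current domain mean by
   more than τ; domains with means closer than a grouping threshold merge
   into possibly non-contiguous clusters) or by 1-D x-means (k-means++
   under a fixed seed, recursive 2-way splits accepted when the BIC of a
   hard-assignment Gaussian mixture with per-cluster variance and mixing
   weights improves; ties break toward fewer clusters — a shared-variance
   BIC without weight terms over-splits a single Gaussian and is not used).
   Block-mean jump detection (window x) is available for quick scans.
   Defaults: x = 25, n_t = 10, τ = 30° / 0.05 Å, grouping 20°.
5. **Assembly.**  Clusters of *different* coordinates whose frame sets have
   Jaccard ratio ≥ 0.8 are unioned into candidate basin states; coordinates
   with at least one such edge are the drivers.  Frames are assigned by
   majority vote of driver-cluster membership (ties to the larger state;
   frames without votes go to the nearest state by coordinate distance).
   Basins below min_population = 30 frames are discarded — small basins are
   both statistically unreliable to average and negligible in the weighting.
   Basins are labelled 1, 2, … by decreasing N_k.

Two structural safeguards keep rotors out of the basin definition.
Dihedrals sharing a rotation axis (identical bond/angle references — the
three hydrogens of a methyl) are redundant descriptors of one torsion, so
only the lowest-atom representative is analysed; and axes carrying three or
more *terminal* atoms are methyl-like tops whose torsion is rotor motion by
construction and never defines basins, even when a skewed well occupancy
puts its σ below the free threshold.  A chain continuation atom is never
terminal, so backbone torsions are unaffected.  Environment-based basin
criteria (e.g. alternating hydrogen bonds) are not implemented; the
assembly accepts externally constructed cluster lists, which is the hook
for such extensions.

## Structure averaging

Bonds and angles are averaged arithmetically; each dihedral in its selected
range.  Free rotors are then overridden: the pivot (lowest atom index of
the axis group) is set to the center of its largest cluster within the
basin, and each dependent atom to the pivot plus the *circular mean of its
observed offset* over the basin — the trajectory's own spacing (e.g.
119.5°), not an idealized 120°.  The averaged Z-matrix is rebuilt into
Cartesian coordinates by natural-extension placement; angles within 1e-3°
of 0/180° raise an error because the placement is ill-conditioned there.

Connectivity choice matters for rings: a ring written as one chain closes
its last bond implicitly, and averaged angle noise accumulates into a
visibly shortened closing bond.  Splitting the ring into two chains spreads
the closure; both definitions round-trip a single structure exactly but
average differently, which is why connectivity is always overridable.

Validation uses Θ, the minimized RMSD over a chosen atom subset.  The Θ
distribution of a basin average over its own frames is single-peaked; a
direct average over a multi-basin trajectory shows one peak per basin —
restricted to the moiety driving the conformerism the separation is large,
over all atoms it can be partially absorbed by the superposition.
Peak-counting uses a 1-vs-2 component Gaussian-mixture comparison (BIC,
plus a ≥ 2σ mean-separation and ≥ 2 % weight requirement so shoulders are
not called modes).

## Environment grids and embedding potential

Environment atoms are grouped into types t with force-field effective
charge q_t and nuclear charge Z_t; the effective electron number n_t =
Z_t − q_t splits the averaged distribution into nuclear- and electron-like
parts that share the same gridded geometry.  Frames of basin k (and only
those) are binned nearest-voxel into per-type number densities g_t(α) =
count/(N_frames·ν_α); the normalization Σ_α g_t ν_α = mean in-grid count is
exact and asserted at 1e-10.  No cloud-in-cell smoothing is applied — the
counting definition is kept literal; atoms outside the grid are tallied,
not fatal.  The default grid is the solute bounding box + 6 Å margin at
0.5 Å spacing.  All environment atoms are treated as effective charges;
near/far partitioning with explicit quantum densities for close residues
is out of scope.

The averaged electrostatic potential is the Coulomb sum of the net voxel
charges (equivalently the Z_t nuclear term minus the n_t electronic term;
identical by the definition of n_t), evaluated in atomic units with
distances clamped below half the smallest voxel edge — the bare sum is
singular at voxel centers and no specific regularization is canonical, so
the softening radius is tied to the only available length scale.  The
binning error at a far-field point is a displacement-dipole term; it
vanishes as spacing → 0 but is not monotone for one accidental charge
placement, which the convergence test accounts for by construction.

The nonadditive term of the linearized-FDET embedding potential is
evaluated on given density grids (e/bohr³) as v[ρ_A + ρ_B] − v[ρ_A] with
LDA potentials: Thomas–Fermi kinetic (5/3)C_TF ρ^{2/3}, Dirac exchange
−(4/3)C_x ρ^{1/3}, and VWN correlation in parametrization V (the VWN-III
vs V choice is otherwise arbitrary here; V is the common LSDA default, and
the implementation is verified against a numerical derivative of ρ·ε_c).
Computing ρ_A or ρ_B from wavefunctions, and any self-consistent embedding,
is out of scope: densities and per-structure observables enter as inputs.
Cube output uses bohr axes and z-fastest ordering; the only unit constant
lives in `basinavg.constants`.

## Observable averaging and subsampling

Ensemble averages are plain means of the per-frame values;
oscillator-strength weighting is offered only as a histogram utility for
spectra-like plots, since weighting the averages themselves is not implied
by the averaging definitions.  Shift error statistics take per-basin
Δε^iso and Δε^emb (geometric − ensemble) and report the per-basin shift
error Δε^emb − Δε^iso in meV, its range and MAE, and the mean magnitude
relative to each basin's own ensemble solvatochromic shift (basins with
zero shift are excluded and reported).  BLA bins are equal-width over
[min, max], right-open with the last bin closed, optionally crossed with a
basin partition.

The subsampling analysis grows, for each of R replicates, a random
incremental ordering of all N frames and records the running mean at every
size s; μ_s ± 2σ_s across replicates is the ~95 % band.  At s = N every
replicate holds the full set, so the running mean there is assigned the
full-ensemble value identically (this sidesteps permutation-order float
rounding and makes σ_N exactly zero, as the construction requires).  σ_s
follows the finite-population law σ_pop·√((N−s)/(N·s)·N/(N−1)), which the
tests check at 15 %.  The critical size s_c against a reference value is
reported both as the first exclusion and, by default, as the smallest s
beyond which the band *stays* exclusive — first crossings can be noise.
The 2σ amplitude is kept as-is; no t-correction.  Bootstrap errors on
ensemble means use 1000 nonparametric resamples under a seed.

## Synthetic generator

`synthgen` emulates the phenomenology the pipeline must handle, with known
ground truth: a 12-atom solute (8-carbon conjugated chain, methyl on C1)
whose internal coordinates are Gaussian around per-conformer references
(defaults σ = 5° dihedrals, 2° angles, 0.01 Å bonds — thermal-oscillation
magnitudes); a synchronized backbone dihedral pair switching between
conformers ±60° ↔ ∓60° on a fixed schedule (default: one switch at frame
650 of 1000, a ~65/35 split like the dominant basins of the rhodopsin
trajectories); a three-well Markov methyl rotor (hop probability
0.02/frame, σ = 8°); a six-point O/H charge environment (TIP3P-like ±0.834/
0.417 e) rigidly displaced with the conformer plus 0.1 Å positional noise;
random rigid rototranslations per frame (frame 0 kept in the body frame);
and observables ε = base(conformer) + 10 eV/Å · (BLA − 0.11 Å) + 0.02 eV
noise, with a conformer-dependent embedded shift — the linear BLA relation
of conjugated chromophores.  Everything is reproducible under a seed.

What it does *not* emulate: anharmonicity, correlated coordinate noise,
force-field sterics, solvent structure beyond point charges, and kinetics
beyond a fixed switch schedule.  Passing tests therefore demonstrate the
correctness of the analysis machinery under its own assumptions, not
detection power on pathological real trajectories (slow drifts, overlapping
wells, gradual transitions).

## Numerical choices and test design

- RMSDs after superposition are computed from the explicitly rotated
  coordinates, not the SVD trace formula, whose cancellation error floors
  near-congruent pairs at ~1e-7 Å.
- The Kabsch solution is cross-checked against an independent stochastic
  rotation search (coarse random rotations plus shrinking local
  refinement), both as an equality at 1e-3 and as an inequality against
  every sampled rotation.
- Dihedral wrap maps exactly −180° to +180°, keeping the (−180, 180]
  contract bit-stable.
- Basin-recovery acceptance checks compare averaged internals to the
  generator references through the noise-normalized RMS over all backbone
  coordinates against 3/√N_k: a per-coordinate 3σ bound over the ~1400
  coordinate×basin×seed draws involved would fail with near certainty under
  the generator's own statistics and would test luck, not correctness.
- Test problem sizes (600–1000 frames, 20 seeds, R = 200 replicates) are
  chosen so the whole suite runs in well under a minute while keeping
  sampling fluctuations far from the asserted bounds.

## Known limitations

- Basin detection assumes time-ordered sampling for its default clustering
  path; `time_ordered=False` falls back to pure distribution clustering.
- No symmetry-aware RMSD: equivalent-atom permutations are avoided by
  excluding methyl hydrogens from Θ subsets, per the standard practice.
- The unassigned-frame fallback (nearest cluster center) uses an L1
  coordinate distance without circular wrapping across the dihedral seam;
  drivers selected by range have already been mapped away from their seam.
- `s_c` depends on the replicate band and hence on R; small R gives ragged
  bands and noisy sustained-exclusion points.
- Cube I/O supports orthorhombic axis-aligned grids only.
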