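# basinavg

Basin-based geometric averaging for conformationally flexible solutes in
averaged environments.

## The problem

Computing an ensemble-averaged observable for a solvated chromophore — say
the first vertical excitation energy ε of a retinal Schiff base inside a
protein — nominally costs one quantum calculation per MD frame: ⟨ε⟩_ens =
(1/N) Σᵢ εᵢ over N ≈ 1000 snapshots.  The classic shortcut, one *average*
solute structure in one *average* environment, breaks down for nonrigid
solutes: averaging a torsion that hops between two wells Φ₁ and Φ₂ lands
near the transition-state geometry, a structure unlike anything the system
ever visits.

`basinavg` implements the basin-based alternative.  The trajectory is
partitioned into K *conformational basins* — subensembles oscillating
around one metastable conformation, with Σₖ N_k + N_discarded = N — by
analysing each internal coordinate's trajectory separately (σ screening,
jump/time-domain detection, x-means clustering, and Jaccard correlation of
cluster frame sets).  Within each basin the solute's internal coordinates
and the environment's charge distribution are averaged, one observable is
computed per basin, and the ensemble estimate is the population-weighted
mean

    ⟨ε̃⟩ = Σₖ (N_k / Σₖ N_k) · ε̃_k ,

so K ≈ 2–3 calculations replace N ≈ 1000.  The package covers the full
workflow around that statistic for users who compute the per-structure
observables elsewhere:

- **geometry / zmatrix** — Kabsch superposition and the minimized RMSD Θ
  (proper rotations only), Z-matrix conversion with overridable
  connectivity, seam-aware dihedral ranges, bond-length alternation (BLA);
- **basins** — per-coordinate screening and clustering, basin assembly,
  with free rotors (methyls) excluded from the basin definition;
- **avgstruct** — per-basin and direct averaged structures, free-rotor
  placement at the major-cluster center with trajectory-mean offsets, and
  Θ-distribution diagnostics (a multi-peaked Θ distribution exposes an
  undetected basin);
- **envgrid** — per-basin time-averaged environment densities g_t(α) on a
  regular grid, effective electron numbers n_t = Z_t − q_t, the averaged
  Coulomb potential, and the nonadditive Thomas–Fermi + Dirac + VWN5 term
  of the linearized frozen-density-embedding (FDET) potential;
- **obsavg** — ensemble and population-weighted averaging, solvatochromic
  shift error statistics, BLA binning, Boltzmann weights, and the
  incremental random-subsampling analysis with its critical sample size
  s_c (the number of random frames a 2σ confidence band needs before it
  beats a given reference);
- **synthgen** — a ground-truth synthetic generator (harmonic internal
  coordinates with discrete conformer switches, a Markov methyl rotor, a
  conformer-coupled point-charge environment, linear BLA→ε observables)
  so every stage is testable without any external data.

## Worked example

```python
import numpy as np
import basinavg as ba
from basinavg import synthgen as sg

cfg = sg.default_config(n_frames=1000, seed=0)      # switch at frame 650
solute, env, truth = sg.make_trajectory(cfg)

aligned, _, _ = ba.align_trajectory(solute.coords, 0)
zs = ba.to_internal(aligned, truth.connectivity, elements=solute.elements)
partition, diag = ba.detect_basins(zs, ba.RunConfig())
print(partition.n_basins, [int(n) for n in partition.populations])
```

prints `2 [648, 352]` — the two conformers are recovered (99.8 % frame
agreement with the generator's labels; the methyl rotor is classified
`free`, σ ≈ 101°, and excluded).  Averaging each basin
(`examples/02_average_structures.py`):

```text
basin 1 (N = 648): switching dihedral  +59.90 deg, mean theta 0.042 A, single-peaked: True
basin 2 (N = 352): switching dihedral  -59.38 deg, mean theta 0.044 A, single-peaked: True
direct  (N = 1000): switching dihedral  +17.91 deg, mean theta 0.205 A, multi-peaked: True
```

The basin averages recover the ±60° wells; the direct average sits at
+17.9°, near the transition state, and its Θ distribution over the full
trajectory splits into one peak per conformer.

On the published per-basin excitation energies of four rhodopsin systems
(`examples/04_weighted_observables.py`), population-weighting the per-basin
geometric values reproduces the weighted averages — e.g. 3.414 eV for the
embedded all-trans chromophore in C1C2 against the ensemble's 3.417 eV —
and the per-basin solvatochromic-shift errors span −45.0 to −23.0 meV with
a mean absolute error of 34.2 meV (21.2 % mean relative error).

The remaining examples show the per-basin environment grids and embedding
potential (`03`) and the subsampling convergence analysis (`05`).  A thin
CLI mirrors the library: `basinavg synth | analyze-coords | detect-basins |
average-structures | theta | env-grid | observables | subsample`.

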