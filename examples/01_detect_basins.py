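"""Detect conformational basins of a flexible solute from its trajectory.

Generates a 1000-frame synthetic trajectory whose backbone dihedral pair
switches conformer at frame 650, then runs the per-coordinate detection
pipeline: alignment, internal-coordinate conversion, sigma screening,
time-domain clustering, and correlation-based basin assembly.
"""

import numpy as np

import basinavg as ba
from basinavg import synthgen as sg

cfg = sg.default_config(n_frames=1000, seed=0)
solute, environment, truth = sg.make_trajectory(cfg)

aligned, _, _ = ba.align_trajectory(solute.coords, 0)
zseries = ba.to_internal(aligned, truth.connectivity, elements=solute.elements)
partition, diag = ba.detect_basins(zseries, ba.RunConfig())

print(f"detected K = {partition.n_basins} conformational basins")
print(f"populations N_k = {[int(n) for n in partition.populations]}, "
      f"{partition.discarded.size} frames discarded")

labels = partition.labels()
true = np.where(truth.labels == "A", 1, 2)
agreement = max(np.mean(labels == true), np.mean(labels == 3 - true))
print(f"agreement with the generator's ground-truth labels: {100 * agreement:.1f}%")

print("\nper-coordinate screening (non-stable coordinates):")
for cid, cls in diag["classes"].items():
    if cls.label != "stable" and cid not in diag["redundant"]:
        print(f"  {cid[0]:>8s} of atom {cid[1]:2d}: {cls.label:9s} (sigma = {cls.stdev:.1f})")

# 'free' / excluded coordinates are the methyl rotor; the two 'ambiguous'
# dihedrals are the synchronized pair whose correlated clusters define the
# two basins.
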