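"""Reference excitation-energy tables for four rhodopsin systems.

Published per-basin first vertical excitation energies (ADC(1)-level, eV) of
protonated retinal Schiff bases in protein environments: the all-trans
chromophore in the channelrhodopsin chimera C1C2 and the all-trans, 9-cis
and 11-cis configurations in jumping spider rhodopsin-1 (JSR1).  For every
conformational basin k the table carries the basin-averaged-structure
("geometric") value and the subensemble-mean ("ensemble") value, isolated
(iso) and embedded (emb), together with the basin population N_k; the
error columns are Delta = geometric - ensemble.

These tables serve as the worked input for the population-weighted
averaging and shift-error statistics; the package never computes excitation
energies itself.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "per_basin_table",
    "ensemble_reference",
    "weighted_reference",
    "SYSTEMS",
]

SYSTEMS = ("AT-C1C2", "9C-JSR1", "11C-JSR1", "AT-JSR1")

# system, basin, eps_geo_iso, eps_ens_iso, eps_geo_emb, eps_ens_emb,
# delta_iso, delta_emb, n_frames
_PER_BASIN = [
    ("AT-C1C2", 1, 3.074, 3.035, 3.410, 3.407, 0.039, 0.003, 497),
    ("AT-C1C2", 2, 3.082, 3.059, 3.415, 3.437, 0.023, -0.022, 219),
    ("AT-C1C2", 3, 3.080, 3.047, 3.478, 3.469, 0.032, 0.009, 31),
    ("9C-JSR1", 1, 3.074, 3.049, 3.174, 3.176, 0.025, -0.002, 691),
    ("9C-JSR1", 2, 3.073, 3.054, 3.180, 3.186, 0.019, -0.006, 165),
    ("9C-JSR1", 3, 3.053, 3.036, 3.134, 3.162, 0.017, -0.028, 99),
    ("11C-JSR1", 1, 2.973, 2.941, 3.048, 3.047, 0.033, 0.001, 863),
    ("11C-JSR1", 2, 2.882, 2.898, 2.964, 3.011, -0.016, -0.047, 69),
    ("AT-JSR1", 1, 2.832, 2.811, 2.943, 2.960, 0.020, -0.017, 741),
    ("AT-JSR1", 2, 2.904, 2.870, 3.016, 3.023, 0.034, -0.007, 244),
]

# full-trajectory ensemble means (iso, emb) and total frame counts
_ENSEMBLE = {
    "AT-C1C2": (3.042, 3.417, 750),
    "9C-JSR1": (3.048, 3.176, 1000),
    "11C-JSR1": (2.938, 3.044, 1000),
    "AT-JSR1": (2.828, 2.977, 1000),
}

# published population-weighted geometric averages (iso, emb)
_WEIGHTED = {
    "AT-C1C2": (3.077, 3.414),
    "9C-JSR1": (3.071, 3.171),
    "11C-JSR1": (2.966, 3.042),
    "AT-JSR1": (2.851, 2.962),
}


def per_basin_table() -> pd.DataFrame:
    """Per-basin geometric vs ensemble excitation energies (eV) with populations."""
    return pd.DataFrame(
        _PER_BASIN,
        columns=[
            "system", "basin",
            "eps_geo_iso", "eps_ens_iso", "eps_geo_emb", "eps_ens_emb",
            "delta_iso", "delta_emb", "n_frames",
        ],
    )


def ensemble_reference() -> pd.DataFrame:
    """Full-trajectory ensemble means per system (eV) and total frame counts."""
    rows = [(s, *_ENSEMBLE[s]) for s in SYSTEMS]
    return pd.DataFrame(rows, columns=["system", "eps_ens_iso", "eps_ens_emb", "n_frames"])


def weighted_reference() -> pd.DataFrame:
    """Published population-weighted geometric averages per system (eV)."""
    rows = [(s, *_WEIGHTED[s]) for s in SYSTEMS]
    return pd.DataFrame(rows, columns=["system", "eps_geo_iso", "eps_geo_emb"])
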