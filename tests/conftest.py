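import numpy as np
import pytest

import basinavg as ba
from basinavg import synthgen as sg


@pytest.fixture(scope="session")
def two_basin_run():
    """A 600-frame two-conformer synthetic run pushed through the full pipeline."""
    cfg = sg.default_config(n_frames=600, schedule=((0, "A"), (400, "B")), seed=3)
    sol, env, truth = sg.make_trajectory(cfg)
    aligned, rot, cm = ba.align_trajectory(sol.coords, 0)
    zs = ba.to_internal(aligned, truth.connectivity, elements=sol.elements)
    part, diag = ba.detect_basins(zs, ba.RunConfig())
    rotors = ba.detect_rotor_groups(diag["classes"], truth.connectivity,
                                    clusters=diag["clusters"])
    return {
        "cfg": cfg, "solute": sol, "env": env, "truth": truth,
        "aligned": aligned, "rotations": rot, "cm_pairs": cm,
        "zseries": zs, "partition": part, "diagnostics": diag, "rotors": rotors,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
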