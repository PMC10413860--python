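"""Synthetic trajectories with known ground truth.

The generator emulates the phenomenology of a flexible conjugated
chromophore in a thermal bath: internal coordinates oscillate harmonically
(Gaussian noise) around per-conformer reference values, a pair of backbone
dihedrals jumps synchronously between conformers on a fixed switch schedule,
a methyl-like rotor hops freely between three wells as a Markov chain, and a
point-charge environment is rigidly displaced with the active conformer.
Observables follow the linear BLA--excitation-energy relation of conjugated
chains, with an embedded variant shifted per conformer.

The default solute is an 8-heavy-atom conjugated chain carrying one
synchronized switching dihedral pair, one tail dihedral, and one methyl
rotor -- the minimal caricature of ring-pucker plus side-chain plus methyl
conformerism.  Everything is reproducible bit-for-bit under a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .geometry import wrap_to_pm180
from .trajio import ChargeTyping, Trajectory
from .zmatrix import Connectivity, ZMatrix, to_cartesian

__all__ = [
    "RotorSpec",
    "EnvironmentSpec",
    "ObservableModel",
    "SynthConfig",
    "GroundTruth",
    "default_config",
    "default_charge_typing",
    "make_trajectory",
    "make_observables",
    "SWITCHER_ATOMS",
    "MOIETY_ATOMS",
    "NON_ROTOR_ATOMS",
    "SINGLE_BONDS",
    "DOUBLE_BONDS",
]

# default 12-atom solute: C0..C7 conjugated chain, methyl C8 on C1, H9-H11
_ELEMENTS = ["C"] * 9 + ["H"] * 3
_REFS = np.array([
    [-1, -1, -1],
    [0, -1, -1],
    [1, 0, -1],
    [2, 1, 0],
    [3, 2, 1],
    [4, 3, 2],
    [5, 4, 3],
    [6, 5, 4],
    [1, 2, 3],
    [8, 1, 2],
    [8, 1, 2],
    [8, 1, 2],
])

SWITCHER_ATOMS = (4, 5)      # the synchronized dihedral pair
TAIL_ATOM = 7                # independent tail dihedral
ROTOR_PIVOT = 9
ROTOR_DEPENDENTS = (10, 11)
MOIETY_ATOMS = (2, 3, 4, 5, 6)          # atoms flanking the switching torsions
NON_ROTOR_ATOMS = tuple(range(9))       # everything but the methyl hydrogens
SINGLE_BONDS = ((0, 1), (2, 3), (4, 5), (6, 7))
DOUBLE_BONDS = ((1, 2), (3, 4), (5, 6))


@dataclass
class RotorSpec:
    """Markov-chain methyl rotor: wells, per-frame hop probability, noise."""

    pivot: int = ROTOR_PIVOT
    dependents: tuple = ROTOR_DEPENDENTS
    wells: tuple = (60.0, 180.0, -60.0)
    hop_prob: float = 0.02
    sigma: float = 8.0
    offsets: tuple = (120.0, -120.0)  # dependent-minus-pivot dihedral offsets


@dataclass
class EnvironmentSpec:
    """Point-charge environment coupled to the solute conformer."""

    labels: tuple = ("O", "H", "O", "H", "O", "H")
    base_positions: np.ndarray = field(default_factory=lambda: np.array([
        [1.0, 4.0, 0.5], [1.8, 4.6, 0.5],
        [5.0, -4.0, 1.0], [5.8, -4.4, 1.0],
        [3.0, 0.5, 4.5], [3.8, 0.9, 4.9],
    ]))
    displacement: dict = field(default_factory=lambda: {
        "A": np.zeros(3),
        "B": np.array([1.2, 0.8, -0.5]),
    })
    sigma: float = 0.1


@dataclass
class ObservableModel:
    """Linear BLA model of the excitation energy, per conformer.

    eps_iso = base[conformer] + slope * (BLA - bla_ref) + noise; the
    embedded variant adds a conformer-dependent solvatochromic shift.
    """

    base_iso: dict = field(default_factory=lambda: {"A": 3.07, "B": 3.08})
    emb_shift: dict = field(default_factory=lambda: {"A": 0.34, "B": 0.33})
    slope: float = 10.0   # eV per Angstrom of BLA
    bla_ref: float = 0.11
    sigma: float = 0.02   # eV
    f_base: dict = field(default_factory=lambda: {"A": 1.05, "B": 1.00})
    f_sigma: float = 0.02


@dataclass
class SynthConfig:
    """Full specification of a synthetic run; defaults are the study conditions."""

    n_frames: int = 1000
    conformers: dict = None                  # name -> reference ZMatrix values
    schedule: tuple = ((0, "A"), (650, "B"))  # (start_frame, conformer)
    sigma_dihedral: float = 5.0   # degrees
    sigma_angle: float = 2.0      # degrees
    sigma_bond: float = 0.01      # Angstrom
    rotor: RotorSpec = field(default_factory=RotorSpec)
    environment: EnvironmentSpec = field(default_factory=EnvironmentSpec)
    observables: ObservableModel = field(default_factory=ObservableModel)
    rigid_motion: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.conformers is None:
            self.conformers = _default_conformers()
        starts = [s for s, _ in self.schedule]
        if starts != sorted(set(starts)) or starts[0] != 0:
            raise ValueError("switch schedule must start at frame 0 with increasing frames")
        for name in {c for _, c in self.schedule}:
            if name not in self.conformers:
                raise ValueError(f"schedule references unknown conformer {name!r}")
        shapes = {tuple(ref["bonds"].shape) for ref in self.conformers.values()}
        if len(shapes) != 1:
            raise ValueError("conformer references have mismatched connectivity")


@dataclass
class GroundTruth:
    """What the generator knows: per-frame labels, references, environment, BLA."""

    labels: np.ndarray              # per-frame conformer name
    conformers: dict                # name -> reference internal values
    connectivity: Connectivity
    elements: list
    env_centroids: dict             # name -> centroid of displaced environment
    bla: np.ndarray                 # per-frame BLA from the sampled bonds
    rotor_wells: np.ndarray         # per-frame pivot well value
    observables: ObservableModel


def _default_conformers() -> dict:
    n = len(_ELEMENTS)
    bonds = np.full(n, np.nan)
    bonds[1:8] = [1.46, 1.35, 1.46, 1.35, 1.46, 1.35, 1.46]
    bonds[8] = 1.50
    bonds[9:] = 1.09
    angles = np.full(n, np.nan)
    angles[2:9] = 120.0
    angles[9:] = 109.5
    dih = np.full(n, np.nan)
    dih[3] = 180.0
    dih[6] = 180.0
    dih[TAIL_ATOM] = 180.0
    dih[8] = 120.0
    dih[ROTOR_PIVOT] = 60.0
    dih[10] = 180.0
    dih[11] = -60.0
    a = {"bonds": bonds.copy(), "angles": angles.copy(), "dihedrals": dih.copy()}
    b = {"bonds": bonds.copy(), "angles": angles.copy(), "dihedrals": dih.copy()}
    a["dihedrals"][SWITCHER_ATOMS[0]] = 60.0
    a["dihedrals"][SWITCHER_ATOMS[1]] = -60.0
    b["dihedrals"][SWITCHER_ATOMS[0]] = -60.0
    b["dihedrals"][SWITCHER_ATOMS[1]] = 60.0
    return {"A": a, "B": b}


def default_config(**overrides) -> SynthConfig:
    """The default study conditions; keyword overrides for variants."""
    return SynthConfig(**overrides)


def default_charge_typing() -> ChargeTyping:
    """Water-like effective charges for the default O/H environment."""
    return ChargeTyping(q={"O": -0.834, "H": 0.417}, Z={"O": 8, "H": 1})


def _frame_labels(cfg: SynthConfig) -> np.ndarray:
    labels = np.empty(cfg.n_frames, dtype=object)
    schedule = list(cfg.schedule) + [(cfg.n_frames, None)]
    for (start, name), (end, _) in zip(schedule[:-1], schedule[1:]):
        labels[start:end] = name
    return labels


def make_trajectory(cfg: SynthConfig) -> tuple[Trajectory, Trajectory, GroundTruth]:
    """Generate solute and environment trajectories plus the ground truth."""
    rng = np.random.default_rng(cfg.seed)
    conn = Connectivity(_REFS.copy())
    n_atoms = conn.n_atoms
    labels = _frame_labels(cfg)
    n = cfg.n_frames

    # rotor Markov chain over wells
    wells = np.asarray(cfg.rotor.wells, dtype=float)
    state = np.empty(n, dtype=int)
    state[0] = rng.integers(len(wells))
    for f in range(1, n):
        if len(wells) > 1 and rng.random() < cfg.rotor.hop_prob:
            others = [w for w in range(len(wells)) if w != state[f - 1]]
            state[f] = others[rng.integers(len(others))]
        else:
            state[f] = state[f - 1]

    bonds = np.empty((n, n_atoms))
    angles = np.empty((n, n_atoms))
    dihedrals = np.empty((n, n_atoms))
    for f in range(n):
        ref = cfg.conformers[labels[f]]
        bonds[f] = ref["bonds"] + rng.normal(0.0, cfg.sigma_bond, n_atoms)
        angles[f] = ref["angles"] + rng.normal(0.0, cfg.sigma_angle, n_atoms)
        dihedrals[f] = wrap_to_pm180(ref["dihedrals"] + rng.normal(0.0, cfg.sigma_dihedral, n_atoms))
        pivot_val = wells[state[f]] + rng.normal(0.0, cfg.rotor.sigma)
        dihedrals[f, cfg.rotor.pivot] = wrap_to_pm180(pivot_val)
        for dep, off in zip(cfg.rotor.dependents, cfg.rotor.offsets):
            dihedrals[f, dep] = wrap_to_pm180(pivot_val + off + rng.normal(0.0, cfg.rotor.sigma))

    solute = np.empty((n, n_atoms, 3))
    for f in range(n):
        z = ZMatrix(conn, _ELEMENTS, bonds[f], angles[f], dihedrals[f])
        solute[f] = to_cartesian(z).coords

    env_spec = cfg.environment
    n_env = env_spec.base_positions.shape[0]
    env = np.empty((n, n_env, 3))
    for f in range(n):
        disp = env_spec.displacement.get(labels[f], np.zeros(3))
        env[f] = env_spec.base_positions + disp + rng.normal(0.0, env_spec.sigma, (n_env, 3))

    if cfg.rigid_motion:
        # frame 0 stays in the body frame so aligned coordinates are comparable
        # to the ground truth without an extra transform
        for f in range(1, n):
            R = Rotation.random(random_state=rng).as_matrix()
            t = rng.uniform(-10.0, 10.0, 3)
            solute[f] = solute[f] @ R.T + t
            env[f] = env[f] @ R.T + t

    singles = np.array(SINGLE_BONDS)
    doubles = np.array(DOUBLE_BONDS)
    bla = bonds[:, singles[:, 1]].mean(axis=1) - bonds[:, doubles[:, 1]].mean(axis=1)

    truth = GroundTruth(
        labels=labels,
        conformers=cfg.conformers,
        connectivity=conn,
        elements=list(_ELEMENTS),
        env_centroids={
            name: env_spec.base_positions.mean(axis=0) + env_spec.displacement.get(name, np.zeros(3))
            for name in cfg.conformers
        },
        bla=bla,
        rotor_wells=wells[state],
        observables=cfg.observables,
    )
    return (
        Trajectory(list(_ELEMENTS), solute),
        Trajectory(list(env_spec.labels), env),
        truth,
    )


def make_observables(truth: GroundTruth, cfg: SynthConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-frame (iso, emb) observable tables from the linear BLA model."""
    rng = np.random.default_rng(cfg.seed + 1)
    model = cfg.observables
    n = truth.labels.size
    base = np.array([model.base_iso[lab] for lab in truth.labels])
    shift = np.array([model.emb_shift[lab] for lab in truth.labels])
    fbase = np.array([model.f_base[lab] for lab in truth.labels])
    eps_iso = base + model.slope * (truth.bla - model.bla_ref) + rng.normal(0.0, model.sigma, n)
    eps_emb = eps_iso + shift + rng.normal(0.0, model.sigma, n)
    f_iso = fbase + rng.normal(0.0, model.f_sigma, n)
    f_emb = f_iso + rng.normal(0.0, model.f_sigma, n)
    frames = np.arange(n)
    iso = pd.DataFrame({"frame": frames, "epsilon": eps_iso, "f": f_iso})
    emb = pd.DataFrame({"frame": frames, "epsilon": eps_emb, "f": f_emb})
    return iso, emb
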