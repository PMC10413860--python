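"""Time-averaged environment grids and embedding potentials.

The environment atoms of every frame of a conformational basin (after the
solute-alignment transform) are binned into a regular orthorhombic grid by
atom type, yielding a time-averaged number density g_t(alpha) per voxel.
With effective charges q_t and nuclear charges Z_t, each type carries an
effective electron number n_t = Z_t - q_t, splitting the averaged charge
distribution into nuclear- and electron-like parts.  The averaged Coulomb
potential of the net effective-charge distribution is the electrostatic part
of the embedding potential; the nonadditive kinetic/exchange-correlation
part of linearized frozen-density embedding (FDET) is evaluated on given
densities with LDA functionals (Thomas-Fermi kinetic, Dirac exchange, VWN5
correlation).

Units: grids are specified in Angstrom and number densities are per
Angstrom^3; potentials are returned in hartree per unit charge, and the
density arguments of the LDA functionals are in electrons per bohr^3 (the
cube-file convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import BOHR_ANGSTROM
from .trajio import ChargeTyping

__all__ = [
    "GridSpec",
    "AveragedEnvironmentGrid",
    "PotentialField",
    "effective_electrons",
    "accumulate_density",
    "electrostatic_potential",
    "nonadditive_lda_potential",
    "assemble_embedding_potential",
    "thomas_fermi_potential",
    "dirac_exchange_potential",
    "vwn5_correlation_potential",
]


@dataclass
class GridSpec:
    """Regular orthorhombic grid: origin (Angstrom), spacing per axis, shape."""

    origin: np.ndarray
    spacing: np.ndarray
    shape: tuple

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.spacing = np.broadcast_to(np.asarray(self.spacing, dtype=float), (3,)).copy()
        self.shape = tuple(int(s) for s in self.shape)
        if np.any(self.spacing <= 0):
            raise ValueError("grid spacing must be positive")
        if any(s < 1 for s in self.shape):
            raise ValueError("grid shape must be >= 1 per axis")

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def centers(self) -> np.ndarray:
        """Voxel-center coordinates, shape (nx, ny, nz, 3), Angstrom."""
        axes = [self.origin[ax] + self.spacing[ax] * np.arange(self.shape[ax]) for ax in range(3)]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        return np.stack([gx, gy, gz], axis=-1)

    @classmethod
    def from_bounding_box(cls, coords, margin: float = 6.0, spacing: float = 0.5) -> "GridSpec":
        coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        lo = coords.min(axis=0) - margin
        hi = coords.max(axis=0) + margin
        shape = np.maximum(np.ceil((hi - lo) / spacing).astype(int) + 1, 1)
        return cls(lo, np.full(3, float(spacing)), tuple(shape))


@dataclass
class AveragedEnvironmentGrid:
    """Per-type time-averaged number densities on a grid, plus the type table."""

    grid: GridSpec
    densities: dict                      # type -> (nx, ny, nz) atoms / Angstrom^3
    typing: ChargeTyping
    n_frames: int
    out_of_grid: dict = field(default_factory=dict)  # type -> total atom-frames outside

    def mean_in_grid_count(self, t) -> float:
        """Average per-frame number of type-t atoms inside the grid."""
        return float(self.densities[t].sum() * self.grid.voxel_volume)

    def effective_electron_density(self) -> np.ndarray:
        """<rho_B>(r_alpha) = sum_t n_t g_t(alpha), electrons / Angstrom^3."""
        out = np.zeros(self.grid.shape)
        for t, g in self.densities.items():
            out += effective_electrons(self.typing.Z[t], self.typing.q[t]) * g
        return out

    def nuclear_charge_density(self) -> np.ndarray:
        """sum_t Z_t g_t(alpha), charge / Angstrom^3."""
        out = np.zeros(self.grid.shape)
        for t, g in self.densities.items():
            out += self.typing.Z[t] * g
        return out

    def net_charge_density(self) -> np.ndarray:
        """sum_t q_t g_t(alpha) = nuclear minus electronic part, charge / Angstrom^3."""
        out = np.zeros(self.grid.shape)
        for t, g in self.densities.items():
            out += self.typing.q[t] * g
        return out

    def total_charge(self) -> float:
        """Total average effective charge on the grid (e)."""
        return float(self.net_charge_density().sum() * self.grid.voxel_volume)


@dataclass
class PotentialField:
    """Potential values (hartree / e) at grid voxels or arbitrary query points."""

    values: np.ndarray
    component: str  # electrostatic | nonadditive | total
    grid: GridSpec | None = None
    points: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("potential values must be finite")


def effective_electrons(Z, q) -> float:
    """Effective number of electrons of an atom type: n_t = Z_t - q_t."""
    if np.any(np.asarray(Z) <= 0):
        raise ValueError("nuclear charge must be positive")
    return Z - q


def accumulate_density(
    env_coords: np.ndarray,
    atom_labels,
    typing: ChargeTyping,
    grid: GridSpec,
) -> AveragedEnvironmentGrid:
    """Bin aligned environment frames into per-type averaged number densities.

    ``env_coords`` is (F, A, 3) in the *aligned* frame of the solute,
    restricted to the frames of one conformational basin.  Nearest-voxel
    assignment: g_t(alpha) = count_t(alpha) / (F * voxel_volume).  Atoms
    falling outside the grid are tallied per type, not an error.
    """
    env_coords = np.asarray(env_coords, dtype=float)
    if env_coords.ndim != 3 or env_coords.shape[0] < 1:
        raise ValueError("env_coords must be a non-empty (F, A, 3) array")
    types = typing.resolve(atom_labels)
    n_frames = env_coords.shape[0]
    nu = grid.voxel_volume
    densities = {t: np.zeros(grid.shape) for t in typing.types}
    out_of_grid = {t: 0 for t in typing.types}
    flat = env_coords.reshape(-1, 3)
    tarr = np.array(types * n_frames)
    idx = np.rint((flat - grid.origin[None, :]) / grid.spacing[None, :]).astype(int)
    inside = np.all((idx >= 0) & (idx < np.array(grid.shape)[None, :]), axis=1)
    for t in typing.types:
        sel = tarr == t
        out_of_grid[t] = int(np.sum(sel & ~inside))
        ii = idx[sel & inside]
        if ii.size:
            np.add.at(densities[t], (ii[:, 0], ii[:, 1], ii[:, 2]), 1.0)
        densities[t] /= n_frames * nu
    return AveragedEnvironmentGrid(grid, densities, typing, n_frames, out_of_grid)


def electrostatic_potential(
    env: AveragedEnvironmentGrid,
    query_points: np.ndarray,
) -> PotentialField:
    """Averaged Coulomb potential of the gridded effective-charge distribution.

    v(r) = sum_alpha c_alpha / |r - r_alpha| in atomic units, with c_alpha
    the mean per-frame effective charge in voxel alpha (nuclear Z_t and
    electronic n_t contributions are identical to using q_t = Z_t - n_t).
    The 1/r singularity at voxel centers is softened by clamping distances
    below half the smallest voxel edge.
    """
    pts = np.atleast_2d(np.asarray(query_points, dtype=float))
    if not np.all(np.isfinite(pts)):
        raise ValueError("query points must be finite")
    charge = env.net_charge_density() * env.grid.voxel_volume  # e per voxel
    mask = charge != 0.0
    values = np.zeros(pts.shape[0])
    if np.any(mask):
        centers = env.grid.centers()[mask] / BOHR_ANGSTROM
        c = charge[mask]
        r_min = 0.5 * float(env.grid.spacing.min()) / BOHR_ANGSTROM
        q_b = pts / BOHR_ANGSTROM
        # chunk queries to bound the (Q x V) distance matrix
        step = max(1, int(2e7 / max(centers.shape[0], 1)))
        for start in range(0, q_b.shape[0], step):
            block = q_b[start:start + step]
            d = np.linalg.norm(block[:, None, :] - centers[None, :, :], axis=-1)
            values[start:start + step] = (c[None, :] / np.maximum(d, r_min)).sum(axis=1)
    return PotentialField(values.reshape(np.asarray(query_points).shape[:-1]),
                          "electrostatic", grid=env.grid, points=pts)


# ---------------------------------------------------------------------------
# LDA functionals (densities in e / bohr^3, potentials in hartree)

_C_TF = 0.3 * (3.0 * np.pi**2) ** (2.0 / 3.0)
_C_X = 0.75 * (3.0 / np.pi) ** (1.0 / 3.0)

# VWN parametrization V of the paramagnetic LSDA correlation energy
_VWN_A = 0.0310907
_VWN_B = 3.72744
_VWN_C = 12.9352
_VWN_X0 = -0.10498


def thomas_fermi_potential(rho: np.ndarray) -> np.ndarray:
    """Thomas-Fermi kinetic potential (5/3) C_TF rho^(2/3)."""
    rho = np.asarray(rho, dtype=float)
    return (5.0 / 3.0) * _C_TF * np.cbrt(rho) ** 2


def dirac_exchange_potential(rho: np.ndarray) -> np.ndarray:
    """Dirac-Slater exchange potential -(4/3) C_x rho^(1/3)."""
    rho = np.asarray(rho, dtype=float)
    return -(4.0 / 3.0) * _C_X * np.cbrt(rho)


def _vwn_eps_and_deriv(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """VWN5 correlation energy per electron and its derivative wrt x = sqrt(r_s)."""
    b, c, x0, A = _VWN_B, _VWN_C, _VWN_X0, _VWN_A
    X = x * x + b * x + c
    X0 = x0 * x0 + b * x0 + c
    Q = np.sqrt(4.0 * c - b * b)
    atan_term = np.arctan(Q / (2.0 * x + b))
    eps = A * (
        np.log(x * x / X)
        + (2.0 * b / Q) * atan_term
        - (b * x0 / X0) * (np.log((x - x0) ** 2 / X) + (2.0 * (b + 2.0 * x0) / Q) * atan_term)
    )
    dX = 2.0 * x + b
    datan = -2.0 * Q / ((2.0 * x + b) ** 2 + Q * Q)
    deps = A * (
        2.0 / x - dX / X
        + (2.0 * b / Q) * datan
        - (b * x0 / X0) * (2.0 / (x - x0) - dX / X + (2.0 * (b + 2.0 * x0) / Q) * datan)
    )
    return eps, deps


def vwn5_correlation_potential(rho: np.ndarray) -> np.ndarray:
    """VWN (parametrization V) paramagnetic correlation potential.

    v_c = eps_c - (r_s / 3) d eps_c / d r_s, evaluated via x = sqrt(r_s).
    Zero density gives zero potential.
    """
    rho = np.asarray(rho, dtype=float)
    out = np.zeros_like(rho)
    mask = rho > 1e-30
    rs = (3.0 / (4.0 * np.pi * rho[mask])) ** (1.0 / 3.0)
    x = np.sqrt(rs)
    eps, deps = _vwn_eps_and_deriv(x)
    out[mask] = eps - (x / 6.0) * deps  # (rs/3) d/drs = (x/6) d/dx
    return out


_FUNCTIONALS = {
    "TF": thomas_fermi_potential,
    "Dirac": dirac_exchange_potential,
    "VWN": vwn5_correlation_potential,
}


def nonadditive_lda_potential(
    rho_A: np.ndarray,
    rho_B: np.ndarray,
    functionals=("TF", "Dirac", "VWN"),
) -> PotentialField:
    """Nonadditive LDA potential v[rho_A + rho_B] - v[rho_A].

    This is the non-classical part of the linearized-FDET embedding
    potential evaluated at the fixed reference density rho_A of the embedded
    species; densities are in e/bohr^3.
    """
    rho_A = np.asarray(rho_A, dtype=float)
    rho_B = np.asarray(rho_B, dtype=float)
    if rho_A.shape != rho_B.shape:
        raise ValueError("density grids must be congruent")
    if np.any(rho_A < 0) or np.any(rho_B < 0):
        raise ValueError("densities must be non-negative")
    unknown = set(functionals) - set(_FUNCTIONALS)
    if unknown:
        raise ValueError(f"unknown functionals: {sorted(unknown)}")
    total = np.zeros_like(rho_A)
    for name in functionals:
        fn = _FUNCTIONALS[name]
        total += fn(rho_A + rho_B) - fn(rho_A)
    return PotentialField(total, "nonadditive")


def assemble_embedding_potential(
    electrostatic: PotentialField,
    nonadditive: PotentialField | None = None,
) -> PotentialField:
    """Linearized-FDET embedding potential: electrostatic plus nonadditive term."""
    if nonadditive is None:
        return PotentialField(electrostatic.values.copy(), "total",
                              grid=electrostatic.grid, points=electrostatic.points)
    if electrostatic.values.shape != nonadditive.values.shape:
        raise ValueError("potential components evaluated on different query sets")
    return PotentialField(electrostatic.values + nonadditive.values, "total",
                          grid=electrostatic.grid, points=electrostatic.points)
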