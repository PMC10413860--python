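"""File formats, run configuration, and core containers.

Conventions at the I/O boundary: lengths in Angstrom, charges in elementary
charge units.  Grid potentials are computed in atomic units and cube files
follow the Gaussian dialect (bohr axes, z-fastest value order); the single
conversion constant lives in :mod:`basinavg.constants`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .constants import BOHR_ANGSTROM

__all__ = [
    "FormatError",
    "Trajectory",
    "ChargeTyping",
    "RunConfig",
    "read_xyz_trajectory",
    "write_xyz_trajectory",
    "read_cube",
    "write_cube",
    "read_observable_table",
    "write_observable_table",
    "read_charge_table",
    "read_connectivity",
    "write_connectivity",
    "read_basin_csv",
    "write_basin_csv",
    "write_basin_summary",
]


class FormatError(ValueError):
    """Raised on malformed input files."""


@dataclass
class Trajectory:
    """Ordered frames of element-labelled Cartesian coordinates (Angstrom)."""

    elements: list[str]
    coords: np.ndarray = field(repr=False)  # (F, A, 3)
    frame_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if len(self.elements) != self.coords.shape[1]:
            raise ValueError("elements length must match atom count")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if self.frame_ids is None:
            self.frame_ids = np.arange(self.coords.shape[0])
        else:
            self.frame_ids = np.asarray(self.frame_ids, dtype=int)
            if self.frame_ids.size != self.coords.shape[0]:
                raise ValueError("frame_ids length must match frame count")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


@dataclass
class ChargeTyping:
    """Atom-type table for an effective-point-charge environment.

    ``q`` is the force-field effective charge (e) and ``Z`` the nuclear
    charge per type; ``type_of`` maps atom labels (element symbols or atom
    names) to type labels, identity when omitted.
    """

    q: dict
    Z: dict
    type_of: dict | None = None

    def __post_init__(self) -> None:
        for t, z in self.Z.items():
            if int(z) != z or z <= 0:
                raise ValueError(f"nuclear charge of type {t!r} must be a positive integer")
        if set(self.q) != set(self.Z):
            raise ValueError("q and Z must cover the same types")

    def resolve(self, labels) -> list:
        """Map per-atom labels to type labels; every atom must have a type."""
        out = []
        for lab in labels:
            t = lab if self.type_of is None else self.type_of.get(lab, lab)
            if t not in self.q:
                raise KeyError(f"no charge type for atom label {lab!r}")
            out.append(t)
        return out

    @property
    def types(self) -> list:
        return sorted(self.q.keys(), key=repr)


@dataclass
class RunConfig:
    """User parameters of the basin-detection and averaging pipeline.

    The detection thresholds are deliberate user choices, not universal
    constants; the defaults suit dihedral-driven conformerism sampled every
    ~1 ps with wells tens of degrees apart.
    """

    window_x: int = 25                    # frames per block for jump detection
    min_domain: int = 10                  # n_t: frames defining a time domain
    jump_threshold_deg: float = 30.0      # tau for angular coordinates
    jump_threshold_ang: float = 0.05      # tau for bond lengths (Angstrom)
    grouping_threshold_deg: float = 20.0  # merge time domains closer than this
    grouping_threshold_ang: float = 0.03
    correlation_threshold: float = 0.8    # Jaccard "close to 1"
    min_population: int = 30              # basins below this are discarded
    dihedral_sigma_thresholds: tuple = (25.0, 80.0)   # stable / ambiguous / free
    angle_sigma_thresholds: tuple = (8.0, 30.0)
    bond_sigma_thresholds: tuple = (0.05, 0.2)
    k_max: int = 8                        # x-means cap
    grid_margin: float = 6.0              # Angstrom around the solute bounding box
    grid_spacing: float = 0.5             # Angstrom
    subsample_repetitions: int = 50       # R
    seed: int = 0
    selections: dict = field(default_factory=dict)  # named atom-index subsets

    def __post_init__(self) -> None:
        if self.window_x < 1 or self.min_domain < 1:
            raise ValueError("window/length parameters must be >= 1")
        if self.grid_spacing <= 0:
            raise ValueError("grid spacing must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        for key in ("dihedral_sigma_thresholds", "angle_sigma_thresholds", "bond_sigma_thresholds"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["selections"] = {k: list(map(int, v)) for k, v in data["selections"].items()}
        for key in ("dihedral_sigma_thresholds", "angle_sigma_thresholds", "bond_sigma_thresholds"):
            data[key] = list(data[key])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)


# ---------------------------------------------------------------------------
# multi-frame XYZ


def read_xyz_trajectory(path) -> Trajectory:
    """Read a multi-frame XYZ file (atom-count line, comment line, atom records)."""
    frames = []
    elements = None
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not any(line.strip() for line in lines):
        raise FormatError(f"{path}: empty XYZ file")
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            natoms = int(lines[pos].split()[0])
        except ValueError as exc:
            raise FormatError(f"{path}: expected atom count at line {pos + 1}") from exc
        if pos + 1 + natoms >= len(lines) + 1 and natoms > 0:
            raise FormatError(f"{path}: truncated frame at line {pos + 1}")
        block = lines[pos + 2: pos + 2 + natoms]
        if len(block) != natoms:
            raise FormatError(f"{path}: truncated frame at line {pos + 1}")
        elems, xyz = [], []
        for ln in block:
            parts = ln.split()
            if len(parts) < 4:
                raise FormatError(f"{path}: bad atom record: {ln!r}")
            elems.append(parts[0])
            try:
                xyz.append([float(parts[1]), float(parts[2]), float(parts[3])])
            except ValueError as exc:
                raise FormatError(f"{path}: non-numeric coordinate in {ln!r}") from exc
        if elements is None:
            elements = elems
        elif elems != elements or natoms != len(elements):
            raise FormatError(f"{path}: inconsistent atoms across frames")
        frames.append(xyz)
        pos += 2 + natoms
    return Trajectory(elements, np.array(frames))


def write_xyz_trajectory(traj: Trajectory, path, comments=None) -> None:
    """Write a multi-frame XYZ file (coordinates printed to 1e-8 Angstrom)."""
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            comment = comments[f] if comments is not None else f"frame {int(traj.frame_ids[f])}"
            fh.write(f"{traj.n_atoms}\n{comment}\n")
            for el, (x, y, z) in zip(traj.elements, traj.coords[f]):
                fh.write(f"{el:<4s} {x:18.8f} {y:18.8f} {z:18.8f}\n")


def write_xyz(elements, coords, path, comment="") -> None:
    """Write a single-structure XYZ file."""
    write_xyz_trajectory(Trajectory(list(elements), np.asarray(coords)[None]), path,
                         comments=[comment])


# ---------------------------------------------------------------------------
# Gaussian cube


def write_cube(values: np.ndarray, origin, spacing, path, comment="basinavg field") -> None:
    """Write a scalar field on a regular orthorhombic grid as a Gaussian cube.

    ``origin`` and ``spacing`` are in Angstrom and are converted to bohr in
    the header; values are emitted in z-fastest order.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 3:
        raise FormatError("cube field must be 3-D")
    spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (3,))
    if np.any(spacing <= 0):
        raise FormatError("cube requires positive, uniform grid spacing")
    origin_b = np.asarray(origin, dtype=float) / BOHR_ANGSTROM
    step_b = spacing / BOHR_ANGSTROM
    nx, ny, nz = values.shape
    with open(path, "w") as fh:
        fh.write(f"{comment}\nregular orthorhombic grid, atomic units\n")
        fh.write(f"{0:5d} {origin_b[0]:12.6f} {origin_b[1]:12.6f} {origin_b[2]:12.6f}\n")
        fh.write(f"{nx:5d} {step_b[0]:12.6f} {0.0:12.6f} {0.0:12.6f}\n")
        fh.write(f"{ny:5d} {0.0:12.6f} {step_b[1]:12.6f} {0.0:12.6f}\n")
        fh.write(f"{nz:5d} {0.0:12.6f} {0.0:12.6f} {step_b[2]:12.6f}\n")
        flat = values.reshape(nx * ny, nz)
        for row in flat:
            for start in range(0, nz, 6):
                fh.write("".join(f" {v: .10E}" for v in row[start:start + 6]) + "\n")


def read_cube(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read a Gaussian cube written by :func:`write_cube`.

    Returns ``(values, origin, spacing)`` with origin/spacing in Angstrom.
    Only orthorhombic axis-aligned grids are supported.
    """
    with open(path) as fh:
        lines = fh.read().split("\n")
    try:
        head = lines[2].split()
        natoms = int(head[0])
        origin = np.array([float(x) for x in head[1:4]]) * BOHR_ANGSTROM
        shape = np.empty(3, dtype=int)
        spacing = np.empty(3)
        for ax in range(3):
            parts = lines[3 + ax].split()
            shape[ax] = int(parts[0])
            vec = np.array([float(x) for x in parts[1:4]])
            off_axis = np.delete(vec, ax)
            if np.any(off_axis != 0.0):
                raise FormatError(f"{path}: non-orthorhombic cube axes unsupported")
            spacing[ax] = vec[ax] * BOHR_ANGSTROM
        body_start = 6 + abs(natoms)
        data = np.fromstring(" ".join(lines[body_start:]), sep=" ")
    except (IndexError, ValueError) as exc:
        raise FormatError(f"{path}: malformed cube file") from exc
    if data.size != np.prod(shape):
        raise FormatError(f"{path}: cube value count mismatch")
    return data.reshape(tuple(shape)), origin, spacing


# ---------------------------------------------------------------------------
# tables


def read_observable_table(path) -> pd.DataFrame:
    """Read a per-frame observable CSV with columns frame, epsilon[, f]."""
    df = pd.read_csv(path)
    cols = {c.strip().lower(): c for c in df.columns}
    if "frame" not in cols or "epsilon" not in cols:
        raise FormatError(f"{path}: need columns 'frame' and 'epsilon'")
    rename = {cols["frame"]: "frame", cols["epsilon"]: "epsilon"}
    if "f" in cols:
        rename[cols["f"]] = "f"
    df = df.rename(columns=rename)[list(dict.fromkeys(rename.values()))]
    if df["frame"].duplicated().any():
        dup = df.loc[df["frame"].duplicated(), "frame"].iloc[0]
        raise FormatError(f"{path}: duplicate frame id {dup}")
    if not np.all(np.isfinite(df["epsilon"].to_numpy(dtype=float))):
        raise FormatError(f"{path}: non-finite epsilon values")
    df["frame"] = df["frame"].astype(int)
    return df.reset_index(drop=True)


def write_observable_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_charge_table(path) -> ChargeTyping:
    """Read a flat TSV charge table with columns: type, Z, q."""
    df = pd.read_csv(path, sep=r"\s+", comment="#",
                     names=["type", "Z", "q"], header=None, dtype={"type": str})
    if df["type"].duplicated().any():
        raise FormatError(f"{path}: duplicate type")
    return ChargeTyping(
        q={t: float(q) for t, q in zip(df["type"], df["q"])},
        Z={t: int(z) for t, z in zip(df["type"], df["Z"])},
    )


def read_connectivity(path):
    """Read per-atom Z-matrix reference triplets (0-based, -1 = absent)."""
    from .zmatrix import Connectivity

    rows = np.loadtxt(path, dtype=int, comments="#", ndmin=2)
    if rows.shape[1] == 4:  # leading atom-index column allowed
        order = np.argsort(rows[:, 0])
        rows = rows[order, 1:]
    if rows.shape[1] != 3:
        raise FormatError(f"{path}: expected 3 or 4 integer columns")
    return Connectivity(rows)


def write_connectivity(connectivity, path) -> None:
    with open(path, "w") as fh:
        fh.write("# atom  bond_ref  angle_ref  dihedral_ref (0-based, -1 = none)\n")
        for i, (b, a, d) in enumerate(connectivity.refs):
            fh.write(f"{i:6d} {b:6d} {a:6d} {d:6d}\n")


def write_basin_csv(partition, path) -> None:
    """Per-frame basin assignment CSV (basin labels 1-based, 0 = discarded)."""
    lab = partition.labels()
    pd.DataFrame({"frame_id": np.arange(partition.n_frames), "basin_label": lab}).to_csv(
        path, index=False
    )


def read_basin_csv(path):
    from .basins import BasinPartition

    df = pd.read_csv(path)
    labels = df.sort_values("frame_id")["basin_label"].to_numpy(dtype=int)
    ks = sorted(set(labels) - {0})
    basins = [np.flatnonzero(labels == k) for k in ks]
    basins.sort(key=lambda b: -b.size)
    return BasinPartition(basins, np.flatnonzero(labels == 0), labels.size)


def write_basin_summary(partition, path, classes=None) -> None:
    summary = {
        "K": partition.n_basins,
        "N_k": [int(n) for n in partition.populations],
        "n_frames": int(partition.n_frames),
        "discarded": [int(f) for f in partition.discarded],
    }
    if classes is not None:
        summary["coordinate_classes"] = {
            repr(cid): {"class": c.label, "stdev": round(float(c.stdev), 6)}
            for cid, c in classes.items()
        }
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=1)
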