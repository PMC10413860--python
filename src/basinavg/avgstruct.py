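"""Per-basin and direct averaged solute structures.

Within a conformational basin the solute oscillates around one metastable
conformation, so its internal coordinates can be averaged arithmetically
(dihedrals in their seam-free range).  Freely rotating groups (methyls) are
handled separately: their pivot dihedral is set to the center of the major
cluster within the basin and the remaining hydrogens are placed at the mean
observed offsets from the pivot -- the trajectory's own spacing, not the
idealized 120 degrees.  "Direct" averaging ignores the basin division; for a
two-conformer coordinate it lands near the transition-state value, which is
exactly the failure mode the basin division avoids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.mixture import GaussianMixture

from .basins import BasinPartition, xmeans_cluster
from .geometry import (
    MolecularGeometry,
    align_trajectory,
    circular_mean_deg,
    dihedral_range_select,
    wrap_to_pm180,
)
from .zmatrix import ZMatrix, ZMatrixSeries, to_cartesian, to_internal

__all__ = [
    "AveragedStructure",
    "RotorGroup",
    "average_internal",
    "place_free_rotors",
    "basin_average_structure",
    "direct_average_structure",
    "detect_rotor_groups",
    "is_bimodal",
]


@dataclass
class RotorGroup:
    """A freely rotating group: pivot atom plus dependent atoms sharing its axis."""

    pivot: int
    dependents: tuple

    def __post_init__(self) -> None:
        self.dependents = tuple(int(d) for d in self.dependents)


@dataclass
class AveragedStructure:
    """An averaged structure: label, averaged internals, reconstructed geometry."""

    label: str
    zmatrix: ZMatrix
    geometry: MolecularGeometry
    n_frames: int
    rotor_assignments: dict = field(default_factory=dict)


def average_internal(zseries: ZMatrixSeries, frames=None) -> ZMatrix:
    """Arithmetically average internal coordinates over the given frames.

    Bonds and angles are plain means; each dihedral is averaged in the range
    chosen by :func:`~basinavg.geometry.dihedral_range_select` on its own
    series and mapped back to (-180, 180].
    """
    idx = np.arange(zseries.n_frames) if frames is None else np.asarray(frames, dtype=int)
    if idx.size < 1:
        raise ValueError("need at least one frame to average")
    if idx.min() < 0 or idx.max() >= zseries.n_frames:
        raise ValueError("frame index out of range")
    bonds = zseries.bonds[idx].mean(axis=0)
    angles = zseries.angles[idx].mean(axis=0)
    dihedrals = np.full(zseries.n_atoms, np.nan)
    for i in range(3, zseries.n_atoms):
        _, transformed = dihedral_range_select(zseries.dihedrals[idx, i])
        dihedrals[i] = wrap_to_pm180(transformed.mean())
    return ZMatrix(zseries.connectivity, list(zseries.elements), bonds, angles, dihedrals)


def place_free_rotors(
    zseries: ZMatrixSeries,
    rotors,
    frames=None,
    seed: int = 0,
    k_max: int = 4,
) -> dict:
    """Dihedral assignments for freely rotating groups within one basin.

    The pivot dihedral is set to the center of its major cluster (x-means on
    the basin's values); each dependent dihedral is placed at the pivot plus
    the circular mean of its observed offset from the pivot over the basin.
    """
    idx = np.arange(zseries.n_frames) if frames is None else np.asarray(frames, dtype=int)
    if idx.size == 0:
        raise ValueError("empty basin")
    assignments: dict = {}
    for rotor in rotors:
        series = zseries.dihedrals[idx, rotor.pivot]
        _, transformed = dihedral_range_select(series)
        clusters = xmeans_cluster(transformed, k_max=k_max, seed=seed,
                                  coord_id=("dihedral", rotor.pivot))
        major = max(clusters, key=lambda c: c.frames.size)
        pivot_value = float(wrap_to_pm180(major.center))
        assignments[rotor.pivot] = pivot_value
        for dep in rotor.dependents:
            offsets = zseries.dihedrals[idx, dep] - zseries.dihedrals[idx, rotor.pivot]
            mean_offset = circular_mean_deg(offsets)
            assignments[dep] = float(wrap_to_pm180(pivot_value + mean_offset))
    return assignments


def detect_rotor_groups(
    classes: dict,
    connectivity,
    clusters: dict | None = None,
    min_wells: int = 3,
) -> list[RotorGroup]:
    """Group dihedral coordinates sharing a rotation axis into free rotors.

    Dihedrals with identical (bond, angle) references rotate about the same
    bond; the lowest atom index becomes the pivot.  An axis group is a free
    rotor when its representative dihedral was classified ``free`` in the
    sigma screening, when its cluster count reaches ``min_wells`` (a
    three-well methyl pattern), or when the axis carries ``min_wells`` or
    more terminal atoms (a methyl-like top) -- the last criterion catches
    skewed well occupancies that dodge the sigma band entirely.
    """
    groups: dict = {}
    for cid, cls in classes.items():
        if cid[0] != "dihedral":
            continue
        atom = cid[1]
        axis = (int(connectivity.refs[atom, 0]), int(connectivity.refs[atom, 1]))
        groups.setdefault(axis, {})[atom] = cls
    bond_parents = set(int(b) for b in connectivity.refs[1:, 0])
    rotors = []
    for axis, members in groups.items():
        atoms = sorted(members)
        rep = atoms[0]
        free = any(c.label == "free" for c in members.values())
        multiwell = (
            clusters is not None
            and ("dihedral", rep) in clusters
            and len(clusters[("dihedral", rep)]) >= min_wells
        )
        terminal_top = (
            len(atoms) >= min_wells and all(a not in bond_parents for a in atoms)
        )
        if free or multiwell or terminal_top:
            rotors.append(RotorGroup(pivot=rep, dependents=tuple(atoms[1:])))
    rotors.sort(key=lambda r: r.pivot)
    return rotors


def basin_average_structure(
    traj,
    basin_frames,
    connectivity,
    rotors=(),
    label: str = "basin",
    reference_frame: int = 0,
    align_subset=None,
    seed: int = 0,
) -> AveragedStructure:
    """Average structure of one conformational basin.

    Frames are Kabsch-aligned to the trajectory's initial geometry, converted
    to internal coordinates, averaged (with free-rotor placement), and the
    averaged Z-matrix is reconstructed in Cartesian space.  Internal
    coordinates are rototranslation invariant, so the alignment exists for
    consistency with the Cartesian environment averaging that reuses it.
    """
    coords = traj.coords if hasattr(traj, "coords") else np.asarray(traj, dtype=float)
    elements = list(traj.elements) if hasattr(traj, "elements") else ["X"] * coords.shape[1]
    idx = np.asarray(basin_frames, dtype=int)
    if idx.size == 0:
        raise ValueError("empty basin")
    if idx.min() < 0 or idx.max() >= coords.shape[0]:
        raise ValueError("basin references unknown frames")
    aligned, _, _ = align_trajectory(coords, reference=reference_frame, subset=align_subset)
    zseries = to_internal(aligned, connectivity, elements=elements)
    zavg = average_internal(zseries, frames=idx)
    assignments = place_free_rotors(zseries, rotors, frames=idx, seed=seed) if rotors else {}
    for atom, value in assignments.items():
        zavg.dihedrals[atom] = value
    geometry = to_cartesian(zavg)
    return AveragedStructure(label, zavg, geometry, int(idx.size), assignments)


def direct_average_structure(
    traj,
    connectivity,
    rotors=(),
    reference_frame: int = 0,
    align_subset=None,
    seed: int = 0,
) -> AveragedStructure:
    """Average structure over the whole trajectory, ignoring basins."""
    coords = traj.coords if hasattr(traj, "coords") else np.asarray(traj, dtype=float)
    return basin_average_structure(
        traj,
        np.arange(coords.shape[0]),
        connectivity,
        rotors=rotors,
        label="direct",
        reference_frame=reference_frame,
        align_subset=align_subset,
        seed=seed,
    )


def is_bimodal(values, min_separation_sigmas: float = 2.0, seed: int = 0) -> bool:
    """Dip-style bimodality check on a 1-D distribution.

    Fits one- and two-component Gaussian mixtures; the distribution is
    called bimodal when the two-component fit wins on BIC *and* the two
    means are separated by more than ``min_separation_sigmas`` of the wider
    component.  Used on theta distributions: a direct-average structure over
    a multi-basin trajectory shows separated peaks, a basin-average over its
    own basin does not.
    """
    v = np.asarray(values, dtype=float).reshape(-1, 1)
    if v.size < 10 or np.ptp(v) < 1e-12:
        return False
    g1 = GaussianMixture(1, random_state=seed).fit(v)
    g2 = GaussianMixture(2, random_state=seed, n_init=3).fit(v)
    if g2.bic(v) >= g1.bic(v):
        return False
    means = g2.means_.ravel()
    sigmas = np.sqrt(g2.covariances_.ravel())
    weights = g2.weights_
    if weights.min() < 0.02:
        return False
    return abs(means[0] - means[1]) > min_separation_sigmas * sigmas.max()
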