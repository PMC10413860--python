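"""Rigid-body superposition, minimized RMSD (theta), and geometric descriptors.

The similarity measure used throughout is the minimized root-mean-square
deviation theta between two structures: the RMSD over a chosen atom subset
after the optimal proper rigid-body superposition (Kabsch algorithm).
Reflections are never allowed, so chirality is preserved.

Dihedral angles live on a circle; series that straddle the +-180 degree seam
are analysed in whichever of the (-180, 180] / [0, 360) ranges gives the
smaller standard deviation, and averages are mapped back to (-180, 180].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MolecularGeometry",
    "DegenerateAlignmentError",
    "kabsch_align",
    "kabsch_rmsd_batch",
    "align_trajectory",
    "theta_set",
    "wrap_to_pm180",
    "dihedral_range_select",
    "circular_mean_deg",
    "compute_bla",
    "bond_lengths",
]


class DegenerateAlignmentError(ValueError):
    """Raised when a superposition subset cannot define a unique rotation."""


@dataclass
class MolecularGeometry:
    """A single structure: element symbols plus Cartesian coordinates in Angstrom."""

    elements: list[str]
    coords: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (n_atoms, 3)")
        if self.coords.shape[0] < 1:
            raise ValueError("geometry needs at least one atom")
        if len(self.elements) != self.coords.shape[0]:
            raise ValueError("elements and coords length mismatch")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def copy(self) -> "MolecularGeometry":
        return MolecularGeometry(list(self.elements), self.coords.copy())


def _resolve_subset(subset, n_atoms: int) -> np.ndarray:
    if subset is None:
        return np.arange(n_atoms)
    idx = np.asarray(subset, dtype=int)
    if idx.ndim != 1 or idx.size == 0:
        raise ValueError("subset must be a non-empty 1-D index list")
    if idx.min() < 0 or idx.max() >= n_atoms:
        raise IndexError("subset index out of range")
    if len(set(idx.tolist())) != idx.size:
        raise ValueError("subset contains duplicate indices")
    return idx


def _check_nondegenerate(centered: np.ndarray) -> None:
    # A unique proper rotation needs >= 3 non-collinear points.
    if centered.shape[0] < 3 or np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise DegenerateAlignmentError(
            "superposition needs at least 3 non-collinear atoms"
        )


def _kabsch_core(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, float]:
    """Optimal proper rotation mapping centered P onto centered Q, plus the RMSD.

    Uses the singular-value decomposition of the covariance matrix with the
    determinant correction that excludes improper rotations.
    """
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    # explicit residual rather than the trace formula: avoids catastrophic
    # cancellation for near-congruent structures
    diff = P @ R.T - Q
    return R, float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))


def kabsch_align(
    mobile: MolecularGeometry,
    reference: MolecularGeometry,
    subset=None,
) -> tuple[MolecularGeometry, float]:
    """Superpose ``mobile`` onto ``reference`` over ``subset``; return (aligned, theta).

    theta is the minimum over proper rotations and translations of the RMSD
    computed on the subset; the optimal transform is applied to *all* atoms of
    the mobile structure.
    """
    idx = _resolve_subset(subset, mobile.n_atoms)
    if reference.n_atoms != mobile.n_atoms and subset is None:
        raise ValueError("atom count mismatch between mobile and reference")
    ridx = _resolve_subset(subset, reference.n_atoms)
    if idx.size != ridx.size:
        raise ValueError("subset size mismatch")
    P = mobile.coords[idx]
    Q = reference.coords[ridx]
    cm_p = P.mean(axis=0)
    cm_q = Q.mean(axis=0)
    _check_nondegenerate(Q - cm_q)
    R, theta = _kabsch_core(P - cm_p, Q - cm_q)
    aligned = (mobile.coords - cm_p) @ R.T + cm_q
    return MolecularGeometry(list(mobile.elements), aligned), theta


def kabsch_rmsd_batch(coords: np.ndarray, reference: np.ndarray, subset=None) -> np.ndarray:
    """Minimized RMSD of every frame in ``coords`` (F, A, 3) against ``reference`` (A, 3)."""
    coords = np.asarray(coords, dtype=float)
    reference = np.asarray(reference, dtype=float)
    idx = _resolve_subset(subset, reference.shape[0])
    Q = reference[idx] - reference[idx].mean(axis=0)
    _check_nondegenerate(Q)
    P = coords[:, idx, :]
    P = P - P.mean(axis=1, keepdims=True)
    H = np.einsum("fai,aj->fij", P, Q)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(np.einsum("fij,fjk->fik", np.transpose(Vt, (0, 2, 1)),
                                        np.transpose(U, (0, 2, 1)))))
    D = np.zeros((coords.shape[0], 3, 3))
    D[:, 0, 0] = 1.0
    D[:, 1, 1] = 1.0
    D[:, 2, 2] = d
    R = np.einsum("fij,fjk,fkl->fil", np.transpose(Vt, (0, 2, 1)), D,
                  np.transpose(U, (0, 2, 1)))
    diff = np.einsum("fai,fji->faj", P, R) - Q[None]
    return np.sqrt(np.mean(np.sum(diff * diff, axis=2), axis=1))


def align_trajectory(
    coords: np.ndarray,
    reference: np.ndarray | int = 0,
    subset=None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Kabsch-align every frame onto a reference structure.

    Returns ``(aligned, rotations, cm_pairs)`` where frame ``f`` of any
    co-moving point set ``x`` (e.g. environment atoms) is mapped by
    ``(x - cm_pairs[f, 0]) @ rotations[f].T + cm_pairs[f, 1]``.
    """
    coords = np.asarray(coords, dtype=float)
    if isinstance(reference, (int, np.integer)):
        reference = coords[int(reference)]
    reference = np.asarray(reference, dtype=float)
    idx = _resolve_subset(subset, reference.shape[0])
    Q = reference[idx] - reference[idx].mean(axis=0)
    _check_nondegenerate(Q)
    cm_q = reference[idx].mean(axis=0)
    n_frames = coords.shape[0]
    aligned = np.empty_like(coords)
    rotations = np.empty((n_frames, 3, 3))
    cm_pairs = np.empty((n_frames, 2, 3))
    for f in range(n_frames):
        P = coords[f, idx]
        cm_p = P.mean(axis=0)
        R, _ = _kabsch_core(P - cm_p, Q)
        aligned[f] = (coords[f] - cm_p) @ R.T + cm_q
        rotations[f] = R
        cm_pairs[f, 0] = cm_p
        cm_pairs[f, 1] = cm_q
    return aligned, rotations, cm_pairs


def apply_alignment(points: np.ndarray, rotations: np.ndarray, cm_pairs: np.ndarray) -> np.ndarray:
    """Apply per-frame alignment transforms to a co-moving point set (F, A, 3)."""
    points = np.asarray(points, dtype=float)
    return np.einsum("fai,fji->faj", points - cm_pairs[:, None, 0, :], rotations) + cm_pairs[:, None, 1, :]


def theta_set(
    average: MolecularGeometry | np.ndarray,
    frames: np.ndarray,
    subset=None,
) -> np.ndarray:
    """One theta value per frame: minimized RMSD of each frame against ``average``.

    ``average`` is typically a basin- or direct-averaged structure and
    ``frames`` the (F, A, 3) coordinates of the (sub)ensemble it represents.
    The distribution of these values measures the compactness of the basin.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[0] == 0:
        raise ValueError("frames must be a non-empty (F, A, 3) array")
    ref = average.coords if isinstance(average, MolecularGeometry) else np.asarray(average)
    return kabsch_rmsd_batch(frames, ref, subset=subset)


# ---------------------------------------------------------------------------
# dihedral range bookkeeping


def wrap_to_pm180(values) -> np.ndarray:
    """Map angles in degrees to the conventional (-180, 180] range."""
    v = np.asarray(values, dtype=float)
    w = ((v + 180.0) % 360.0) - 180.0
    return np.where(w == -180.0, 180.0, w)


def dihedral_range_select(series) -> tuple[str, np.ndarray]:
    """Choose the analysis range for a dihedral series.

    The standard deviation is evaluated in both the (-180, 180] and [0, 360)
    representations; the series is analysed in [0, 360) only when that is
    strictly smaller (ties keep the conventional range).  Returns
    ``(flag, transformed)`` with flag ``"pm180"`` or ``"0-360"``.
    """
    s = np.asarray(series, dtype=float)
    alt = np.mod(s, 360.0)
    if np.std(alt) < np.std(s):
        return "0-360", alt
    return "pm180", s.copy()


def circular_mean_deg(values) -> float:
    """Circular mean of angles in degrees, mapped to (-180, 180]."""
    v = np.radians(np.asarray(values, dtype=float))
    m = np.degrees(np.arctan2(np.mean(np.sin(v)), np.mean(np.cos(v))))
    return float(wrap_to_pm180(m))


# ---------------------------------------------------------------------------
# descriptors


def bond_lengths(coords: np.ndarray, pairs) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    pairs = np.asarray(pairs, dtype=int)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("pairs must have shape (n_bonds, 2)")
    return np.linalg.norm(coords[..., pairs[:, 0], :] - coords[..., pairs[:, 1], :], axis=-1)


def compute_bla(geom: MolecularGeometry | np.ndarray, single_bonds, double_bonds) -> float | np.ndarray:
    """Bond length alternation: mean single-bond length minus mean double-bond length.

    Accepts a single geometry or an (F, A, 3) trajectory (returns one BLA per
    frame).  For conjugated chromophores BLA correlates (roughly linearly)
    with the vertical excitation energy.
    """
    coords = geom.coords if isinstance(geom, MolecularGeometry) else np.asarray(geom)
    if len(np.atleast_2d(single_bonds)) == 0 or len(np.atleast_2d(double_bonds)) == 0:
        raise ValueError("single and double bond lists must be non-empty")
    singles = bond_lengths(coords, single_bonds).mean(axis=-1)
    doubles = bond_lengths(coords, double_bonds).mean(axis=-1)
    out = singles - doubles
    return float(out) if np.ndim(out) == 0 else out
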