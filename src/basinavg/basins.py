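"""Conformational basin detection from per-internal-coordinate trajectories.

Rather than clustering whole structures in an n-dimensional coordinate space,
each internal coordinate's trajectory is analysed on its own: a standard
deviation screening separates freely rotating groups (large sigma) from
stable ones (small sigma); the remaining "ambiguous" coordinates are
clustered either from their time-ordered trajectory (jump / time-domain
detection) or from their value distribution (x-means).  Clusters of
different coordinates whose frame sets nearly coincide (Jaccard ratio close
to 1) signal a collective conformational change and are assembled into
disjoint conformational basins; independent rotors never correlate and are
excluded.  Small basins are discarded rather than averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

__all__ = [
    "CoordClass",
    "CoordCluster",
    "BasinPartition",
    "screen_by_stdev",
    "detect_jumps",
    "time_domains",
    "xmeans_cluster",
    "cluster_correlation",
    "assemble_basins",
    "detect_basins",
]


@dataclass
class CoordClass:
    """Screening verdict for one coordinate: free / stable / ambiguous."""

    coord_id: object
    label: str
    stdev: float


@dataclass
class CoordCluster:
    """One cluster of values of a single coordinate: which frames, which center."""

    coord_id: object
    cluster_label: int
    frames: np.ndarray
    center: float

    def frame_set(self) -> frozenset:
        return frozenset(int(f) for f in self.frames)


@dataclass
class BasinPartition:
    """Disjoint frame-index basins ordered by decreasing population, plus discards.

    Satisfies the partition identity sum_k N_k + |discarded| = N.
    """

    basins: list[np.ndarray]
    discarded: np.ndarray
    n_frames: int

    def __post_init__(self) -> None:
        seen: set[int] = set()
        total = 0
        for b in self.basins:
            s = set(int(f) for f in b)
            if seen & s:
                raise ValueError("basins must be pairwise disjoint")
            seen |= s
            total += len(s)
        disc = set(int(f) for f in self.discarded)
        if seen & disc:
            raise ValueError("discarded frames overlap a basin")
        if total + len(disc) != self.n_frames:
            raise ValueError("basins + discarded must cover all frames exactly once")

    @property
    def populations(self) -> np.ndarray:
        return np.array([len(b) for b in self.basins], dtype=int)

    @property
    def n_basins(self) -> int:
        return len(self.basins)

    def labels(self) -> np.ndarray:
        """Per-frame basin label, 1-based; discarded frames get 0."""
        lab = np.zeros(self.n_frames, dtype=int)
        for k, b in enumerate(self.basins, start=1):
            lab[np.asarray(b, dtype=int)] = k
        return lab


# ---------------------------------------------------------------------------


def screen_by_stdev(series, low: float, high: float, coord_id=None) -> CoordClass:
    """Classify a coordinate by its standard deviation.

    sigma < low: stable chemical group; sigma > high: freely rotating group;
    in between: ambiguous, needs clustering.  Dihedral series should be
    passed *after* :func:`~basinavg.geometry.dihedral_range_select`.
    """
    s = np.asarray(series, dtype=float)
    if s.size < 2:
        raise ValueError("screening needs at least 2 frames")
    if not 0 <= low < high:
        raise ValueError("thresholds must satisfy 0 <= low < high")
    sd = float(np.std(s))
    label = "stable" if sd < low else ("free" if sd > high else "ambiguous")
    return CoordClass(coord_id, label, sd)


def detect_jumps(series, window: int, threshold: float) -> list[int]:
    """Locate jumps by differencing consecutive block means.

    Means are taken over consecutive blocks of ``window`` frames; a jump is
    reported at each block boundary where the absolute change of the block
    mean exceeds ``threshold``.  Resolution is +- one window.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if window < 1:
        raise ValueError("window must be >= 1")
    s = np.asarray(series, dtype=float)
    n_blocks = s.size // window
    if n_blocks < 2:
        raise ValueError("series must contain at least two windows")
    means = s[: n_blocks * window].reshape(n_blocks, window).mean(axis=1)
    jumps = np.flatnonzero(np.abs(np.diff(means)) > threshold)
    return [int((b + 1) * window) for b in jumps]


def time_domains(
    series,
    n_t: int,
    tau: float,
    grouping_threshold: float,
    coord_id=None,
) -> list[CoordCluster]:
    """Cluster a time-ordered series via constant-regime time domains.

    A new domain starts when the running mean over the last ``n_t`` frames
    departs from the current domain's mean by more than ``tau``.  Domains
    whose means differ by less than ``grouping_threshold`` are merged into a
    single (possibly non-contiguous) cluster.  Exploits the time ordering of
    the sampling, unlike distribution clustering.
    """
    if n_t < 1:
        raise ValueError("n_t must be >= 1")
    s = np.asarray(series, dtype=float)
    n = s.size
    domains: list[tuple[int, int]] = []  # [start, end) intervals
    start = 0
    i = n_t
    while i <= n - 1:
        dom_mean = s[start:i].mean()
        recent = s[max(i - n_t + 1, start): i + 1].mean()
        if abs(recent - dom_mean) > tau:
            # domain breaks at the beginning of the departing stretch
            cut = max(i - n_t + 1, start + 1)
            domains.append((start, cut))
            start = cut
            i = cut + n_t
        else:
            i += 1
    domains.append((start, n))

    # group domains with close means (single-linkage on sorted means)
    dom_means = [s[a:b].mean() for a, b in domains]
    order = np.argsort(dom_means)
    groups: list[list[int]] = []
    for di in order:
        if groups and abs(dom_means[di] - np.mean([dom_means[j] for j in groups[-1]])) < grouping_threshold:
            groups[-1].append(di)
        else:
            groups.append([di])
    clusters = []
    for lab, grp in enumerate(groups):
        frames = np.concatenate([np.arange(*domains[j]) for j in grp])
        frames.sort()
        clusters.append(CoordCluster(coord_id, lab, frames, float(s[frames].mean())))
    clusters.sort(key=lambda c: -c.frames.size)
    for lab, c in enumerate(clusters):
        c.cluster_label = lab
    return clusters


def _xmeans_bic(values: np.ndarray, centers: np.ndarray, labels: np.ndarray) -> float:
    """BIC of a hard-assignment 1-D Gaussian mixture (per-cluster variance).

    The classification likelihood with mixing-weight terms is what keeps a
    clean single Gaussian from being split: halving it improves the residual
    variance but pays ln(1/2) per point in weight.
    """
    n = values.size
    k = centers.size
    loglik = 0.0
    for j in range(k):
        member = values[labels == j]
        nj = member.size
        if nj == 0:
            continue
        var = max(float(np.mean((member - centers[j]) ** 2)), 1e-12)
        loglik += nj * (np.log(nj / n) - 0.5 * np.log(2 * np.pi * var) - 0.5)
    n_params = 3 * k - 1  # centers, variances, free weights
    return -2.0 * loglik + n_params * np.log(n)


def xmeans_cluster(values, k_max: int = 8, seed: int = 0, coord_id=None) -> list[CoordCluster]:
    """x-means clustering of a 1-D value distribution.

    Starts from one cluster and recursively splits a cluster in two whenever
    the split strictly improves the BIC, up to ``k_max`` clusters.  k-means++
    seeding under a fixed seed makes the result deterministic; ties break
    toward fewer clusters.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 1 or k_max < 1:
        raise ValueError("need at least one value and k_max >= 1")
    clusters: list[np.ndarray] = [np.arange(v.size)]
    improved = True
    while improved and len(clusters) < k_max:
        improved = False
        next_clusters: list[np.ndarray] = []
        for members in clusters:
            vals = v[members]
            if members.size < 4 or np.ptp(vals) < 1e-12 or len(clusters) + len(next_clusters) >= k_max:
                next_clusters.append(members)
                continue
            km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(vals[:, None])
            lab = km.labels_
            bic_one = _xmeans_bic(vals, np.array([vals.mean()]), np.zeros(vals.size, dtype=int))
            bic_two = _xmeans_bic(vals, km.cluster_centers_.ravel(), lab)
            if bic_two < bic_one - 1e-9 and lab.min() != lab.max():
                next_clusters.append(members[lab == 0])
                next_clusters.append(members[lab == 1])
                improved = True
            else:
                next_clusters.append(members)
        clusters = next_clusters
    out = [
        CoordCluster(coord_id, 0, np.sort(m), float(v[m].mean()))
        for m in clusters
    ]
    out.sort(key=lambda c: -c.frames.size)
    for lab, c in enumerate(out):
        c.cluster_label = lab
    return out


def cluster_correlation(a, b) -> float:
    """Jaccard ratio |a n b| / |a u b| between two frame-id sets."""
    sa, sb = set(int(x) for x in a), set(int(x) for x in b)
    if not sa and not sb:
        raise ValueError("both frame sets are empty")
    return len(sa & sb) / len(sa | sb)


# ---------------------------------------------------------------------------


def assemble_basins(
    coord_clusters: dict,
    correlation_threshold: float,
    min_population: int,
    n_frames: int,
    classes: dict | None = None,
    series: dict | None = None,
) -> BasinPartition:
    """Group correlated per-coordinate clusters into conformational basins.

    ``coord_clusters`` maps coordinate id -> list of :class:`CoordCluster`
    partitioning the frames.  Clusters of different coordinates with Jaccard
    correlation above ``correlation_threshold`` are merged into one candidate
    basin (connected components); coordinates classified ``free`` (rotors, if
    ``classes`` is given) are excluded, as are coordinates whose clusters do
    not correlate with any other coordinate when correlated drivers exist.
    Frames are assigned by majority vote of the driving coordinates'
    memberships; basins below ``min_population`` are discarded.  Basins come
    out ordered by decreasing population.
    """
    if not 0 < correlation_threshold <= 1:
        raise ValueError("correlation threshold must be in (0, 1]")
    # deterministic coordinate order => permutation invariance
    coord_ids = sorted(coord_clusters.keys(), key=repr)
    eligible = []
    for cid in coord_ids:
        if classes is not None and cid in classes and getattr(classes[cid], "label", classes[cid]) == "free":
            continue
        if len(coord_clusters[cid]) >= 2:
            eligible.append(cid)

    if not eligible:
        return BasinPartition([np.arange(n_frames)], np.array([], dtype=int), n_frames)

    nodes = [(cid, i) for cid in eligible for i in range(len(coord_clusters[cid]))]
    fsets = {(cid, i): coord_clusters[cid][i].frame_set() for cid, i in nodes}
    # union-find over clusters joined across coordinates
    parent = {nd: nd for nd in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[rx] = ry

    correlated_coords: set = set()
    for ii, nd_a in enumerate(nodes):
        for nd_b in nodes[ii + 1:]:
            if nd_a[0] == nd_b[0]:
                continue
            sa, sb = fsets[nd_a], fsets[nd_b]
            if not sa and not sb:
                continue
            if len(sa & sb) / len(sa | sb) >= correlation_threshold:
                union(nd_a, nd_b)
                correlated_coords.add(nd_a[0])
                correlated_coords.add(nd_b[0])

    if correlated_coords:
        drivers = sorted(correlated_coords, key=repr)
    elif len(eligible) == 1:
        drivers = eligible
    else:
        # several switching coordinates, none correlated: no collective change
        drivers = []

    if not drivers:
        return BasinPartition([np.arange(n_frames)], np.array([], dtype=int), n_frames)

    driver_nodes = [nd for nd in nodes if nd[0] in drivers]
    components: dict = {}
    for nd in driver_nodes:
        components.setdefault(find(nd), []).append(nd)
    comp_list = sorted(components.values(), key=lambda mem: (-sum(len(fsets[nd]) for nd in mem), repr(mem)))

    # majority vote of driver-cluster memberships per frame
    votes = np.zeros((len(comp_list), n_frames), dtype=int)
    for ci, members in enumerate(comp_list):
        for nd in members:
            votes[ci, list(fsets[nd])] += 1
    assignment = np.argmax(votes, axis=0)  # argmax takes the first (largest) component on ties
    unvoted = votes.sum(axis=0) == 0
    if np.any(unvoted) and series is not None:
        # nearest basin by coordinate distance to the component's cluster centers
        centers = np.array([
            [np.mean([coord_clusters[cid][i].center for cid, i in members if cid == d] or [np.nan])
             for d in drivers]
            for members in comp_list
        ])
        for f in np.flatnonzero(unvoted):
            point = np.array([series[d][f] for d in drivers])
            dist = np.nansum(np.abs(centers - point[None, :]), axis=1)
            assignment[f] = int(np.argmin(dist))

    raw = [np.flatnonzero(assignment == ci) for ci in range(len(comp_list))]
    raw = [b for b in raw if b.size > 0]
    raw.sort(key=lambda b: -b.size)
    kept = [b for b in raw if b.size >= min_population]
    dropped = [b for b in raw if b.size < min_population]
    if not kept:  # everything tiny: keep the largest rather than discard all
        kept, dropped = raw[:1], raw[1:]
    discarded = np.sort(np.concatenate(dropped)) if dropped else np.array([], dtype=int)
    return BasinPartition(kept, discarded, n_frames)


# ---------------------------------------------------------------------------
# orchestration


def detect_basins(zseries, config, time_ordered: bool = True):
    """Full per-coordinate pipeline: range-select, screen, cluster, assemble.

    ``zseries`` is a :class:`~basinavg.zmatrix.ZMatrixSeries`; ``config`` a
    :class:`~basinavg.trajio.RunConfig`.  Returns ``(partition, diagnostics)``
    where diagnostics carries per-coordinate classes, selected dihedral
    ranges, and clusters.  With ``time_ordered`` (default) ambiguous
    coordinates are clustered from time domains; otherwise pure x-means on
    the value distribution is used.

    Dihedrals sharing a rotation axis (identical bond and angle references,
    e.g. the three hydrogens of a methyl) describe the same torsion up to a
    constant offset; only the lowest-atom representative per axis enters the
    clustering and basin assembly, so same-axis redundancy can never outvote
    a genuine collective change.
    """
    from .geometry import dihedral_range_select

    classes: dict = {}
    clusters: dict = {}
    series_used: dict = {}
    ranges: dict = {}
    n_frames = zseries.n_frames

    axis_rep: dict = {}
    redundant: set = set()
    axis_members: dict = {}
    for i in range(3, zseries.n_atoms):
        axis = (int(zseries.connectivity.refs[i, 0]), int(zseries.connectivity.refs[i, 1]))
        axis_members.setdefault(axis, []).append(i)
        if axis in axis_rep:
            redundant.add(("dihedral", i))
        else:
            axis_rep[axis] = i
    # methyl-like tops: >= 3 dihedrals about one axis, all terminal atoms.
    # Their torsion is rotor motion, not conformerism, so they never define
    # basins even when a skewed well occupancy dodges the 'free' sigma band.
    bond_parents = set(int(b) for b in zseries.connectivity.refs[1:, 0])
    rotor_axes = {
        axis for axis, members in axis_members.items()
        if len(members) >= 3 and all(m not in bond_parents for m in members)
    }
    rotor_reps = {("dihedral", axis_rep[axis]) for axis in rotor_axes}

    kinds = (
        [("bond", i) for i in range(1, zseries.n_atoms)]
        + [("angle", i) for i in range(2, zseries.n_atoms)]
        + [("dihedral", i) for i in range(3, zseries.n_atoms)]
    )
    for kind, i in kinds:
        if kind == "bond":
            s = zseries.bonds[:, i]
            low, high = config.bond_sigma_thresholds
            tau, grp = config.jump_threshold_ang, config.grouping_threshold_ang
        elif kind == "angle":
            s = zseries.angles[:, i]
            low, high = config.angle_sigma_thresholds
            tau, grp = config.jump_threshold_deg, config.grouping_threshold_deg
        else:
            flag, s = dihedral_range_select(zseries.dihedrals[:, i])
            ranges[(kind, i)] = flag
            low, high = config.dihedral_sigma_thresholds
            tau, grp = config.jump_threshold_deg, config.grouping_threshold_deg
        cid = (kind, i)
        cls = screen_by_stdev(s, low, high, coord_id=cid)
        classes[cid] = cls
        series_used[cid] = s
        if cls.label != "ambiguous" or cid in redundant or cid in rotor_reps:
            continue
        if time_ordered:
            clusters[cid] = time_domains(s, config.min_domain, tau, grp, coord_id=cid)
        else:
            clusters[cid] = xmeans_cluster(s, k_max=config.k_max, seed=config.seed, coord_id=cid)

    partition = assemble_basins(
        clusters,
        config.correlation_threshold,
        config.min_population,
        n_frames,
        classes=classes,
        series=series_used,
    )
    diagnostics = {
        "classes": classes,
        "clusters": clusters,
        "ranges": ranges,
        "series": series_used,
        "redundant": redundant,
        "rotor_axes": rotor_axes,
    }
    return partition, diagnostics
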