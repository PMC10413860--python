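"""Ensemble and basin-weighted observable averaging and convergence analysis.

The reference value of an observable (here: vertical excitation energy
epsilon in eV and oscillator strength f) is the plain mean over all sampled
frames ("ensemble averaging").  Basin-based geometric averaging replaces the
per-frame values of basin k by the single value computed on the basin's
averaged structure, then combines basins with population weights N_k.  The
partition identity guarantees that population-weighting the *subensemble
means* recovers the full-ensemble mean exactly.

The random-subsampling analysis measures how many randomly selected frames
an explicit ensemble average needs before its ~95% confidence band (mean
+- 2 sigma over replicates) excludes a given reference value; that critical
size s_c is what geometric averaging competes against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import KBOLTZ_EV

__all__ = [
    "ShiftStats",
    "SubsampleCurve",
    "ensemble_average",
    "basin_weighted_average",
    "boltzmann_weights",
    "error_delta",
    "shift_error_stats",
    "bla_bin",
    "incremental_subsample",
    "critical_sample_size",
    "bootstrap_mean_error",
    "oscillator_weighted_histogram",
]


def _epsilon_and_f(table):
    """Accept a DataFrame with epsilon[, f] columns or a plain array."""
    if hasattr(table, "columns"):
        eps = table["epsilon"].to_numpy(dtype=float)
        f = table["f"].to_numpy(dtype=float) if "f" in table.columns else None
        frames = table["frame"].to_numpy(dtype=int) if "frame" in table.columns else np.arange(eps.size)
        return eps, f, frames
    eps = np.asarray(table, dtype=float)
    return eps, None, np.arange(eps.size)


def ensemble_average(table, frames=None) -> tuple[float, float | None]:
    """Unweighted arithmetic mean of (epsilon, f) over a frame subset."""
    eps, f, frame_ids = _epsilon_and_f(table)
    if frames is None:
        sel = np.arange(eps.size)
    else:
        wanted = np.asarray(frames, dtype=int)
        if wanted.size == 0:
            raise ValueError("empty frame subset")
        lookup = {int(fr): i for i, fr in enumerate(frame_ids)}
        try:
            sel = np.array([lookup[int(fr)] for fr in wanted])
        except KeyError as exc:
            raise KeyError(f"frame {exc.args[0]} not in table") from exc
    if sel.size == 0:
        raise ValueError("empty frame subset")
    return float(eps[sel].mean()), (float(f[sel].mean()) if f is not None else None)


def basin_weighted_average(values, weights) -> float:
    """Population-weighted average sum_k N_k v_k / sum_k N_k.

    The denominator is the sum over the basins actually used, so discarded
    frames never dilute the average.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.shape != w.shape:
        raise ValueError("values and weights must have equal length")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if w.sum() <= 0:
        raise ValueError("weights must sum to a positive value")
    return float(np.sum(w * v) / np.sum(w))


def boltzmann_weights(G, T: float, units: str = "eV") -> np.ndarray:
    """Normalized Boltzmann weights w_k ~ exp(-G_k / kT) of basin free energies."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    G = np.asarray(G, dtype=float)
    if units != "eV":
        raise ValueError("free energies are expected in eV")
    x = -(G - G.min()) / (KBOLTZ_EV * T)
    w = np.exp(x)
    return w / w.sum()


def error_delta(geometric: float, ensemble: float) -> float:
    """Geometric-averaging error Delta = geometric value - ensemble value."""
    return geometric - ensemble


@dataclass
class ShiftStats:
    """Per-basin solvatochromic-shift errors (meV) and their summary statistics."""

    errors_mev: np.ndarray
    mae_mev: float
    range_mev: tuple          # (most negative, least negative/largest)
    relative_pct: np.ndarray  # per-basin |error| / |ensemble shift| in percent
    mean_relative_pct: float
    excluded: list = field(default_factory=list)  # basins with zero ensemble shift


def shift_error_stats(delta_iso, delta_emb, ensemble_shift) -> ShiftStats:
    """Error statistics of geometric averaging on the solvatochromic shift.

    Per basin, the shift error is Delta_eps^emb - Delta_eps^iso (the
    embedded-minus-isolated error difference, in meV), and the relative
    error divides it by the subensemble's own solvatochromic shift
    <eps^emb>_k - <eps^iso>_k.  Basins with zero ensemble shift are excluded
    from the relative statistic and reported.
    """
    d_iso = np.asarray(delta_iso, dtype=float)
    d_emb = np.asarray(delta_emb, dtype=float)
    shift = np.asarray(ensemble_shift, dtype=float)
    if not (d_iso.shape == d_emb.shape == shift.shape):
        raise ValueError("per-basin inputs must be paired")
    errors_mev = (d_emb - d_iso) * 1000.0
    nonzero = shift != 0.0
    excluded = [int(i) for i in np.flatnonzero(~nonzero)]
    rel = np.abs(errors_mev[nonzero] / (shift[nonzero] * 1000.0)) * 100.0
    return ShiftStats(
        errors_mev=errors_mev,
        mae_mev=float(np.mean(np.abs(errors_mev))),
        range_mev=(float(errors_mev.min()), float(errors_mev.max())),
        relative_pct=rel,
        mean_relative_pct=float(rel.mean()) if rel.size else float("nan"),
        excluded=excluded,
    )


def bla_bin(bla_values, n_bins: int = 6, partition=None, min_population: int = 0):
    """Group frames into equal-width BLA bins, optionally split by basin.

    Bins span [min, max] of the BLA values, right-open with the last bin
    closed.  Returns ``(edges, groups)`` where groups maps
    ``(bin_index, basin_label)`` -> frame-index array (basin label 0 when no
    partition is given; discarded frames are left out).  Groups below
    ``min_population`` are retained but reported -- callers decide.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    bla = np.asarray(bla_values, dtype=float)
    if np.unique(bla).size < 2:
        raise ValueError("need at least 2 distinct BLA values to bin")
    edges = np.linspace(bla.min(), bla.max(), n_bins + 1)
    bin_idx = np.clip(np.searchsorted(edges, bla, side="right") - 1, 0, n_bins - 1)
    labels = partition.labels() if partition is not None else np.ones(bla.size, dtype=int)
    groups = {}
    for b in range(n_bins):
        for k in sorted(set(labels.tolist()) - {0}):
            sel = np.flatnonzero((bin_idx == b) & (labels == k))
            if sel.size:
                groups[(b, k)] = sel
    flagged = [key for key, sel in groups.items() if sel.size < min_population]
    return edges, groups, flagged


@dataclass
class SubsampleCurve:
    """Replicate statistics of incrementally grown random subensembles.

    ``mu[s-1]`` and ``sigma[s-1]`` are the mean and standard deviation over
    replicates of the s-frame running mean; the band is mu +- 2 sigma (a
    ~95% confidence interval under normality).  At s = N every replicate
    holds the full ensemble, so the band has zero width.
    """

    sizes: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    n_replicates: int
    seed: int
    replicate_means: np.ndarray | None = None

    @property
    def lower(self) -> np.ndarray:
        return self.mu - 2.0 * self.sigma

    @property
    def upper(self) -> np.ndarray:
        return self.mu + 2.0 * self.sigma


def incremental_subsample(table, R: int, seed: int = 0, keep_replicates: bool = False) -> SubsampleCurve:
    """Random incremental subsampling of the per-frame observable.

    For each of R replicates the N frames are taken in an independent random
    order; the running mean after s frames is the ensemble average of a
    random s-subensemble.  Because the s = N set is the full ensemble for
    every replicate, its running mean is assigned the full-ensemble value
    exactly (no permutation-order rounding), making sigma_N identically 0.
    """
    if R < 2:
        raise ValueError("need at least 2 replicates")
    eps, _, _ = _epsilon_and_f(table)
    n = eps.size
    rng = np.random.default_rng(seed)
    means = np.empty((R, n))
    full_mean = float(eps.mean())
    sizes = np.arange(1, n + 1)
    for r in range(R):
        perm = rng.permutation(n)
        means[r] = np.cumsum(eps[perm]) / sizes
        means[r, -1] = full_mean
    mu = means.mean(axis=0)
    sigma = means.std(axis=0, ddof=0)
    # every replicate's s = N value is the same float, so the dispersion is
    # identically zero; bypass the rounding of numpy's two-pass std there
    mu[-1] = full_mean
    sigma[-1] = 0.0
    return SubsampleCurve(sizes, mu, sigma, R, seed,
                          replicate_means=means if keep_replicates else None)


def critical_sample_size(curve: SubsampleCurve, reference: float) -> dict:
    """Critical subensemble size s_c against a reference value.

    ``s_sustained`` is the smallest s such that the 2-sigma band excludes
    the reference for *all* larger sizes (robust to noise-driven early
    crossings); ``s_first`` is the first exclusion.  When the band contains
    the reference all the way to s = N (e.g. the reference equals the
    full-ensemble mean), s_c = N and the result is flagged.
    """
    outside = (reference < curve.lower) | (reference > curve.upper)
    n = curve.sizes[-1]
    if not outside.any():
        return {"s_sustained": int(n), "s_first": int(n), "never_excluded": True}
    inside_idx = np.flatnonzero(~outside)
    s_sustained = 1 if inside_idx.size == 0 else int(curve.sizes[inside_idx[-1]] + 1)
    s_sustained = min(s_sustained, int(n))
    return {
        "s_sustained": s_sustained,
        "s_first": int(curve.sizes[np.argmax(outside)]),
        "never_excluded": False,
    }


def bootstrap_mean_error(values, n_boot: int = 1000, seed: int = 0) -> float:
    """Nonparametric bootstrap standard error of the mean."""
    v = np.asarray(values, dtype=float)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, v.size, size=(n_boot, v.size))
    return float(v[idx].mean(axis=1).std(ddof=0))


def oscillator_weighted_histogram(eps, f, bins=50):
    """Histogram of excitation energies weighted by oscillator strength.

    A plotting device for spectra-like displays; the ensemble averages
    themselves are plain means.
    """
    eps = np.asarray(eps, dtype=float)
    f = np.asarray(f, dtype=float)
    hist, edges = np.histogram(eps, bins=bins, weights=f)
    return hist, edges
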