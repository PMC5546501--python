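"""Significance machinery for nanoclustering curves.

Three pieces: pointwise Monte-Carlo envelopes under complete spatial
randomness (CSR), averaging of replicated per-image L(r)-r curves into a
condition curve, and a bootstrap test comparing two conditions via the
integrated squared difference of their mean curves.

The envelope conditions on the observed number of points per image (a
binomial process with exactly n points, the usual practice when testing a
single observed pattern against CSR).  Envelope bounds are pointwise order
statistics, not simultaneous bands; a max-deviation global envelope is
available behind a flag for sensitivity analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .point_patterns import Window
from .ripley import KCurve, RGrid, k_function

__all__ = [
    "Envelope",
    "GroupComparison",
    "csr_envelope",
    "exceeds_envelope",
    "average_curves",
    "bootstrap_compare",
]

#: r-band (nm) where nanocluster signal lives; used for classification and
#: for the bootstrap statistic unless overridden.
DEFAULT_R_BAND = (5.0, 100.0)


@dataclass
class Envelope:
    """Pointwise CSR bounds for L(r)-r at a stated confidence level."""

    rgrid: RGrid
    lower: np.ndarray
    upper: np.ndarray
    level: float
    n_simulations: int
    conditioning_n: int
    seed: int | None = None
    global_envelope: bool = False

    def __post_init__(self) -> None:
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        if self.lower.shape != self.rgrid.radii.shape or self.upper.shape != self.rgrid.radii.shape:
            raise ValueError("bounds must match the radius grid")
        if np.any(self.lower > self.upper):
            raise ValueError("lower bound exceeds upper bound")


@dataclass
class GroupComparison:
    """Bootstrap comparison of two groups of per-image curves."""

    statistic: float
    p_value: float
    n_bootstrap: int
    seed: int | None
    r_band: tuple[float, float]
    n_a: int
    n_b: int


def _min_simulations(level: float) -> int:
    # smallest B with a resolvable (1-level)/2 tail: (B+1)*(1-level)/2 >= 1
    return math.ceil(2.0 / (1.0 - level)) - 1


def _simulate_l_curves(
    n: int,
    window: Window,
    rgrid: RGrid,
    n_simulations: int,
    rng: np.random.Generator,
    correction: str,
) -> np.ndarray:
    from .synthetic import simulate_csr

    curves = np.empty((n_simulations, len(rgrid)))
    for s in range(n_simulations):
        pat = simulate_csr(n, window, rng=rng)
        curves[s] = k_function(pat, rgrid, correction).l_values
    return curves


def csr_envelope(
    n: int,
    window: Window | None = None,
    rgrid: RGrid | None = None,
    n_simulations: int = 199,
    level: float = 0.99,
    seed: int | None = None,
    *,
    correction: str = "isotropic",
    global_envelope: bool = False,
    rng: np.random.Generator | None = None,
) -> Envelope:
    """Monte-Carlo CSR envelope for L(r)-r, conditioned on n points.

    Simulates ``n_simulations`` CSR patterns with exactly ``n`` points in the
    window, computes each L(r)-r, and returns pointwise bounds.  The bounds
    are the k-th smallest and k-th largest simulated values per radius with
    k = floor((B+1)(1-level)/2), giving exact pointwise coverage
    (B+1-2k)/(B+1) for a fresh CSR pattern.  Deterministic given ``seed``.
    """
    if n < 2:
        raise ValueError("envelope requires n >= 2 points")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    b_min = _min_simulations(level)
    if n_simulations < b_min:
        raise ValueError(
            f"n_simulations={n_simulations} cannot resolve level {level}; "
            f"need at least {b_min}"
        )
    window = window or Window()
    rgrid = rgrid or RGrid()
    if rng is None:
        rng = np.random.default_rng(seed)

    curves = _simulate_l_curves(n, window, rgrid, n_simulations, rng, correction)
    k = int((n_simulations + 1) * (1.0 - level) / 2.0)
    k = max(k, 1)
    if global_envelope:
        # symmetric max-deviation band: scale the pointwise std by the
        # level-quantile of the max standardised deviation across r
        mean = curves.mean(axis=0)
        sd = curves.std(axis=0, ddof=1)
        sd = np.where(sd > 0, sd, np.inf)
        dev = np.max(np.abs(curves - mean) / sd, axis=1)
        c = np.sort(dev)[min(int(level * n_simulations), n_simulations - 1)]
        sd = np.where(np.isfinite(sd), sd, 0.0)
        lower, upper = mean - c * sd, mean + c * sd
    else:
        srt = np.sort(curves, axis=0)
        lower = srt[k - 1]
        upper = srt[n_simulations - k]
    return Envelope(rgrid, lower, upper, level, n_simulations, n,
                    seed=seed, global_envelope=global_envelope)


def exceeds_envelope(
    curve: KCurve,
    envelope: Envelope,
    r_band: tuple[float, float] = DEFAULT_R_BAND,
) -> dict:
    """Classify a curve against a CSR envelope.

    Returns per-radius above/below flags and a summary over the report band:
    'clustered' if L(r)-r strictly exceeds the upper bound at any radius in
    the band, else 'dispersed' if strictly below the lower bound, else
    'random'.  Ties at the boundary count as inside (strict inequality).
    """
    if not np.array_equal(curve.rgrid.radii, envelope.rgrid.radii):
        raise ValueError("curve and envelope use different radius grids")
    l = curve.l_values
    above = l > envelope.upper
    below = l < envelope.lower
    band = curve.rgrid.band_mask(*r_band)
    if np.any(above & band):
        summary = "clustered"
    elif np.any(below & band):
        summary = "dispersed"
    else:
        summary = "random"
    return {"above": above, "below": below, "band": band, "classification": summary}


def _check_shared_grid(curves: list[KCurve]) -> RGrid:
    if not curves:
        raise ValueError("empty curve group")
    grid = curves[0].rgrid
    for c in curves[1:]:
        if not np.array_equal(c.rgrid.radii, grid.radii):
            raise ValueError("curves use different radius grids")
    return grid


def _group_weights(curves: list[KCurve], weighting: str) -> np.ndarray:
    if weighting == "equal":
        w = np.ones(len(curves))
    elif weighting == "by_point_count":
        w = np.array([float(c.n) for c in curves])
        if w.sum() <= 0:
            w = np.ones(len(curves))
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    return w / w.sum()


def average_curves(
    group: list[KCurve], weighting: str = "by_point_count"
) -> KCurve:
    """Pointwise weighted mean of a group of curves sharing one grid.

    ``by_point_count`` (default) weights each image by its gold count, since
    patterns with more particles give less noisy curves; ``equal`` averages
    images uniformly.
    """
    grid = _check_shared_grid(group)
    w = _group_weights(group, weighting)
    k_mean = np.einsum("i,ij->j", w, np.array([c.k_values for c in group]))
    l_mean = np.einsum("i,ij->j", w, np.array([c.l_values for c in group]))
    total_n = int(sum(c.n for c in group))
    condition = group[0].condition if len({c.condition for c in group}) == 1 else ""
    return KCurve(grid, k_mean, l_mean, n=total_n,
                  image_id=f"mean_of_{len(group)}", condition=condition)


def _band_statistic(
    la: np.ndarray, lb: np.ndarray, radii: np.ndarray, band: np.ndarray
) -> float:
    diff2 = (la - lb) ** 2
    return float(np.trapezoid(diff2[band], radii[band]))


def bootstrap_compare(
    group_a: list[KCurve],
    group_b: list[KCurve],
    n_bootstrap: int = 1000,
    seed: int | None = None,
    r_band: tuple[float, float] = DEFAULT_R_BAND,
    *,
    weighting: str = "by_point_count",
    rng: np.random.Generator | None = None,
) -> GroupComparison:
    """Bootstrap test for a difference between two conditions' mean curves.

    The statistic is T = integral over the r-band of
    (mean_a L(r)-r  -  mean_b L(r)-r)^2 dr (trapezoid rule on the grid).
    The null distribution is built by pooling all per-image curves and
    resampling two groups of the original sizes with replacement
    ``n_bootstrap`` times; the p-value uses the add-one convention
    p = (1 + #{T* >= T_obs}) / (1 + n_bootstrap), so p >= 1/(1+B) always.
    Deterministic given ``seed``.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 curves")
    if n_bootstrap < 99:
        raise ValueError("n_bootstrap must be at least 99")
    grid = _check_shared_grid(list(group_a) + list(group_b))
    radii = grid.radii
    band = grid.band_mask(*r_band)
    if not np.any(band):
        raise ValueError(f"r_band {r_band} contains no grid radii")

    la = average_curves(group_a, weighting).l_values
    lb = average_curves(group_b, weighting).l_values
    t_obs = _band_statistic(la, lb, radii, band)

    pooled = list(group_a) + list(group_b)
    pool_l = np.array([c.l_values for c in pooled])
    if weighting == "by_point_count":
        pool_w = np.array([float(c.n) for c in pooled])
        if pool_w.sum() <= 0:
            pool_w = np.ones(len(pooled))
    else:
        pool_w = np.ones(len(pooled))

    if rng is None:
        rng = np.random.default_rng(seed)
    na, nb = len(group_a), len(group_b)
    n_pool = na + nb
    idx_a = rng.integers(0, n_pool, size=(n_bootstrap, na))
    idx_b = rng.integers(0, n_pool, size=(n_bootstrap, nb))

    def _resampled_means(idx: np.ndarray) -> np.ndarray:
        w = pool_w[idx]  # (B, m)
        w = w / w.sum(axis=1, keepdims=True)
        return np.einsum("bm,bmr->br", w, pool_l[idx])

    ma = _resampled_means(idx_a)
    mb = _resampled_means(idx_b)
    diff2 = (ma - mb) ** 2
    t_star = np.trapezoid(diff2[:, band], radii[band], axis=1)
    p = (1.0 + np.count_nonzero(t_star >= t_obs)) / (1.0 + n_bootstrap)
    return GroupComparison(t_obs, float(p), n_bootstrap, seed,
                           (float(r_band[0]), float(r_band[1])), na, nb)
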