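"""Within-site spatial structure: Mantel permutation test and semivariogram.

Spatial autocorrelation in infestation violates the independence assumption
behind sequential-sampling stopping rules, so a site-level test for it is a
standard pre-sampling diagnostic.  The Mantel statistic correlates the
tree-to-tree geographic distances with the corresponding infestation
differences; significance comes from permuting tree labels.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .site_data import SiteSample

__all__ = ["MantelResult", "Semivariogram", "mantel_test", "semivariogram"]

#: Sites this small are tested by exact enumeration of all N! relabellings.
EXACT_ENUMERATION_MAX_N = 7


@dataclass(frozen=True)
class MantelResult:
    """Mantel correlation between geographic and infestation distances."""

    r: float
    p: float
    n_perm: int
    n_trees: int


@dataclass
class Semivariogram:
    """Binned empirical semivariance of infestation by lag distance.

    ``gamma`` is NaN for bins with no pairs (``pair_counts`` 0).
    """

    bin_edges: np.ndarray
    gamma: np.ndarray
    pair_counts: np.ndarray

    @property
    def bin_centres(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def _mantel_r_fixed(geo_c: np.ndarray, geo_norm: float,
                    inf_v: np.ndarray, inf_mean: float, inf_norm: float) -> float:
    # Pearson r where the infestation vector's mean/norm are permutation-
    # invariant (relabelling permutes pairs bijectively).
    return float(np.dot(geo_c, inf_v - inf_mean) / (geo_norm * inf_norm))


def mantel_test(site: SiteSample, n_perm: int = 9999, seed: int = 0) -> MantelResult:
    """One-tailed Mantel permutation test for positive spatial association.

    The geographic matrix holds Euclidean distances between tree positions;
    the infestation matrix holds absolute differences in percent galled.
    ``r`` is the Pearson correlation over the n(n-1)/2 unordered pairs, and
    ``p`` the +1-corrected one-tailed probability of an equal or larger r
    under random relabelling of trees.  For sites of at most
    ``EXACT_ENUMERATION_MAX_N`` trees all N! relabellings are enumerated
    instead of sampled.
    """
    n = site.n_trees
    if n < 4:
        raise ValueError("Mantel test needs at least 4 trees")
    pct = site.pct_values()
    if np.ptp(pct) == 0:
        raise ValueError("zero-variance distance vector: infestation is constant")

    geo = pdist(site.coords())
    inf_sq = squareform(pdist(pct[:, None], metric="cityblock"))
    iu = np.triu_indices(n, k=1)

    geo_c = geo - geo.mean()
    geo_norm = float(np.linalg.norm(geo_c))
    inf_v = inf_sq[iu]
    inf_mean = float(inf_v.mean())
    inf_norm = float(np.linalg.norm(inf_v - inf_mean))
    r_obs = _mantel_r_fixed(geo_c, geo_norm, inf_v, inf_mean, inf_norm)

    if n <= EXACT_ENUMERATION_MAX_N:
        n_all = math.factorial(n)
        ge = 0
        for perm in itertools.permutations(range(n)):
            v = inf_sq[np.ix_(perm, perm)][iu]
            if _mantel_r_fixed(geo_c, geo_norm, v, inf_mean, inf_norm) >= r_obs - 1e-12:
                ge += 1
        # identity permutation is in the enumeration, so p = ge / N!
        return MantelResult(r=r_obs, p=ge / n_all, n_perm=n_all - 1, n_trees=n)

    rng = np.random.default_rng(seed)
    ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        v = inf_sq[np.ix_(perm, perm)][iu]
        if _mantel_r_fixed(geo_c, geo_norm, v, inf_mean, inf_norm) >= r_obs:
            ge += 1
    p = (1 + ge) / (n_perm + 1)
    return MantelResult(r=r_obs, p=p, n_perm=n_perm, n_trees=n)


def semivariogram(
    site: SiteSample,
    bin_width: float = 10.0,
    max_lag: float | None = None,
) -> Semivariogram:
    """Empirical semivariogram of percent galling.

    gamma(h) = (1 / (2 |N(h)|)) * sum over pairs in the bin of the squared
    infestation difference.  Defaults: 10 m bins (the sampling-grid spacing)
    up to half the maximum pairwise distance.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    d = pdist(site.coords())
    pct = site.pct_values()
    sq = pdist(pct[:, None], metric="sqeuclidean")
    if max_lag is None:
        max_lag = float(d.max()) / 2.0

    n_bins = max(1, int(np.ceil(max_lag / bin_width)))
    edges = np.arange(n_bins + 1, dtype=float) * bin_width
    # half-open bins [lo, hi); a pair exactly at the top edge joins the last bin
    idx = np.searchsorted(edges, d, side="right") - 1
    idx[d == edges[-1]] = n_bins - 1
    keep = (idx >= 0) & (idx < n_bins)

    counts = np.bincount(idx[keep], minlength=n_bins)
    sums = np.bincount(idx[keep], weights=sq[keep], minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        gamma = sums / (2.0 * counts)
    gamma[counts == 0] = np.nan
    return Semivariogram(bin_edges=edges, gamma=gamma, pair_counts=counts)
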