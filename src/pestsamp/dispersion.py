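"""Negative binomial fitting and k-estimability diagnostics.

Aggregated pest counts are classically described by the negative binomial
distribution, parameterized by its mean mu and the clumping parameter k
(small k = strong aggregation, k -> infinity = Poisson).  Sequential
sampling plans need k, but k is notoriously hard to estimate from modest
samples; the subsampling study here quantifies that difficulty for a given
site by refitting k to many small with-replacement draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .site_data import SiteSample

__all__ = [
    "NegBinFit",
    "GofResult",
    "KSubsampleStudy",
    "fit_negbin",
    "lr_goodness_of_fit",
    "subsample_k_study",
]

_LOGK_LO, _LOGK_HI = np.log(1e-4), np.log(1e6)


@dataclass(frozen=True)
class NegBinFit:
    """Maximum-likelihood negative binomial fit.

    ``mu`` is the fitted mean (equal to the sample mean at the optimum) and
    ``k`` the clumping parameter; ``converged`` is False whenever the data
    are degenerate or the optimum sits on the parameter boundary (the
    near-Poisson limit included), mirroring the fit failures that occur with
    small low-density samples in the field.
    """

    mu: float
    k: float
    loglik: float
    converged: bool
    n_obs: int

    def pmf(self, x) -> np.ndarray:
        return stats.nbinom.pmf(x, self.k, self.k / (self.k + self.mu))


@dataclass(frozen=True)
class GofResult:
    """Likelihood-ratio (G^2) goodness-of-fit against a fitted NB."""

    g2: float
    df: int
    p: float
    n_categories: int


@dataclass
class KSubsampleStudy:
    """k estimates from repeated small with-replacement draws of one site."""

    site_id: str
    subsample_size: int
    n_draws: int
    k_estimates: np.ndarray
    n_failures: int
    interval50: tuple[float, float]
    interval90: tuple[float, float]


def _nb_negll(logk: float, counts: np.ndarray, mu: float) -> float:
    k = np.exp(logk)
    return -stats.nbinom.logpmf(counts, k, k / (k + mu)).sum()


def fit_negbin(counts) -> NegBinFit:
    """Fit a negative binomial (mu, k) by maximum likelihood.

    For fixed k the likelihood in mu is maximized at the sample mean, so the
    fit reduces to a one-dimensional profile search over log k.  Degenerate
    data (constant values, all zeros) and boundary optima yield
    ``converged=False``; the function never raises for such data, because
    downstream subsampling studies must count failures rather than crash.
    """
    counts = np.asarray(counts, dtype=int)
    if counts.size == 0:
        raise ValueError("empty input")
    if counts.size < 2:
        raise ValueError("need at least 2 observations")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")

    n = counts.size
    mean = counts.mean()
    failed = NegBinFit(mu=float(mean), k=float("nan"), loglik=float("nan"),
                       converged=False, n_obs=n)
    if mean == 0 or np.all(counts == counts[0]):
        return failed  # k unidentifiable

    res = optimize.minimize_scalar(
        _nb_negll,
        bounds=(_LOGK_LO, _LOGK_HI),
        args=(counts, mean),
        method="bounded",
        options={"xatol": 1e-10},
    )
    logk = float(res.x)
    loglik = -float(res.fun)
    # a flat profile can park the optimizer near (not at) a bound; treat the
    # outermost decade on either side as "on the boundary"
    on_boundary = logk > _LOGK_HI - np.log(10) or logk < _LOGK_LO + np.log(10)
    if not res.success or not np.isfinite(loglik) or on_boundary:
        return failed
    return NegBinFit(mu=float(mean), k=float(np.exp(logk)), loglik=loglik,
                     converged=True, n_obs=n)


def lr_goodness_of_fit(counts, fit: NegBinFit) -> GofResult:
    """Likelihood-ratio goodness-of-fit of counts against a fitted NB.

    Categories are the unpooled integers 0..max(counts); with two estimated
    parameters the degrees of freedom are ``n_categories - 3``.  The
    statistic is G^2 = 2 * sum over occupied categories of
    obs * ln(obs / expected), referred to a chi-square upper tail.
    """
    if not fit.converged:
        raise ValueError("fit did not converge")
    counts = np.asarray(counts, dtype=int)
    cmax = int(counts.max())
    n_categories = cmax + 1
    df = n_categories - 1 - 2
    if df < 1:
        raise ValueError("too few categories")
    obs = np.bincount(counts, minlength=n_categories).astype(float)
    expected = counts.size * fit.pmf(np.arange(n_categories))
    occ = obs > 0
    g2 = 2.0 * float(np.sum(obs[occ] * np.log(obs[occ] / expected[occ])))
    p = float(stats.chi2.sf(g2, df))
    return GofResult(g2=g2, df=df, p=p, n_categories=n_categories)


def subsample_k_study(
    site: SiteSample,
    sizes=(20, 50, 100),
    n_draws: int = 100,
    seed: int = 0,
) -> list[KSubsampleStudy]:
    """How well can k be estimated from small samples of this site?

    For each subsample size, draws ``n_draws`` with-replacement samples of
    the site's rounded percent galling, refits the NB to each, and reports
    the central 50% and 90% ranges of the successful k estimates.  Fits that
    fail (degenerate draws, boundary optima) are counted in ``n_failures``
    and excluded from the intervals.
    """
    values = site.pseudocounts()
    out: list[KSubsampleStudy] = []
    for size in sizes:
        if size < 5:
            raise ValueError("subsample size must be >= 5")
        ks: list[float] = []
        n_failures = 0
        for draw in range(n_draws):
            rng = np.random.default_rng([seed, size, draw])
            sample = rng.choice(values, size=size, replace=True)
            fit = fit_negbin(sample)
            if fit.converged:
                ks.append(fit.k)
            else:
                n_failures += 1
        k_arr = np.array(ks)
        if k_arr.size == 0:
            warnings.warn(
                f"site {site.site_id!r}, n={size}: every draw failed to fit",
                stacklevel=2,
            )
            i50 = i90 = (float("nan"), float("nan"))
        else:
            i50 = tuple(np.percentile(k_arr, [25, 75]))
            i90 = tuple(np.percentile(k_arr, [5, 95]))
        out.append(
            KSubsampleStudy(
                site_id=site.site_id,
                subsample_size=size,
                n_draws=n_draws,
                k_estimates=k_arr,
                n_failures=n_failures,
                interval50=i50,
                interval90=i90,
            )
        )
    return out
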