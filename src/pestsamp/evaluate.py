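"""Evaluate sampling schemes: estimates, envelopes, errors, decision rates.

Given a site pre-sample, the full-sample mean is taken as the "true"
infestation and every scheme is judged by how quickly its running estimate
converges on it — as a 95% confidence envelope and mean absolute deviation
for random sampling, and as a single deterministic error curve for ordered
and transect sampling.  Decision rates score each estimate against action
thresholds (percent needles galled above which intervention is considered).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schemes import Trajectory
from .site_data import SiteSample

__all__ = [
    "DEFAULT_THRESHOLDS",
    "RandomSamplingEvaluation",
    "DeterministicEvaluation",
    "PrecisionResult",
    "true_mean",
    "decision_correct",
    "evaluate_random",
    "evaluate_deterministic",
    "bootstrap_precision",
]

#: Action thresholds in percent needles galled: ~1% low, 5% moderate, 10% high.
DEFAULT_THRESHOLDS = (1.0, 3.0, 5.0, 7.0, 10.0)


def _values(site: SiteSample, measure: str) -> np.ndarray:
    if measure == "pct_galled":
        return site.pct_values()
    if measure == "pseudocount":
        return site.pseudocounts().astype(float)
    if measure == "gall_count":
        return site.gall_counts().astype(float)
    raise ValueError(f"unknown measure {measure!r}")


def true_mean(site: SiteSample, measure: str = "pct_galled") -> float:
    """Site mean infestation over the complete pre-sample."""
    return float(_values(site, measure).mean())


def decision_correct(estimate: float, truth: float, threshold: float) -> bool:
    """Is the threshold decision from an estimate the same as from the truth?

    Correct iff estimate and truth fall on the same side of the threshold;
    "at or above" counts as above for both, so a tie cannot create an
    asymmetric error.
    """
    return (estimate >= threshold) == (truth >= threshold)


@dataclass
class RandomSamplingEvaluation:
    """Per-n summaries of many with-replacement random sampling replicates."""

    site_id: str
    n_reps: int
    true_mean: float
    n: np.ndarray  # 1..n_max
    mean_estimate: np.ndarray
    envelope_lo: np.ndarray  # 2.5th percentile across replicates
    envelope_hi: np.ndarray  # 97.5th percentile
    mean_abs_deviation: np.ndarray
    decision_rate: dict[float, np.ndarray] = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "n": self.n,
                "mean_estimate": self.mean_estimate,
                "envelope_lo": self.envelope_lo,
                "envelope_hi": self.envelope_hi,
                "mean_abs_deviation": self.mean_abs_deviation,
            }
        )
        for thr, rate in self.decision_rate.items():
            df[f"decision_rate_{thr:g}pct"] = rate
        return df


@dataclass
class DeterministicEvaluation:
    """Estimate and error curves for a single deterministic trajectory."""

    site_id: str
    scheme: str
    n: np.ndarray
    estimate: np.ndarray
    abs_deviation: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"n": self.n, "estimate": self.estimate,
             "abs_deviation": self.abs_deviation}
        )


@dataclass(frozen=True)
class PrecisionResult:
    """Bootstrap precision of the pre-sample mean.

    ``precision`` is half the width of the 95% percentile envelope of the
    resampled means divided by the estimated infestation — the pre-sample's
    own uncertainty when read as an estimate of whole-farm infestation.
    """

    estimate: float
    half_width: float
    precision: float
    n_boot: int


def evaluate_random(
    site: SiteSample,
    n_reps: int = 10_000,
    n_max: int | None = None,
    thresholds=DEFAULT_THRESHOLDS,
    seed: int = 0,
    measure: str = "pct_galled",
) -> RandomSamplingEvaluation:
    """Simulate with-replacement random sampling and summarize per n.

    Each replicate draws ``n_max`` trees with replacement; the running mean
    after each added tree gives an estimate at every n.  Across replicates
    the function reports the mean estimate, the empirical 2.5/97.5
    percentile envelope (linear-interpolation percentiles), the mean
    absolute deviation from the full-sample mean, and the fraction of
    replicates deciding correctly against each threshold.  Replicate r uses
    the random stream (seed, r), so results are reproducible and
    order-independent.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    values = _values(site, measure)
    n_trees = site.n_trees
    if n_max is None:
        n_max = n_trees
    truth = float(values.mean())
    thresholds = tuple(float(t) for t in thresholds)
    if any(t <= 0 for t in thresholds):
        raise ValueError("thresholds must be positive")

    idx = np.empty((n_reps, n_max), dtype=np.int64)
    for rep in range(n_reps):
        rng = np.random.default_rng([seed, rep])
        idx[rep] = rng.integers(0, n_trees, size=n_max)
    draws = values[idx]
    estimates = np.cumsum(draws, axis=1) / np.arange(1, n_max + 1)

    lo, hi = np.percentile(estimates, [2.5, 97.5], axis=0)
    rates = {
        thr: (((estimates >= thr) == (truth >= thr)).mean(axis=0))
        for thr in sorted(thresholds)
    }
    return RandomSamplingEvaluation(
        site_id=site.site_id,
        n_reps=n_reps,
        true_mean=truth,
        n=np.arange(1, n_max + 1),
        mean_estimate=estimates.mean(axis=0),
        envelope_lo=lo,
        envelope_hi=hi,
        mean_abs_deviation=np.abs(estimates - truth).mean(axis=0),
        decision_rate=rates,
    )


def evaluate_deterministic(
    site: SiteSample, trajectory: Trajectory, measure: str = "pct_galled"
) -> DeterministicEvaluation:
    """Running estimate and absolute error along a deterministic trajectory."""
    values = _values(site, measure)
    truth = float(values.mean())
    seq = values[trajectory.indices]
    n = np.arange(1, seq.size + 1)
    estimate = np.cumsum(seq) / n
    return DeterministicEvaluation(
        site_id=site.site_id,
        scheme=trajectory.scheme,
        n=n,
        estimate=estimate,
        abs_deviation=np.abs(estimate - truth),
    )


def bootstrap_precision(
    site: SiteSample,
    n_boot: int = 10_000,
    seed: int = 0,
    measure: str = "pct_galled",
) -> PrecisionResult:
    """Percentile-bootstrap precision of the pre-sample mean.

    Resamples the N trees with replacement ``n_boot`` times; half the
    2.5-97.5 percentile width of the resample means, divided by the
    full-sample mean, is the precision (e.g. 0.19 means +/-19%).
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    values = _values(site, measure)
    n = values.size
    rng = np.random.default_rng(seed)
    means = values[rng.integers(0, n, size=(n_boot, n))].mean(axis=1)
    lo, hi = np.percentile(means, [2.5, 97.5])
    half_width = float(hi - lo) / 2.0
    estimate = float(values.mean())
    precision = half_width / estimate if half_width > 0 else 0.0
    return PrecisionResult(estimate=estimate, half_width=half_width,
                           precision=precision, n_boot=n_boot)
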