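"""Diagnostic plots for the pre-sampling analyses."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .dispersion import KSubsampleStudy  # noqa: E402
from .evaluate import DeterministicEvaluation, RandomSamplingEvaluation  # noqa: E402
from .spatial import Semivariogram  # noqa: E402

__all__ = [
    "plot_k_subsample",
    "plot_semivariogram",
    "plot_random_envelope",
    "plot_error_curves",
]


def plot_k_subsample(studies: list[KSubsampleStudy], true_k: float | None = None,
                     ax=None):
    """Central 50% (box) and 90% (whisker) ranges of k by subsample size."""
    if ax is None:
        _, ax = plt.subplots()
    for i, st in enumerate(studies):
        if st.k_estimates.size == 0:
            continue
        lo50, hi50 = st.interval50
        lo90, hi90 = st.interval90
        ax.plot([i, i], [lo90, hi90], color="k", lw=1)
        ax.add_patch(plt.Rectangle((i - 0.2, lo50), 0.4, hi50 - lo50,
                                   fill=False, edgecolor="k"))
        ax.plot(i, np.median(st.k_estimates), "k_", ms=12)
    if true_k is not None:
        ax.axhline(true_k, color="grey", ls="--", lw=1)
    ax.set_xticks(range(len(studies)))
    ax.set_xticklabels([str(s.subsample_size) for s in studies])
    ax.set_xlabel("subsample size n")
    ax.set_ylabel("estimated k")
    ax.set_yscale("log")
    return ax


def plot_semivariogram(sv: Semivariogram, ax=None):
    if ax is None:
        _, ax = plt.subplots()
    ok = sv.pair_counts > 0
    ax.plot(sv.bin_centres[ok], sv.gamma[ok], "o-", color="k", ms=4)
    ax.set_xlabel("lag distance (m)")
    ax.set_ylabel("semivariance (%$^2$)")
    ax.set_ylim(bottom=0)
    return ax


def plot_random_envelope(ev: RandomSamplingEvaluation, ax=None):
    """Mean estimate with its 95% envelope, as a function of sample size."""
    if ax is None:
        _, ax = plt.subplots()
    ax.fill_between(ev.n, ev.envelope_lo, ev.envelope_hi, color="0.85")
    ax.plot(ev.n, ev.mean_estimate, color="k", lw=1)
    ax.axhline(ev.true_mean, color="grey", ls="--", lw=1)
    ax.set_xlabel("number of sampled trees n")
    ax.set_ylabel("estimated infestation (%)")
    return ax


def plot_error_curves(random_ev: RandomSamplingEvaluation,
                      deterministic: list[DeterministicEvaluation], ax=None):
    """Absolute estimation error vs n for random and deterministic schemes."""
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(random_ev.n, random_ev.mean_abs_deviation, color="k", lw=2,
            label="random (mean)")
    for ev in deterministic:
        ax.plot(ev.n, ev.abs_deviation, lw=1, label=ev.scheme)
    ax.set_xlabel("number of sampled trees n")
    ax.set_ylabel("absolute error (%)")
    ax.legend(frameon=False, fontsize=8)
    return ax
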