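# Methods

## Scope and data model

The unit of analysis is a *site pre-sample*: N mapped trees (here 100–200,
on a ~10 m grid) with, per tree, a percentage of needles galled in [0, 100],
optionally a raw gall count, and the field-collection order. Percent galling
is rounded to the nearest 1% (halves away from zero, so 2.5% → 3) to form an
integer *pseudo-count* suitable for discrete-distribution fitting; rounding
is half-away-from-zero by explicit convention so that fits are reproducible
across platforms. Geographic coordinates, when given in degrees, are
projected to local metres with an equirectangular approximation about a
reference point (north = R·Δlat, east = R·cos(lat₀)·Δlon, R = 6 371 000 m);
for stands spanning under a kilometre, and tree positions known only to a
few metres, the approximation error is negligible. Column mapping on input
is explicit (no header guessing), because deposited field tables do not
share a layout.

## Negative binomial fitting

Pseudo-counts are fitted to NB(μ, k) by maximum likelihood. Because the
likelihood in μ, for any fixed k, is maximized at the sample mean, the fit
profiles over log k alone with a bounded 1-D optimiser (bounds 10⁻⁴–10⁶,
absolute tolerance 10⁻¹⁰ on log k). The fit reports `converged=False` — and
never raises — when the data are degenerate (constant, all zero) or the
optimum lies in the outermost decade of the search interval. The boundary
rule intentionally classifies effectively-Poisson samples (k → ∞) as
failures: a boundary k carries no information, and the subsampling study
must count such draws as fit failures the way field analysts would discard
them. Small low-density samples fail often, which is itself a finding.

Goodness-of-fit is the likelihood-ratio statistic over *unpooled* integer
categories 0..max(x): G² = 2 Σ obsₓ ln(obsₓ/expₓ) (empty categories
contribute nothing), df = (max + 1) − 1 − 2, p from the χ² upper tail. The
unpooled convention is a deliberate choice: it matches the df bookkeeping of
the standard `goodfit`-style implementations this workflow descends from. It
is mildly anti-conservative with many sparse cells — measured type-I error
at μ = 4, k = 1, n = 200 is ≈ 8–9% at nominal 5% — which the calibration
test bounds but does not remove; pooling sparse tails would trade df
comparability for better calibration. Inputs whose maximum value leaves
fewer than one df are rejected ("too few categories").

## k estimability (subsampling study)

For subsample sizes n (default 20/50/100), the study draws `n_draws`
(default 100) with-replacement samples of the site's pseudo-counts, refits
the NB to each, records failures, and summarizes the successful k̂ by their
central 50% and 90% empirical intervals (25–75 and 5–95 linear-interpolation
percentiles). Each draw uses an independent random stream keyed by
(seed, size, draw), so studies are bit-reproducible and insensitive to
execution order. The operational question is whether the 90% interval is
narrow enough for a warm-up sample of that size to parameterize a
sequential-sampling stopping rule; for aggregated low-density data the
interval typically spans one to two orders of magnitude even at n = 100.

## Spatial structure

The Mantel test correlates Euclidean distances between tree positions with
absolute differences in percent galling over all n(n−1)/2 pairs, and
assesses the one-tailed (positive association) significance by random
relabelling of trees with the +1-corrected estimator
p = (1 + #{r_perm ≥ r_obs}) / (n_perm + 1), default 9 999 permutations. For
n ≤ 7 all n! relabellings are enumerated exactly instead. Because a
relabelling permutes pairs bijectively, the permuted vector's mean and norm
are invariant, which reduces each permutation to one dot product. The
absolute-difference metric for the infestation "distance" is the natural
1-D Euclidean choice; a different metric convention would shift r slightly,
which is why reported correlations should be compared across sites within
one convention rather than across software.

The semivariogram bins unordered pairs by separation (default 10 m bins —
the grid spacing — up to half the maximum pairwise distance) and reports
γ(h) = Σ (xᵢ − xⱼ)² / (2|N(h)|) per bin, with empty bins flagged (NaN) and
pair counts attached so that a complete binning can be verified against
n(n−1)/2.

## Sampling schemes and their evaluation

The "true" mean is the full pre-sample mean; all schemes are judged against
it. Random sampling draws with replacement — the pre-sample is itself a
sample of a larger stand, so resampling it with replacement is the honest
model of repeated field sampling, and it is why envelopes keep finite width
even at n = N. Each replicate r of a run uses the stream (seed, r); the
running mean after each added tree yields an estimate at every n, and across
replicates (default 10 000) the per-n summaries are: mean estimate, 2.5th
and 97.5th linear-interpolation percentiles (the 95% envelope), mean
absolute deviation, and per-threshold correct-decision rates. A decision is
correct when estimate and truth fall on the same side of the threshold, with
"at or above" counting as above on both sides so ties cannot create
one-sided errors. Default thresholds are 1/3/5/7/10% needles galled, the
range from tolerable to clearly intervention-worthy.

Ordered trajectories replay (or reverse) the field-collection raster. Belt
transects include every tree whose along-track projection lies in the closed
segment [0, L] and whose cross-track distance is ≤ w/2 (closed boundaries,
ties in the along-track coordinate broken by tree id); each set expands to
centre, left-jittered and right-jittered transects, where *left* is +90°
counter-clockwise from the direction of travel (recorded in the trajectory
metadata, since the opposite handedness convention would be otherwise
undiagnosable from outputs); two sets interleave A1, B1, A2, B2, A3, B3, and
a tree reachable from several transects is kept at first occurrence.
Deterministic schemes get no envelopes or decision rates — with one
trajectory there is no distribution to summarize.

Bootstrap precision of the pre-sample mean resamples all N trees with
replacement (default 10 000 resamples); half the 2.5–97.5 percentile width
of the resample means divided by the full-sample mean gives the "±X%"
figure quoted for a pre-sample's own accuracy.

## Synthetic sites

The generator produces grid stands (default 10 m spacing) visited in a
back-and-forth raster, with integer percent-galling values built by a
Gaussian copula: a zero-mean unit-variance latent field z is transformed to
u = Φ(z) and pushed through the NB(μ, k) quantile function. The copula
preserves the NB marginal exactly for any spatial structure, and makes
values monotone in μ at fixed seed. Spatial structure uses the correlation
model share·exp(−d/φ) + (1−share)·δ, realized by Cholesky factorization
(practical to ~2 000 trees; a jitter of 10⁻¹⁰ guards the factorization).

Two knobs matter. The range φ defaults to the scale real semivariograms
suggest (half the stand's long axis) for autocorrelated sites. The
structured share defaults to 0.7, calibrated so that a 200-tree stand shows
a mean Mantel r near 0.09 — the weak-correlation regime observed in real
stands (significant sites r ≈ 0.07–0.13) — because a fully structured
exponential field at stand scale produces Mantel correlations several times
larger and wildly unstable realization means. Even at share 0.7, single
autocorrelated realizations have means that wander substantially around μ
(the whole stand shares a handful of latent patches); analyses that probe
the marginal law are therefore run on spatially independent realizations,
and spatially correlated results are property checks, not reproductions —
no joint spatial law for real stands is known.

`generate_paperlike_panel` builds seven sites mirroring the published
survey panel: N = 100 for two sites and 200 for five, means 1.04–7.02%,
k 0.73–2.72, with the four sites reported as spatially autocorrelated given
corr_range = half the long axis. The defaults *are* the study conditions;
they are not tuned per analysis.

What the generator does not emulate: non-grid tree placement, anisotropy,
shoot-level measurement error, the dependence of attack on shoot length, and
any relationship between gall counts and percent galling. Tests passing on
synthetic sites therefore validate the machinery and its statistical
calibration, not the biology of any particular pest.

## Problem sizes and numerical conventions

Default problem sizes (10 000 randomizations and bootstrap resamples, 9 999
Mantel permutations, 100 subsample draws) run in seconds on one core for a
200-tree site; the test suite uses the same sizes for calibration checks
(500 goodness-of-fit replicates, 200 null Mantel sites) and completes in
well under a minute. Percentiles are linear-interpolation throughout
(numpy's default), seeds are explicit everywhere, and every stochastic
routine derives per-replicate streams from (seed, replicate index) so
results are independent of execution order. Known limitations: the G²
calibration noted above; Mantel p-values depend mildly on the permutation
count and tail convention, so cross-software comparisons of p (not r) need
care; k̂ from 200 trees of a low-density site still carries a factor-≈2
realization spread, which is precisely the phenomenon the subsampling study
is designed to expose.
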