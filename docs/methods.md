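# Methods

This note documents the statistical models, defaults, and design choices in
`capwin`, and what the simulated benchmarks do and do not demonstrate.

## Counting model

Windows are fixed genomic intervals (capture-bait targets plus any
off-target or control regions the user nominates), stored 0-based
half-open; GFF3 input is shifted on read. An alignment is counted in every
window it overlaps by at least one base pair. Reads that are unmapped,
secondary, supplementary, duplicate-flagged, or below the MAPQ cutoff
(default 10) are excluded. In paired mode, properly paired reads are
counted once per fragment, using the interval from the leftmost mate's
start across the template length; a fragment spanning a window is counted
even where the window falls in the inner, unsequenced gap. Any-overlap
counting means adjacent windows can share a read; window totals are
therefore not additive across overlapping designs.

## Normalization

All methods return per-sample factors centered to geometric mean 1, so
normalization (`count / factor`) changes relative scale only. Normalized
values live in a `normalized` layer; raw counts are never overwritten.

*Library size* sets `f_s ∝ Σ_w y_ws`. With few windows, or when a large
fraction of windows genuinely changes, totals are dominated by the changing
windows and this skews; the function warns when mean counts are low.

*GoF selection* first removes depth differences using library-size scaling,
then scores each window with the Pearson statistic
`GoF_w = Σ_s (y_ws − μ_w)²/μ_w`. Low GoF means stable across all samples;
windows at or below the 0.25 quantile (configurable) become normalization
anchors. Factors are then the median over anchors of the ratio of each
sample's count to the window's geometric-mean reference (median-of-ratios),
which is robust to the odd outlying anchor. One scaling caveat: multiplying
one sample's raw counts by `a` rescales the geometric-mean library
reference, hence every GoF value, by the common constant `a^(1/n)`; ranking
and anchor selection — everything the method consumes — are invariant, but
the raw GoF magnitudes are not individually meaningful across datasets.

*Control windows* applies the same median-of-ratios over user-nominated
windows (matched by window id first, exact interval as fallback). *Custom*
wraps user-supplied factors, centered.

All-zero windows receive infinite GoF and are never selected; windows with
any zero count are dropped from median-of-ratios (their geometric-mean
reference degenerates).

## Differential tests

All tests compare two treatment groups per window on the normalized layer.
Significance is strict (`p < α`, `BF ≥ threshold`) and unadjusted by
default, matching how detection thresholds are swept in the benchmark; an
optional Benjamini–Hochberg layer is available for real analyses.

### Conditional NB exact test (`nb_exact`)

The statistical core of edgeR's classic exact test, re-implemented. Counts
in each group are negative binomial with common dispersion φ; conditional
on a window's total T, the group-A sum follows beta-binomial(T, n_A/φ,
n_B/φ), reducing at φ = 0 to binomial(T, n_A/(n_A+n_B)). Two-sided
p-values: at φ = 0, equal-tail doubling capped at 1; at φ > 0, the
minimum-likelihood rule (total probability of outcomes no more probable
than the observed one), computed by locating the contiguous
more-probable-than-observed run around the unimodal conditional mode, so
ties are counted exactly once. Group sums of normalized counts are rounded
to integers; normalization is what justifies the equal-effective-library
conditioning. An independent cross-check against edgeR's
`exactTest(rejection.region="smallp")` agrees to 1e-6.

The common dispersion is estimated by method of moments: per window, the
within-group variance pooled across replicated groups and the mean of the
group means give `φ_w = max(0, (s² − μ)/μ²)`; the estimate is the median
over windows with μ > 0. This is a deliberate simplification of edgeR's
qCML estimator.

**Known limitation.** A single common φ assumes the variance law
`μ + φμ²` holds across the abundance range. When noise is proportional to
the mean (variance `(cv·μ)²`, as in this package's simulator and in many
capture datasets), no common φ fits both low- and high-count windows: the
test over-rejects on windows more dispersed than the common estimate and
under-rejects on the rest. On null simulations (fold 1, 5 replicates,
bimodal base counts, cv 0.1) the empirical false-positive rate is ~0.15 /
0.11 / 0.05 at α = 0.1 / 0.05 / 0.01, while the same test with the true φ
on genuinely NB data is well calibrated (~0.100/0.047/0.008). Per-window
(tagwise) dispersion would address this but is out of scope; treat
`nb_exact` p-values as anticonservative when dispersion is mean-dependent,
and prefer `bootstrap_t` when calibration matters.

### Bootstrap t (`bootstrap_t`)

Welch t on transformed counts (default log2(x+0.5), which roughly
stabilizes variance for proportional noise). The null enforces equality by
centering each group at its own mean; the centered residuals of *both*
groups are pooled and null groups of the original sizes are drawn from the
pool with replacement, B = 1000 times by default (minimum 100). The
estimator is p = (1+k)/(B+1) with k the count of resampled |t*| at or above
|t_obs|.

Pooling is a deliberate choice over within-group resampling: resampling
each group only from its own n atoms (algebraically identical to the
classical percentile-t pivot) is measurably conservative at n = 5
(rejection ~0.078/0.029/0.003 at nominal 0.1/0.05/0.01 on normal data),
because n-atom resamples estimate the tail of the Studentized distribution
too coarsely. With 2n pooled atoms the test is calibrated at all three
levels on both normal data and simulated count experiments. Pooling
implicitly assumes comparable residual spread in the two groups, reasonable
after the log transform.

Degenerate resamples (zero within-group variance) are scored t* = 0: they
carry no Studentized evidence, and mapping them to ±∞ would hand a single
atom unbounded influence. Observed statistics keep the natural conventions:
identical constant groups give p = 1; constant groups with different means
give t = ±∞ and hence p = 1/(B+1). Note that near-degenerate resamples
(tiny but nonzero variance) still produce occasional very large finite
|t*|; the attainable minimum p is therefore not always exactly 1/(B+1).

Per-window RNG substreams derive from (seed, window index), so p-values do
not depend on window order or parallel scheduling. For n = 2 per group the
full resampling distribution (256 combinations) can be enumerated exactly
(`exhaustive=True`), which the tests use as an oracle.

### JZS Bayes factor (`bayes_factor`)

The pooled-variance two-sample t is converted to the Jeffreys–Zellner–Siow
Bayes factor BF₁₀: a Cauchy(0, r) prior on the standardized effect size,
r = √2/2 by default (the conventional "medium" prior), yielding a
one-dimensional integral over the prior variance mixture evaluated by
adaptive quadrature (relative tolerance 1e-10, integrand max-rescaled in
log space so extreme t does not underflow). Agreement with an independent
high-precision quadrature is 1e-6 relative. Zero pooled variance yields
BF = 1 (no evidence) with a warning. Thresholds 1.1 / 1.5 / 2 pair with
detection stringencies 0.1 / 0.05 / 0.01 in the benchmark.

## Simulator

`simulate_experiment` emulates a two-arm capture count experiment directly
at the count level (no read-level synthesis): 52 windows by default, base
counts drawn with replacement from a 156-value pool, a chosen subset of
windows multiplied by fold ≥ 1 in every treatment replicate, and each
realized count `round(max(0, expected + N(0, cv·expected)))` with cv = 0.1
by default, applied to both arms.

The shipped base-count pool is a **synthetic stand-in**: 156 values frozen
from one seeded draw of an equal-weight two-component lognormal mixture
(modes near 50 and 1000), reproducing the double-peaked count distribution
characteristic of capture experiments. Real pilot counts can be substituted
via `base_counts` / `--base-counts`.

What the simulator does *not* emulate: mean–variance structure of true NB
sequencing noise (its Gaussian proportional noise is underdispersed
relative to Poisson below ~100 counts and overdispersed above), depth
differences between samples (inject distortions explicitly to study
normalization), correlated windows, off-target reads, or GC/length biases.
Passing benchmarks therefore demonstrate correct implementation and
relative detector behaviour under these conditions, not performance
guarantees on any particular real dataset.

## Benchmark

`run_grid` crosses replicates {3,5,10} × windows changed {5,10,20} × fold
{1.5,2,4} × detection level {0.1,0.05,0.01} (the Bayes method uses the
paired BF thresholds), simulating a fresh dataset per combination ×
iteration with seeds derived deterministically from (seed, combination
index, iteration); all three detectors run on each dataset after GoF
normalization. Confusion counts score called windows against the injected
truth; precision/recall/F follow the definitions above, with 0/0 reported
as NaN and excluded from iteration means (a combination whose every
iteration is undefined stays NaN). Identical seeds give byte-identical
outputs. The default scale used in the acceptance checks — 3 iterations and
300 bootstrap resamples per cell — was chosen to keep a full-grid run
around a minute on one CPU while leaving the per-cell means stable to a few
percent; `--iterations 10` reproduces the full-scale experiment.

## Numerical conventions

- All factors strictly positive; products centered to 1 within 1e-9.
- Exact-test tie detection uses a 1e-9 log-probability tolerance.
- MA pseudocount 0.5; correlation and density diagnostics use log2(x+1).
- On-target fraction of an all-zero sample is 0; constant samples get NaN
  similarity with a warning.
- Windows on chromosomes missing from a BAM header get zero counts with a
  warning rather than an error, so partial designs still load.
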