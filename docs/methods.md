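# Methods

This note documents the models, parameter choices, numerical decisions and
known limitations of `ironnorm`. Everything quantitative below is computed
by the test suite or by `scripts/acceptance.py`; nothing is quoted from
elsewhere.

## Data model

Intensities are a features × samples grid of finite, non-negative
linear-scale values with unique row/column identifiers. Scale transitions
are explicit: every matrix carries a `scale_tag` (`linear` or `log2`) and
operations assert the scale they need instead of guessing. Zeros are legal
in linear input (real scanner exports contain them); any operation that
must take a log replaces values ≤ 0 by the smallest positive value *on
that chip* first. This pseudo-handling means exact zeros do not round-trip
through normalization — they come back as the chip's floor intensity — an
accepted trade-off for keeping the log defined.

A chip layout (probe → probeset map with `mask`/`qc` flags) is optional.
Without one, every feature is treated as an assigned, unmasked probe,
summarization is skipped, and the pipeline operates purely at feature
level — the generic mode for non-array intensity matrices.

## Background subtraction

Per chip, observed intensity is modelled as `O = B + S`, background
`B ~ N(μ, σ²)`, signal `S ~ Exp(α)`, independent. The correction is the
posterior mean of the signal,

    E[S | O = o] = a + σ·φ(a/σ)/Φ(a/σ),   a = o − μ − σ²α,

the mean of a normal truncated to `S > 0`. It is strictly positive and
strictly increasing in `o`, so per-chip rank order is preserved exactly.
`φ/Φ` is evaluated as `exp(logpdf − logcdf)` so the deep lower tail
(`a/σ < −30`) neither under- nor overflows.

**Estimation.** The marginal of `O` is the exponentially-modified Gaussian
(EMG). Mode-based starting values (kernel-density mode of the lower half
of the data; σ from the reflected spread below the mode; α from the
reciprocal mean excess above the mode) are refined by EMG maximum
likelihood over `(μ, log σ, log α)` with L-BFGS-B. The refinement matters:
the mode of the EMG density sits above μ by `z*·σ + ασ²` where
`φ(z*)/Φ(z*) = ασ` — about +29 intensity units for μ=100, σ=15, α=0.005 —
so a mode-only estimator is systematically biased while the MLE recovers
μ within a fraction of a unit at n = 50 000 (see
`background_mu_max_abs_error` in the acceptance output). `log α` is
bounded so that a signal-free chip degrades gracefully to a normal fit
with μ at the mode. Chips are corrected strictly independently — a
column's result never changes when other columns are added or removed.

The correction is computed on linear intensities; the log domain is only a
visualization device for these distributions. Constant chips and chips
with fewer than 100 values are rejected rather than guessed at.

## Reference selection

The common reference is the "median chip": the sample minimizing the mean
pairwise RMSD of raw log₂ intensity vectors over retained features
(QC-flagged, unassigned and layout-unknown features are dropped when a
layout is present). Raw — pre-background — intensities are used so the
reference choice does not depend on a tunable correction. Chips are
compared in pairs, so peak memory is two log vectors plus the n² distance
table. Ties break to the lexicographically smallest sample ID, logged.
Optionally probesets are summarized first, shrinking the vectors ~5× for
very large cohorts.

## Pair-wise normalization

### Training-set candidates

Excluded from training: probes outside any probeset; masked probes; every
probe tied at a chip's minimum or maximum intensity on either chip
(extremes are truncation/saturation suspects, and *all* probes attaining
the extreme value are removed, not just one); probes above the saturation
threshold (default 64 000 on a 16-bit scale) on either chip. The
saturation/extreme tests use the *raw* intensities even when background
subtraction is on — saturation is a property of the scanner reading — while
curve training and application use the corrected values. Fewer than
`min_training_size` (default 100) survivors abort the pair rather than fit
an unstable curve.

### Iterative rank-order pruning

Within the surviving set, both chips are ranked (average ranks on ties —
stable and symmetric); each probe's divergence is
`%Δ = |rank_X − rank_Y| / set size × 100`. If the maximum %Δ exceeds the
convergence threshold (default 1%), every probe above
`max %Δ − prune_decrement` (default 0.5 percentage points) is removed in
bulk, the set is re-ranked, and the loop repeats. The cutoff always sits
below the current maximum, so each pass removes at least one probe and
termination is guaranteed; sizes decrease strictly until convergence. The
cutoff is *not* clamped at the convergence threshold — the loop exits only
through the ≤ 1% test. Probes that survive are treated as
non-differentially expressed between the two chips; the point of the
iteration is that even a large one-sided block of truly changed probes
(a third of the chip) is expelled within a few dozen passes, because its
members keep the largest rank divergences.

### Density weighting and curve fitting

Training points are sorted by `A = log₂(X·Y)`. Each point's weight is
`σ_avg^4`, where `σ_avg` averages the sample standard deviations of the
A-values of every sliding 1%-window containing the point. σ is computed on
A-values (not M-values): the purpose is density adjustment, and local A
spread is exactly inverse local density. Sliding windows advance by stride
1 and are truncated at the ends — terminal points simply belong to fewer
windows; no shrinking windows. The exponent 4 is configurable
(`weight_exponent`); smaller exponents may suit small (hundreds of points)
homogeneous training sets.

Weighted least-squares lines of `M` on `A` are fitted in every sliding
window 10% of the training set (minimum 3 points); each point's fitted
correction is `mean(slopes)·A + mean(offsets)` over the windows covering
it. Windows with zero weight or zero A-variance fall back to a horizontal
line at their (weighted) mean M. Implementation uses the closed
2-parameter WLS form over prefix sums, with A globally centred and weights
normalized by their maximum for conditioning; both transformations leave
the fitted values mathematically unchanged, and tests verify agreement
with a naive per-window `polyfit` oracle to 1e−10.

### Projection, interpolation, extrapolation

The residual `d = fit − observed M` is split evenly
(`x_proj = x + d/2`, `y_proj = y − d/2`), preserving each point's A
coordinate. Points landing on exactly the same `y_proj` are merged by
averaging corrections. Every probe on the chip — including probes excluded
from training — is corrected by linear interpolation of the correction
over `y_proj` at its log intensity; below/above the trained range the mean
correction of the first/last `extrapolation_points` (default 10) curve
points applies. Note the boundary behaviour: the constant extrapolation
value is a terminal *mean*, so the mapping can step slightly at the exact
range boundary when the terminal corrections have a trend; within the
range the mapping is continuous. Self-normalization is exact to machine
precision: identical vectors give M ≡ 0, a fitted curve of zeros, and a
unit mapping.

### Log base

All log-space computation uses base 2 (configurable). Correction factors
are ratios, so the base affects reported curve coordinates but not
normalized intensities.

## Probeset summarization

One-step Tukey biweight of the member probes' log₂ intensities per sample:
`M = median`, `S = median |v − M|`, `u = (v − M)/(cS + ε)`,
weights `(1 − u²)²` for `|u| < 1` else 0, result `Σwv/Σw`, reported as
`2^result` (linear) by default. `c = 5`, `ε = 10⁻⁴`: the classical
constants for this estimator in array processing. One step (no iteration);
`S = 0` is handled by the ε guard (weights collapse onto the median).
Masked probes never contribute; probesets left empty are dropped with a
warning. Each sample is summarized independently.

## Pipeline composition and incremental mode

Stage order: reference selection (if `auto`) → per-chip background
subtraction → probe-level pair normalization vs the reference → biweight
summarization → probeset-level pair normalization vs the *reference's own
summarized vector* (the natural reading of "a final pass at the probeset
level"; same reference throughout). The probeset-level pass reuses the
candidate rules with the layout rules inert (probesets have no mask or
membership) and the min/max/saturation rules applied to the summarized
values. The reference chip is background-subtracted and summarized but
never curve-adjusted.

Each chip's output is a pure function of (chip, reference, config). Batch
runs and `normalize_incremental` share one code path, so a chip normalized
alone is **bit-identical** to the same chip inside any batch — the
acceptance output's `incremental_max_abs_diff` is exactly 0, not merely
small. A stored reference bundle carries the raw and corrected reference
vectors, the summarized vector, and a fingerprint hashing the config and
the raw reference; incremental mode refuses to run against a mismatched
fingerprint or a permuted feature order.

## Synthetic data generator

Per probeset, latent log₂ expression ~ N(11, 2.5²); per probe, a
multiplicative log-normal affinity (σ = 1 log₂) and an additive
exponential signal component (rate 0.005, mean 200). This per-probe true
signal is drawn once and shared across chips — the exponential term is
*signal*, not noise; a per-chip exponential of that magnitude would be an
irreducible noise floor comparable to the signal itself and no
normalization method could demonstrate recovery against it. Per chip, the
shared signal passes through a strictly monotone distortion (identity /
constant gain / median-pivoted power law / monotone PCHIP warp through log
anchors), gains ~1% CV multiplicative measurement noise (log₂ σ = 0.015),
receives additive N(100, 15²) background, and is clipped at the 16-bit
ceiling 65 535. An optional "arm" — an exact-count random subset of
probesets (e.g. 34%) shifted up by Uniform(1, 3) log₂ units on designated
chips — reproduces strongly one-sided differential expression.

**Calibration rationale.** Recovery of a distortion is only measurable
when the replicate noise floor sits well below the distortion's median
|log₂ ratio| effect (a ≥ 90% reduction requires floor < 10% of effect).
With a g = 1.2 power-law warp the effect is ≈ 0.23 log₂ median; the
defaults put the combined floor (multiplicative noise ⊕ background noise
at the median intensity ≈ 2000) near 0.02, and the normalizer reaches that
floor. Two structural facts found during design and worth knowing: the
exponential signal floor compresses the warp's effect at low intensities,
and the additive background dominates chip-to-chip ratio noise for dim
probes — so floor arithmetic must be done at the realized intensity
distribution, not at nominal parameter values.

**What the generator does not emulate:** probe-sequence (GC) effects,
spatial artifacts, batch effects spanning many chips, heavy-tailed outlier
probes, or real scanner saturation shapes (clipping here is a hard
ceiling). Passing tests therefore demonstrate correctness of the
algorithmic machinery and its robustness to nonlinear response and
one-sided differential expression — not immunity to every artifact class
in real data.

## Problem sizes and defaults

Unit and property tests run at 10²–10⁴ features; the end-to-end
throughput check runs the full pipeline at 50 000 probes × 20 chips
(≈ 25 s on one core, comfortably inside the package's design target of
minutes-scale batch processing). `scripts/acceptance.py` uses 10 000
probes for pair-level scenarios, 50 000 values × 10 seeds for background
recovery, and a 6-chip, 6 000-probe pipeline scenario.

## Known limitations

- Exact zeros are floored at the chip minimum before logs (see above).
- The extrapolation constants can introduce a small step exactly at the
  trained-range boundary.
- The background model assumes a single additive normal + exponential mix
  per chip; bimodal backgrounds will mis-fit.
- Rank pruning needs the two chips to share a majority of
  non-differentially-expressed probes; if most of the chip truly changes,
  the "rank-invariant" training set is not meaningful (this is a property
  of the method, not the implementation).
- MM probes, CEL/CDF binary formats, and comparison re-implementations of
  other pipelines are out of scope.
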