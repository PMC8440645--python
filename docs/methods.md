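# Methods

## The generative model

A tapper produces inter-tap intervals

    r_k = −α ê_{k−1} + t_k + n_k + M_k − M_{k−1}
    t_k = t_{k−1} − β ê_{k−1}

with perceived asynchrony `ê_k = e_k − mean asynchrony`, timekeeper noise
`n_k ~ N(0, σ_T²)`, motor noise `M_k ~ N(0, σ_M²)`.  Assumptions: noise is
Gaussian and white (no drift term); the corrections act on the asynchrony
relative to the tapper's *fixed* mean asynchrony, not an online estimate —
this matches the stationary model the estimator assumes.  With `β = 0` the
coupled system reduces exactly to the fixed-period model, under which the
asynchrony series is ARMA(1,1): AR coefficient `1 − α`, with the MA part
contributed by the motor noise.  Closed forms used as test oracles (at
`σ_M = 0`): lag-1 autocorrelation `1 − α`; stationary SD
`σ_T / sqrt(1 − (1 − α)²)`.

Stability: the switch-response dynamics are governed by the matrix
`[[1−α−β, 1], [−β, 1]]` acting on (perceived error, period error).  The
simulator aborts with an instability error when `|e_k|` exceeds ten base
periods.  Two useful exact facts (both used in tests): the system is
nilpotent — one-beat adaptation — only at `α = β = 1`; and a zero-gain
tapper keeps its inter-tap intervals on the first tempo forever while its
delay intervals drift off the beat.

### Simulation conventions

* Initialisation: `t_0` = first tempo of the block; `e_0 ~ N(mean
  asynchrony, σ_T²)`; the tapper joins at beat 3 (participants are
  instructed to listen for about three beats before tapping).
* Missing taps are deleted completely at random after the trajectory is
  generated, so the underlying dynamics are unaffected.
* Isochronous blocks are simulated with `β = 0` (the fixed-period model);
  switching blocks use the participant's full `(α, β)`.

## Protocols

Isochronous blocks: ~100 beats at a 500 ms inter-onset interval, two
repetitions.  Tempo-switch blocks: the period alternates between
`500 − step/2` and `500 + step/2` ms, `step ∈ {10, 30, 50, 70, 90}`, with
run lengths drawn uniformly from 8–12 intervals; a 100-beat block holds
~9–10 switches, so the two repetitions of a condition deliver ~8–10
accelerations and ~8–10 decelerations.  The step-90 condition uses periods
455/545 ms (the symmetric ±45 ms split).  The first tempo of a block is
randomized under the block's seed.

## Preprocessing

Taps are assigned to their nearest beat (ties to the earlier beat; when two
taps compete for a beat the nearer is kept with a warning).  A beat is
*valid* when its tap lies within ±200 ms; a beat whose nearest tap lies
beyond the valid window is *excluded* (the tap is discarded); a beat with
no tap in its vicinity is *omitted*.  Leading omitted beats before the
first matched tap are trimmed rather than counted as missing, because the
instructed delayed start must not inflate missingness.  `r_k` and `d_k` are
undefined wherever a contributing tap is not valid.  Blocks with ≥ 40%
excluded-or-omitted beats are dropped from modelling.  Block summaries for
switching blocks remove the mechanical jump of each tempo change by
analysing `e'_k = e_k + (s_k − s_{k−1})`; on isochronous blocks this is a
no-op.  SDs use the n−1 denominator.

## The bGLS estimator

Isochronous regression: `y = r_k − t_0` on `X = ê_{k−1}`, intercept-free
(`t_0` is the metronome period; `ê` uses the block mean asynchrony over all
valid beats).  The equivalent estimate-and-discard-intercept variant is
asserted equal on complete data in the test suite.  Iteration: start with
Σ = I; GLS for the coefficient; residual autocovariances `γ̂₀, γ̂₁`; map
`σ_M² = −γ̂₁` clamped into `[0, γ̂₀/3]` (which enforces `0 ≤ σ_M ≤ σ_T`),
`σ_T² = γ̂₀ − 2σ_M²`; rebuild the banded Σ and repeat until the coefficient
moves less than 1e−6 or 20 iterations.  Near-zero residual variance
(noise-free data) short-circuits to plain least squares.  Missing data:
affected rows are dropped and Σ over surviving rows is keyed by true beat
lag, so non-adjacent survivors are exactly uncorrelated, as the noise model
implies.

Tempo-switch fits use complete 10-beat windows around each change (2 beats
before to 7 after), differenced form
`r_k − r_{k−1} = −(α+β) ê_{k−1} + α ê_{k−2} + z_k` — differencing removes
the unknown changing mean `t_k` — with the MA(2) moment map
`σ_M² = γ̂₂` clamped into `[0, γ̂₀/8]`, `σ_T² = (γ̂₀ − 6σ_M²)/2`.  The
block-level mean asynchrony defines `ê` (a segment is too short to estimate
it); a consequence worth knowing is that exact noise-free recovery holds
when the true offset is supplied, while the empirical block mean carries an
O(transition-fraction) bias that real noise swamps.  Segments are fitted
fully per segment (noise parameters included) and averaged segments →
block → blocks, with blocks weighted equally.

Model comparison (extended vs `β = 0`) uses a likelihood-ratio test with
1 df and AIC with k = 4 vs 3.  For the comparison, each model's Gaussian
likelihood is maximised over its noise parameters with the coefficients
profiled out by GLS, and the reduced optimum is also evaluated inside the
extended model's space, so the nesting inequality (extended ≥ reduced)
holds exactly.  The reported point estimates remain the moment-iterated
bGLS values.

## Model-free measures

* Lag-1 correlation of perceived asynchronies; pooled mode demeans per
  participant before pooling pairs.
* Stepwise AR up to lag 4, no intercept, entered one lag at a time while
  the nested-SSE F test has p < 0.1; the group-level variant gives every
  subject its own coefficients, so each step adds one predictor per subject
  (numerator df = number of subjects).  The fixed 4-lag coefficients are
  reported regardless of the stepwise path.  Note the entry rule itself
  caps exact-order selection near 90%: roughly one series in ten admits a
  spurious extra lag, by design.
* Switch trajectories: only transitions with complete data from 2 beats
  before to 7 after are used; delay intervals are baseline-aligned by the
  mean asynchrony of the two pre-change beats (their average then sits
  exactly on the old period), averaged within participant, then across
  participants; participants with fewer than two usable repetitions are
  excluded.
* Separability of post-switch delays: the 4 beats from each change onward
  are excluded (configurable 2–6); remaining delays are labelled by their
  own interval's tempo.  d′ uses the pooled-SD form; AUC comes from a
  threshold sweep at midpoints with trapezoidal integration and equals the
  pairwise statistic P(short < long) + ½P(=) exactly; its orientation is
  anchored to tempo identity (below 0.5 is meaningful), and the difference
  of means is deliberately not SD-normalized.

## Group statistics

Kruskal–Wallis (tie-corrected) for omnibus tests; post hoc pairwise
comparisons refer mean-rank differences to the studentized range with
infinite df and the Tukey–Kramer unequal-n standard error; Cliff's delta as
the effect size (δ = 2·AUC − 1 against the ROC measure, asserted exactly in
tests).  Reference z-scoring standardises each step-size with the
neurotypical group's mean and SD, then averages over steps; the update rate
is the mean of the z-scored isochronous α and combined tempo-switch β.  The
bootstrap comparison of correlations resamples both groups with
replacement, records within-group and pooled Spearman correlations per
replicate, and reports two-sided tail proportions with the (b+1)/(B+1)
correction; degenerate resamples are redrawn with a retry cap.  AQ50
scoring follows the three-factor structure (social skill: 12 items, 9
reverse-keyed; communication/mindreading: 6 items, 1 reverse-keyed);
responses are integers 0–3, reverse-keyed items score `3 − raw`; the
item-number mapping is configuration, with a default following the
published 50-item ordering.

## Synthetic cohort defaults

Group centres are the fitted medians of the emulated study — α
0.37/0.37/0.27, σ_T 20.9/19.8/21.1 ms, σ_M 8.1/9.3/10 ms, mean asynchrony
−32.2/−30.8/−30.3 ms for CON/DYS/ASD — with truncated-normal
between-participant spread (α sd 0.15, σ_T sd 5, σ_M sd 4, mean asynchrony
sd 18) and missing-tap rates 1%/1%/3%.  Raw period-correction medians are
not published (only z-scored contrasts), so β centres 0.45/0.42/0.20 were
chosen once from the tempo-tracking literature range to reproduce the
reported z-ordering; they are a modelling choice, not a fitted quantity.
Draws respect `σ_M < 0.85 σ_T` and `α + β ≤ 1.2` (stability).  Group sizes
default to 47/32/30.  One master seed drives per-participant substreams
(spawn-key on group and index), so cohorts are reproducible and stable
under cohort-size changes; all randomness flows through explicit
generators.

What the generator does *not* emulate: tempo-dependence of the mean
asynchrony, anticipation strategies, non-Gaussian or drifting noise,
block-order and fatigue effects, and hardware latency/jitter.  Passing the
qualitative cohort checks therefore shows the analysis chain recovers the
model's structure, not that real tappers obey the model.

## Parameter recovery: what is attainable

With two 100-beat blocks per tapper, α and σ_T recover well (Spearman rank
correlations vs truth ≈ 0.85–0.93 across cohorts).  σ_M does not: its
information enters only through the lag-1 residual autocovariance, whose
sampling noise at n ≈ 200 is comparable to the spread of σ_M² itself when
σ_M is drawn from 3–15 ms against σ_T 10–35 ms.  Exact maximum likelihood
on the ARMA(1,1) asynchrony series — the efficient bound for this problem —
reaches only ≈ 0.32 under these draws, and the bGLS iteration performs at
that level (≈ 0.3–0.4, robust to iteration count, starting covariance,
joint-block fitting and instrumental-variable initialisation).  Recovering
σ_M ranks reliably needs either longer recordings or a generating
distribution with much larger σ_M dispersion.  The acceptance script
reports the honest minimum; treat per-participant σ_M estimates at this
problem size as noisy and interpret them only in group aggregate.

## Numerical choices and degenerate inputs

Convergence tolerance 1e−6 on coefficients, 20 iterations, dense Cholesky
solves (blocks are ≤ a few hundred beats); variance floor 1e−10 keeps Σ
positive definite; noise-free data short-circuit to least squares.  Fits
are refused below 10 usable rows (isochronous) or 6 difference rows
(segments); blocks at ≥ 40% missingness are unusable; empty aggregation
cells propagate as missing, never as zero.  Problem sizes in the test
suite — 60-tapper recovery runs, 10 replicate cohorts at full group sizes
for the ordering checks, 5 000-beat closed-form checks — were chosen as the
smallest sizes at which the Monte-Carlo error is clearly below the effects
being asserted.
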