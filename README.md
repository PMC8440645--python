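# tapsync

Trial-by-trial analysis of paced finger tapping: a generative simulator of
tappers, preprocessing of tap/metronome event streams, model-free
synchronization statistics, bounded-GLS estimation of linear
phase/period-correction models, and the group-level statistics used to
compare clinical cohorts.

## Who this is for

Researchers analysing sensorimotor-synchronization experiments in which a
participant taps along with an auditory metronome — either at a fixed tempo
(isochronous blocks) or with a tempo that switches unpredictably between two
periods — and who want to decompose tapping variability into error
correction and internal noise sources, participant by participant.  The
package ships a full synthetic stand-in for a three-group study
(neurotypical / dyslexia / autism-like cohorts), so every analysis can be
exercised end to end without access to raw data.

## The model

Per beat *k*, the asynchrony `e_k` is the signed interval between tap and
metronome onset (negative = anticipatory, the usual human behaviour), `s_k`
the inter-stimulus interval, `r_k` the inter-tap interval, and `d_k` the
delay from stimulus *k−1* to tap *k*, with `r_k = d_k − e_{k−1}`.  Each
produced interval is modelled as

```
r_k = −α ê_{k−1} + t_k + n_k + M_k − M_{k−1}
t_k = t_{k−1} − β ê_{k−1}
```

where `ê` is the asynchrony relative to the tapper's own mean asynchrony
(which is perceived as synchronous), `α` is the **phase correction** (the
fraction of the last perceived error subtracted from the next interval),
`β` the **period correction** (the fraction used to update the internal
tempo estimate `t_k`), `n_k ~ N(0, σ_T²)` the **timekeeper noise** and
`M_k ~ N(0, σ_M²)` the **motor noise**.  With `β = 0` and a fixed tempo
(`t_k = t_0`) this is the classic fixed-period model, and the asynchrony
series is AR(1) with coefficient `1 − α`.

Because the motor noise enters two consecutive intervals, the regression
residual `z_k = n_k + M_k − M_{k−1}` is MA(1) — `γ₀ = σ_T² + 2σ_M²`,
`γ₁ = −σ_M²` — which is what lets the two noise sources be separated.  The
**bGLS** estimator iterates generalized least squares with this banded
covariance, re-estimating `(σ_T, σ_M)` from residual autocovariances under
the identifiability bound `0 ≤ σ_M ≤ σ_T`.  Tempo-switch blocks are fitted
per change segment in differenced form,
`r_k − r_{k−1} = −(α+β) ê_{k−1} + α ê_{k−2} + z_k`, whose MA(2) residual
structure (`γ₀ = 2σ_T² + 6σ_M²`, `γ₁ = −(σ_T² + 4σ_M²)`, `γ₂ = σ_M²`)
again separates the noises.  Missing taps drop the affected rows, and the
covariance over surviving rows is keyed by true beat lag.

## Worked example

Simulate one tapper at the neurotypical group medians (α = 0.37,
σ_T = 20.9 ms, σ_M = 8.1 ms, mean asynchrony −32 ms, 1% missing taps), two
100-beat isochronous blocks at 500 ms, and re-estimate everything:

```python
import numpy as np
from tapsync import synth, core, bgls, modelfree

rng = np.random.default_rng(3)
params = synth.TapperParams(alpha=0.37, sigma_T=20.9, sigma_M=8.1,
                            mean_asynchrony=-32.0, miss_rate=0.01)
summs, fits, percs = [], [], []
for _ in range(2):
    m = synth.generate_metronome("isochronous", 500.0, n_beats=100)
    taps, _ = synth.simulate_tapper(m, params, rng=rng)
    trial = core.match_taps_to_beats(m, taps)
    summs.append(core.summarize_block(trial))
    fits.append(bgls.fit_bgls_iso(trial))
    percs.append(core.perceived_asynchrony(trial))

print(f"mean asynchrony : {np.mean([s.mean_asynchrony for s in summs]):7.1f} ms")
print(f"SD of asynchrony: {np.mean([s.sd_asynchrony for s in summs]):7.1f} ms")
print(f"lag-1 correlation: {modelfree.lag1_correlation(percs, pooled=True):5.2f}")
print(f"alpha   : {np.mean([f.alpha for f in fits]):5.2f}")
print(f"sigma_T : {np.mean([f.sigma_T for f in fits]):5.1f} ms")
print(f"sigma_M : {np.mean([f.sigma_M for f in fits]):5.1f} ms")
```

prints

```
mean asynchrony :   -27.6 ms
SD of asynchrony:    28.9 ms
lag-1 correlation:  0.54
alpha   :  0.37
sigma_T :  21.1 ms
sigma_M :   8.6 ms
```

The tapper anticipates the beat by ~28 ms and carries about half of each
error into the next tap (lag-1 correlation 0.54 ≈ the AR(1) prediction
`1 − α` minus the motor-noise contribution); the bGLS estimates land on the
generating parameters.

## Command line

```sh
tapsync simulate --seed 1 --out cohort/           # events.csv + ground_truth.csv
tapsync analyze --events cohort/events.csv --out analysis/
tapsync recover --seed 1 --n-tappers 60 --out recovery.json
```

`analyze` chains preprocessing → block summaries → model-free measures →
bGLS fits (isochronous + per-segment tempo-switch) → reference z-scoring,
combined update-rate scores and Kruskal–Wallis / Tukey–Kramer / Cliff's
delta group statistics, writing tidy CSVs and a JSON report.

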