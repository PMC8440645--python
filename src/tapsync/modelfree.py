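"""Model-free synchronization statistics.

Four families of measures:

* error persistence -- the lag-1 correlation of perceived asynchronies
  (positive values mean errors are carried into the next tap);
* autoregressive structure -- a stepwise-selected AR model of the asynchrony
  series, quantifying how many beats back errors still matter;
* tempo-switch dynamics -- delay-interval trajectories aligned to the moment
  of a tempo change;
* post-switch separability -- d', ROC AUC and the raw difference of means
  between the delay-interval distributions under the two tempos, indexing
  whether the tapper eventually settled on the new tempo.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from tapsync.core import AlignedTrial, DegenerateInputError, InputError, perceived_asynchrony

__all__ = [
    "ARFitResult",
    "SwitchTrajectory",
    "SeparabilityResult",
    "lag1_correlation",
    "fit_ar_stepwise",
    "align_switch",
    "separability",
    "delay_samples_by_tempo",
]


def _consecutive_pairs(series: np.ndarray) -> np.ndarray:
    """(x_{k-1}, x_k) pairs, dropping pairs that straddle a NaN."""
    x = np.asarray(series, dtype=float)
    ok = ~np.isnan(x[:-1]) & ~np.isnan(x[1:])
    return np.column_stack([x[:-1][ok], x[1:][ok]])


def lag1_correlation(perceived, pooled: bool = False) -> float:
    """Pearson correlation between consecutive perceived asynchronies.

    ``perceived`` is one demeaned series, or (with ``pooled=True`` or in the
    per-participant both-blocks case) a list of series whose consecutive
    pairs are concatenated before correlating.  Pairs straddling a missing
    beat are dropped.
    """
    if isinstance(perceived, np.ndarray) and perceived.ndim == 1:
        series_list = [perceived]
    elif pooled or (isinstance(perceived, (list, tuple))):
        series_list = list(perceived)
    else:
        series_list = [np.asarray(perceived, dtype=float)]
    pairs = [_consecutive_pairs(s) for s in series_list]
    pairs = np.vstack([p for p in pairs if len(p)]) if pairs else np.empty((0, 2))
    if len(pairs) < 10:
        raise DegenerateInputError("need at least 10 consecutive pairs")
    return float(sps.pearsonr(pairs[:, 0], pairs[:, 1]).statistic)


@dataclass(frozen=True)
class ARFitResult:
    """Stepwise AR fit of the perceived-asynchrony series.

    ``n_selected_predictors`` is the stepwise path result (lags enter one at
    a time while the nested F test stays under ``entry_p``);
    ``coefficients`` always reports the fixed maximal-lag fit regardless of
    the stepwise outcome.  At group level coefficients has one row per
    subject.
    """

    coefficients: np.ndarray
    n_selected_predictors: int
    residual_variance: float
    level: str
    stepwise_pvalues: tuple


def _lagged_design(series: np.ndarray, max_lag: int) -> tuple[np.ndarray, np.ndarray]:
    """Rows k with e_k and all of e_{k-1}..e_{k-max_lag} defined."""
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n <= max_lag:
        return np.empty(0), np.empty((0, max_lag))
    y = x[max_lag:]
    X = np.column_stack([x[max_lag - j : n - j] for j in range(1, max_lag + 1)])
    ok = ~np.isnan(y) & ~np.isnan(X).any(axis=1)
    return y[ok], X[ok]


def _sse(y: np.ndarray, X: np.ndarray) -> tuple[float, np.ndarray]:
    if X.shape[1] == 0:
        return float(y @ y), np.empty(0)
    b, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ b
    return float(resid @ resid), b


def fit_ar_stepwise(
    series,
    max_lag: int = 4,
    entry_p: float = 0.1,
    level: str = "participant",
) -> ARFitResult:
    """Stepwise autoregression on perceived (demeaned, intercept-free)
    asynchronies.

    Lags enter in temporal order (lag 1 first); lag *j* is accepted when the
    F test comparing the nested sums of squared errors has p < ``entry_p``,
    and the path stops at the first rejection.  At ``level="group"`` every
    subject gets its own coefficients and adding lag *j* adds one predictor
    per subject, so the numerator degrees of freedom equal the number of
    subjects.  Rows containing any missing lag are dropped listwise, on the
    maximal-lag design so all nested fits share rows.
    """
    if level not in ("participant", "group"):
        raise InputError("level must be 'participant' or 'group'")
    if isinstance(series, np.ndarray) and series.ndim == 1:
        series_list = [series]
    else:
        series_list = [np.asarray(s, dtype=float) for s in series]
    if level == "participant":
        designs = [_lagged_design(s, max_lag) for s in series_list]
        y = np.concatenate([d[0] for d in designs])
        X_full = np.vstack([d[1] for d in designs])
        n_subjects = 1
    else:
        # block-diagonal: one coefficient set per subject
        designs = [_lagged_design(s, max_lag) for s in series_list]
        n_subjects = len(designs)
        y = np.concatenate([d[0] for d in designs])
        blocks = []
        for si, (ys, Xs) in enumerate(designs):
            row = np.zeros((len(ys), n_subjects * max_lag))
            row[:, si * max_lag : (si + 1) * max_lag] = Xs
            blocks.append(row)
        X_full = np.vstack(blocks)
    n = len(y)
    if n <= (max_lag + 1) * n_subjects:
        raise DegenerateInputError("series too short for the requested lags")

    def cols_for(p: int) -> np.ndarray:
        if level == "participant":
            return X_full[:, :p]
        keep = np.concatenate(
            [np.arange(si * max_lag, si * max_lag + p) for si in range(n_subjects)]
        ) if p else np.array([], dtype=int)
        return X_full[:, keep]

    sse_prev, _ = _sse(y, cols_for(0))
    selected = 0
    pvals = []
    for j in range(1, max_lag + 1):
        Xj = cols_for(j)
        sse_j, _ = _sse(y, Xj)
        q = n_subjects  # predictors added at this step
        df_full = n - Xj.shape[1]
        if df_full <= 0 or sse_j <= 0:
            break
        F = ((sse_prev - sse_j) / q) / (sse_j / df_full)
        p = float(sps.f.sf(F, q, df_full))
        pvals.append(p)
        if p < entry_p:
            selected = j
            sse_prev = sse_j
        else:
            break

    sse_full, b_full = _sse(y, cols_for(max_lag))
    resid_var = sse_full / max(n - max_lag * n_subjects, 1)
    coefficients = (
        b_full if level == "participant" else b_full.reshape(n_subjects, max_lag)
    )
    return ARFitResult(
        coefficients=coefficients,
        n_selected_predictors=selected,
        residual_variance=float(resid_var),
        level=level,
        stepwise_pvalues=tuple(pvals),
    )


@dataclass(frozen=True)
class SwitchTrajectory:
    """Group-average delay-interval trajectory around a tempo change.

    ``rel_beats`` runs from two beats before to seven beats after the change
    (the change itself is relative beat 0).  Delay intervals are baseline
    aligned by subtracting each segment's mean asynchrony over the two
    pre-change beats, so the pre-change part sits on the old metronome
    period by construction.
    """

    rel_beats: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    per_participant: np.ndarray  # participants x window
    participant_ids: tuple
    direction: str
    step_size: float
    n_segments: int


def _segments_for_trial(
    trial: AlignedTrial, direction: Optional[str], window: tuple[int, int]
) -> list[dict]:
    """Complete-data switch windows from one switching block."""
    w0, w1 = window
    out = []
    sw = trial.switch_indices()
    dirs = trial.switch_directions()
    for j, dr in zip(sw, dirs):
        if direction is not None and dr != direction:
            continue
        lo, hi = j + w0, j + w1
        if min(lo, j - 2) - 1 < 0 or hi >= trial.n_beats:
            continue  # truncated by block edges (d needs the previous stim)
        beats = np.arange(lo, hi + 1)
        if not (trial.valid_mask[beats].all() and trial.valid_mask[j - 2 : j].all()):
            continue  # any missing tap in the window drops the segment
        baseline = trial.e[j - 2 : j].mean()  # two pre-change beats
        out.append(
            {
                "switch": j,
                "direction": dr,
                "d_aligned": trial.d[beats] - baseline,
                "beats": beats,
                "baseline": baseline,
            }
        )
    return out


def align_switch(
    trials: Sequence[AlignedTrial],
    direction: str,
    window: tuple[int, int] = (-2, 7),
    participant_ids: Optional[Sequence] = None,
    min_repetitions: int = 2,
) -> SwitchTrajectory:
    """Average tempo-change responses, first within then across participants.

    ``trials`` are switching blocks; ``participant_ids`` groups blocks by
    participant (one participant by default).  Segments with missing taps in
    the window or truncated by block edges are dropped, and participants
    with fewer than ``min_repetitions`` usable segments are excluded from
    the group trajectory.
    """
    if participant_ids is None:
        participant_ids = [0] * len(trials)
    if len(participant_ids) != len(trials):
        raise InputError("participant_ids must parallel trials")
    step = trials[0].metronome.step_size
    per_part: dict = {}
    n_segments = 0
    for pid, trial in zip(participant_ids, trials):
        for seg in _segments_for_trial(trial, direction, window):
            per_part.setdefault(pid, []).append(seg["d_aligned"])
            n_segments += 1
    means = {
        pid: np.mean(np.vstack(segs), axis=0)
        for pid, segs in per_part.items()
        if len(segs) >= min_repetitions
    }
    if not means:
        raise DegenerateInputError("no usable tempo-change segments")
    mat = np.vstack(list(means.values()))
    sem = (
        np.std(mat, axis=0, ddof=1) / np.sqrt(mat.shape[0])
        if mat.shape[0] > 1
        else np.zeros(mat.shape[1])
    )
    return SwitchTrajectory(
        rel_beats=np.arange(window[0], window[1] + 1),
        mean=mat.mean(axis=0),
        sem=sem,
        per_participant=mat,
        participant_ids=tuple(means.keys()),
        direction=direction,
        step_size=step,
        n_segments=n_segments,
    )


@dataclass(frozen=True)
class SeparabilityResult:
    """Separability of post-switch delay intervals under the two tempos.

    ``d1`` is the longer tempo, so positive ``diff_means`` (and d' > 0,
    AUC > 0.5) mean the tapper's delays track the metronome.  AUC keeps its
    tempo-anchored orientation: values below 0.5 are possible and meaningful
    (delays anti-tracking the tempo), so no max(AUC, 1-AUC) folding.
    """

    d_prime: float
    auc: float
    diff_means: float
    step_size: float
    n_long: int
    n_short: int


def _roc_auc_below_threshold(short: np.ndarray, long_: np.ndarray) -> float:
    """AUC of the 'below threshold => short tempo' classifier, by sweeping
    thresholds at midpoints between sorted unique values and integrating the
    (FPR, TPR) curve with the trapezoid rule."""
    vals = np.unique(np.concatenate([short, long_]))
    thr = np.concatenate([[-np.inf], (vals[:-1] + vals[1:]) / 2, [np.inf]])
    # classify "short" when value < threshold; count ties as half
    tpr = np.array([np.mean(short < t) + 0.5 * np.mean(short == t) for t in thr])
    fpr = np.array([np.mean(long_ < t) + 0.5 * np.mean(long_ == t) for t in thr])
    order = np.argsort(fpr, kind="stable")
    return float(np.trapezoid(tpr[order], fpr[order]))


def separability(
    delays_long, delays_short, step_size: float = np.nan
) -> SeparabilityResult:
    """d', AUC and difference of means for two delay-interval samples.

    ``delays_long`` are the delay intervals recorded under the longer tempo
    (sample d1), ``delays_short`` under the shorter (d2).  Identical
    distributions give d' = 0, AUC = 0.5, diff_means = 0.
    """
    d1 = np.asarray(delays_long, dtype=float)
    d2 = np.asarray(delays_short, dtype=float)
    d1, d2 = d1[~np.isnan(d1)], d2[~np.isnan(d2)]
    if len(d1) == 0 or len(d2) == 0:
        raise DegenerateInputError("both tempo samples must be non-empty")
    mu1, mu2 = d1.mean(), d2.mean()
    v1 = d1.var(ddof=1) if len(d1) > 1 else 0.0
    v2 = d2.var(ddof=1) if len(d2) > 1 else 0.0
    pooled = np.sqrt((v1 + v2) / 2)
    d_prime = (mu1 - mu2) / pooled if pooled > 0 else np.inf * np.sign(mu1 - mu2)
    return SeparabilityResult(
        d_prime=float(d_prime),
        auc=_roc_auc_below_threshold(d2, d1),
        diff_means=float(mu1 - mu2),
        step_size=float(step_size),
        n_long=len(d1),
        n_short=len(d2),
    )


def delay_samples_by_tempo(
    trials: Sequence[AlignedTrial], exclude_after_switch: int = 4
) -> tuple[np.ndarray, np.ndarray]:
    """Pool delay intervals by current tempo, excluding the transient.

    The ``exclude_after_switch`` beats from each tempo change onward
    (including the change beat itself, where most of the adaptation happens)
    are dropped; remaining delay intervals are labelled by the tempo of
    their own inter-stimulus interval.  Returns ``(d_long, d_short)``.
    """
    if not 2 <= exclude_after_switch <= 6:
        raise InputError("exclude_after_switch must be between 2 and 6")
    longs, shorts = [], []
    for trial in trials:
        s = trial.s
        if trial.metronome.protocol != "switching":
            raise InputError("separability needs switching blocks")
        mid = trial.metronome.base_period
        drop = np.zeros(trial.n_beats, dtype=bool)
        for j in trial.switch_indices():
            drop[j : j + exclude_after_switch] = True
        ok = ~drop & ~np.isnan(trial.d) & ~np.isnan(s)
        longs.append(trial.d[ok & (s > mid)])
        shorts.append(trial.d[ok & (s < mid)])
    return np.concatenate(longs), np.concatenate(shorts)
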