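"""Domain types and preprocessing for paced-tapping event streams.

Notation follows the standard sensorimotor-synchronization conventions:

* ``e_k`` -- asynchrony of tap *k* (tap onset minus stimulus onset, ms;
  negative values mean the tap anticipates the beat, which is the typical
  human behaviour).
* ``s_k`` -- inter-stimulus interval between beats *k-1* and *k*.
* ``r_k`` -- inter-tap interval between taps *k-1* and *k*.
* ``d_k`` -- delay interval from stimulus *k-1* to tap *k*.

These satisfy the identity ``r_k = d_k - e_{k-1}`` wherever all three are
defined.  All times are milliseconds, block-relative, stored as floats;
missing values are NaN.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "MetronomeSequence",
    "TapSequence",
    "AlignedTrial",
    "BlockSummary",
    "ConfigurationError",
    "InputError",
    "DegenerateInputError",
    "STATUS_VALID",
    "STATUS_EXCLUDED",
    "STATUS_OMITTED",
    "match_taps_to_beats",
    "summarize_block",
    "perceived_asynchrony",
    "between_block_correlation",
    "read_events_csv",
    "events_to_trials",
    "trial_to_frame",
    "summary_to_dict",
    "metronome_from_onsets",
]

STATUS_VALID = "valid"
STATUS_EXCLUDED = "excluded"
STATUS_OMITTED = "omitted"


class ConfigurationError(ValueError):
    """Analysis parameters are internally inconsistent with the protocol."""


class InputError(ValueError):
    """Malformed input data (unordered onsets, schema violations...)."""


class DegenerateInputError(ValueError):
    """Too little usable data for the requested computation."""


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise InputError(f"{name} must be one-dimensional")
    return arr


@dataclass(frozen=True)
class MetronomeSequence:
    """Stimulus onsets with protocol metadata.

    ``protocol`` is ``"isochronous"`` or ``"switching"``.  For switching
    protocols, the inter-stimulus intervals alternate between
    ``base_period - step_size/2`` and ``base_period + step_size/2``;
    ``switch_indices`` holds the beat indices *k* at which the interval
    ``s_k`` first takes the new tempo, and ``switch_directions`` holds
    ``"acceleration"`` (interval got shorter) or ``"deceleration"`` per
    switch.
    """

    onsets: np.ndarray
    base_period: float
    protocol: str = "isochronous"
    step_size: float = 0.0
    switch_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    switch_directions: tuple = ()

    def __post_init__(self):
        onsets = _as_float_array(self.onsets, "onsets")
        if len(onsets) < 2:
            raise InputError("metronome needs at least two onsets")
        if np.any(np.diff(onsets) <= 0):
            raise InputError("metronome onsets must be strictly increasing")
        object.__setattr__(self, "onsets", onsets)
        object.__setattr__(
            self, "switch_indices", np.asarray(self.switch_indices, dtype=int)
        )
        if self.protocol not in ("isochronous", "switching"):
            raise InputError(f"unknown protocol {self.protocol!r}")

    @property
    def n_beats(self) -> int:
        return len(self.onsets)

    @property
    def s(self) -> np.ndarray:
        """Inter-stimulus intervals, ``s[j] = onset[j+1] - onset[j]``."""
        return np.diff(self.onsets)

    def s_per_beat(self) -> np.ndarray:
        """Per-beat interval array: element *k* is ``s_k``; ``s_0`` is NaN."""
        out = np.full(self.n_beats, np.nan)
        out[1:] = np.diff(self.onsets)
        return out


@dataclass(frozen=True)
class TapSequence:
    """A participant's tap onsets (strictly increasing, ms)."""

    tap_onsets: np.ndarray

    def __post_init__(self):
        taps = _as_float_array(self.tap_onsets, "tap_onsets")
        if len(taps) and np.any(np.diff(taps) <= 0):
            raise InputError("tap onsets must be strictly increasing")
        object.__setattr__(self, "tap_onsets", taps)


@dataclass
class AlignedTrial:
    """Per-beat matched taps for one block.

    Arrays are indexed by beat.  ``status`` distinguishes ``valid`` taps
    (within the exclusion window of the beat), ``excluded`` taps (present but
    outside it), and ``omitted`` beats (no tap in the omission window).
    ``r`` and ``d`` are NaN wherever a contributing tap is not valid.
    """

    metronome: MetronomeSequence
    stimulus_onsets: np.ndarray
    tap_onsets: np.ndarray
    e: np.ndarray
    status: np.ndarray
    r: np.ndarray
    d: np.ndarray
    s: np.ndarray
    offset: int = 0  # beats trimmed from the start of the block (lead-in)

    @property
    def n_beats(self) -> int:
        return len(self.stimulus_onsets)

    @property
    def valid_mask(self) -> np.ndarray:
        return self.status == STATUS_VALID

    @property
    def pct_missing(self) -> float:
        """Fraction of beats that are excluded or omitted."""
        return float(np.mean(~self.valid_mask))

    def switch_indices(self) -> np.ndarray:
        """Switch beat indices re-expressed in trimmed-trial coordinates."""
        idx = self.metronome.switch_indices - self.offset
        keep = (idx >= 0) & (idx < self.n_beats)
        return idx[keep]

    def switch_directions(self) -> tuple:
        idx = self.metronome.switch_indices - self.offset
        keep = (idx >= 0) & (idx < self.n_beats)
        return tuple(d for d, k in zip(self.metronome.switch_directions, keep) if k)


@dataclass(frozen=True)
class BlockSummary:
    """Model-free block summary: mean/SD of asynchrony and missingness."""

    mean_asynchrony: float
    sd_asynchrony: float
    pct_missing: float
    n_beats: int
    perturbation_adjusted: bool
    usable_for_modelling: bool

    def __post_init__(self):
        if not (0.0 <= self.pct_missing <= 1.0):
            raise ValueError("pct_missing must lie in [0, 1]")
        if self.sd_asynchrony < 0:
            raise ValueError("sd_asynchrony must be non-negative")


def match_taps_to_beats(
    metronome: MetronomeSequence,
    taps: TapSequence,
    exclusion_halfwidth: float = 200.0,
    omission_halfwidth: float = 200.0,
    trim_leading_omissions: bool = True,
) -> AlignedTrial:
    """Assign taps to metronome beats and derive the asynchrony series.

    A beat is ``valid`` when a tap falls within ``+-exclusion_halfwidth`` of
    it, ``excluded`` when the nearest tap sits in the
    ``(exclusion, omission]`` band, and ``omitted`` when no tap falls within
    ``+-omission_halfwidth``.  Each tap is assigned to at most one beat (its
    nearest); when several taps compete for one beat the nearest is kept and
    the rest discarded with a warning.

    Participants are instructed to start tapping only after a few beats, so
    leading omitted beats before the first matched tap are trimmed rather
    than counted as missing (disable with ``trim_leading_omissions=False``).
    """
    if exclusion_halfwidth <= 0 or omission_halfwidth <= 0:
        raise ConfigurationError("window half-widths must be positive")
    if exclusion_halfwidth > omission_halfwidth:
        raise ConfigurationError(
            "exclusion window cannot be wider than the omission window"
        )
    min_period = float(np.min(metronome.s))
    if min_period < 2 * omission_halfwidth:
        raise ConfigurationError(
            f"metronome period {min_period} ms overlaps the "
            f"±{omission_halfwidth} ms omission windows"
        )
    tap_arr = taps.tap_onsets
    if len(tap_arr) == 0:
        raise InputError("tap sequence is empty")

    stim = metronome.onsets
    n = len(stim)
    # nearest beat for every tap; windows cannot overlap so the nearest beat
    # is the only candidate
    nearest_beat = np.clip(np.searchsorted(stim, tap_arr), 0, n - 1)
    left = np.clip(nearest_beat - 1, 0, n - 1)
    # ties (tap exactly halfway) go to the earlier beat
    use_left = np.abs(tap_arr - stim[left]) <= np.abs(tap_arr - stim[nearest_beat])
    use_left &= left != nearest_beat
    nearest_beat = np.where(use_left, left, nearest_beat)

    tap_for_beat = np.full(n, np.nan)
    status = np.full(n, STATUS_OMITTED, dtype=object)
    for b in range(n):
        # all taps nearest to this beat; their distance is bounded by half
        # the metronome period, so a stray tap between beats lands in one
        # beat's excluded band rather than being double-counted
        cand = tap_arr[nearest_beat == b]
        if len(cand) == 0:
            continue  # no tap near this beat -> omitted
        if len(cand) > 1:
            warnings.warn(
                f"{len(cand)} taps compete for beat {b}; keeping the nearest",
                stacklevel=2,
            )
        best = cand[np.argmin(np.abs(cand - stim[b]))]
        if abs(best - stim[b]) <= exclusion_halfwidth:
            tap_for_beat[b] = best
            status[b] = STATUS_VALID
        else:
            # a tap exists near the beat but outside the valid window: the
            # beat counts as excluded (the tap is discarded), not omitted
            tap_for_beat[b] = best
            status[b] = STATUS_EXCLUDED

    offset = 0
    if trim_leading_omissions:
        while offset < n and status[offset] == STATUS_OMITTED:
            offset += 1
        if offset >= n - 1:
            raise DegenerateInputError("no matched taps in block")

    stim_t = stim[offset:]
    tap_t = tap_for_beat[offset:]
    status_t = status[offset:]
    m = len(stim_t)

    e = np.where(status_t == STATUS_VALID, tap_t - stim_t, np.nan)
    valid = status_t == STATUS_VALID
    r = np.full(m, np.nan)
    d = np.full(m, np.nan)
    both = valid[1:] & valid[:-1]
    r[1:][both] = (tap_t[1:] - tap_t[:-1])[both]
    d[1:][valid[1:]] = (tap_t[1:] - stim_t[:-1])[valid[1:]]

    s = np.full(m, np.nan)
    s[1:] = np.diff(stim_t)

    return AlignedTrial(
        metronome=metronome,
        stimulus_onsets=stim_t,
        tap_onsets=tap_t,
        e=e,
        status=status_t,
        r=r,
        d=d,
        s=s,
        offset=offset,
    )


def _perturbation_adjusted(trial: AlignedTrial) -> np.ndarray:
    """``e'_k = e_k + (s_k - s_{k-1})``: removes the step injected by an
    unexpected tempo change from the asynchrony series."""
    ds = np.zeros(trial.n_beats)
    s = trial.s
    ok = ~np.isnan(s[1:]) & ~np.isnan(s[:-1])
    ds[1:][ok] = (s[1:] - s[:-1])[ok]
    return trial.e + ds


def summarize_block(
    trial: AlignedTrial, adjust_perturbation: bool = False
) -> BlockSummary:
    """Mean and SD of asynchrony over valid beats (SD with n-1 denominator).

    With ``adjust_perturbation`` the series is first corrected by
    ``+(s_k - s_{k-1})`` so the mechanical jump at each tempo switch does not
    inflate the SD; on an isochronous block this is a no-op.
    """
    e = _perturbation_adjusted(trial) if adjust_perturbation else trial.e
    vals = e[trial.valid_mask]
    if len(vals) < 2:
        raise DegenerateInputError("need at least two valid asynchronies")
    return BlockSummary(
        mean_asynchrony=float(np.mean(vals)),
        sd_asynchrony=float(np.std(vals, ddof=1)),
        pct_missing=trial.pct_missing,
        n_beats=trial.n_beats,
        perturbation_adjusted=bool(adjust_perturbation),
        usable_for_modelling=trial.pct_missing < 0.40,
    )


def perceived_asynchrony(trial_or_series) -> np.ndarray:
    """Asynchronies relative to the participant's own mean asynchrony.

    Accepts an :class:`AlignedTrial` or a plain NaN-padded series; NaNs are
    preserved positionally and the mean is taken over defined entries only.
    """
    if isinstance(trial_or_series, AlignedTrial):
        e = np.where(trial_or_series.valid_mask, trial_or_series.e, np.nan)
    else:
        e = np.asarray(trial_or_series, dtype=float)
    valid = ~np.isnan(e)
    if valid.sum() < 2:
        raise DegenerateInputError("need at least two valid asynchronies")
    return e - e[valid].mean()


def between_block_correlation(
    metric_block1: Sequence[float], metric_block2: Sequence[float]
) -> tuple[float, float]:
    """Paired (Pearson, Spearman) correlation of a per-participant metric
    across two repetitions of a condition (test-retest reliability)."""
    x = _as_float_array(metric_block1, "metric_block1")
    y = _as_float_array(metric_block2, "metric_block2")
    if len(x) != len(y):
        raise InputError("blocks must be paired by participant")
    if len(x) < 3:
        raise DegenerateInputError("need at least three participants")
    pearson = float(sps.pearsonr(x, y).statistic)
    spearman = float(sps.spearmanr(x, y).statistic)
    return pearson, spearman


# ---------------------------------------------------------------------------
# event-table I/O

EVENT_COLUMNS = ["participant_id", "group", "block_id", "condition", "event_type", "onset_ms"]


def read_events_csv(path) -> pd.DataFrame:
    """Read a long-format event table (one row per stimulus or tap onset)."""
    df = pd.read_csv(path)
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"event CSV missing columns: {sorted(missing)}")
    return df


def metronome_from_onsets(onsets, atol: float = 0.5) -> MetronomeSequence:
    """Reconstruct a :class:`MetronomeSequence` (protocol, tempo switches)
    from raw stimulus onsets.

    Interval changes larger than ``atol`` ms are treated as tempo switches;
    a block with no switches is isochronous with the median interval as base
    period.
    """
    onsets = _as_float_array(onsets, "onsets")
    s = np.diff(onsets)
    changes = np.flatnonzero(np.abs(np.diff(s)) > atol) + 1  # index into s
    if len(changes) == 0:
        return MetronomeSequence(
            onsets=onsets, base_period=float(np.median(s)), protocol="isochronous"
        )
    tempos = np.unique(np.round(s, 3))
    if len(tempos) != 2:
        raise InputError(
            f"switching block must alternate between two tempos, found {tempos}"
        )
    lo, hi = float(tempos[0]), float(tempos[1])
    directions = tuple(
        "acceleration" if s[j] < s[j - 1] else "deceleration" for j in changes
    )
    return MetronomeSequence(
        onsets=onsets,
        base_period=(lo + hi) / 2,
        protocol="switching",
        step_size=hi - lo,
        # s[j] = onset[j+1]-onset[j] is s_{k} for beat k=j+1
        switch_indices=changes + 1,
        switch_directions=directions,
    )


def events_to_trials(
    events: pd.DataFrame,
    exclusion_halfwidth: float = 200.0,
    omission_halfwidth: float = 200.0,
) -> pd.DataFrame:
    """Match taps to beats for every (participant, block) in an event table.

    Returns a DataFrame with one row per block carrying the metadata columns
    and an ``trial`` object column.
    """
    rows = []
    keys = ["participant_id", "group", "block_id", "condition"]
    for key, g in events.groupby(keys, sort=True):
        stim = np.sort(g.loc[g.event_type == "stim", "onset_ms"].to_numpy(float))
        tap = np.sort(g.loc[g.event_type == "tap", "onset_ms"].to_numpy(float))
        metronome = metronome_from_onsets(stim)
        trial = match_taps_to_beats(
            metronome,
            TapSequence(tap),
            exclusion_halfwidth=exclusion_halfwidth,
            omission_halfwidth=omission_halfwidth,
        )
        rows.append(dict(zip(keys, key)) | {"trial": trial})
    return pd.DataFrame(rows)


def trial_to_frame(trial: AlignedTrial) -> pd.DataFrame:
    """Tidy per-beat representation of an aligned trial (CSV-friendly)."""
    return pd.DataFrame(
        {
            "beat": np.arange(trial.n_beats) + trial.offset,
            "stimulus_onset_ms": trial.stimulus_onsets,
            "tap_onset_ms": trial.tap_onsets,
            "e_ms": trial.e,
            "r_ms": trial.r,
            "d_ms": trial.d,
            "s_ms": trial.s,
            "status": trial.status,
        }
    )


def summary_to_dict(summary: BlockSummary) -> dict:
    return {
        "mean_asynchrony": summary.mean_asynchrony,
        "sd_asynchrony": summary.sd_asynchrony,
        "pct_missing": summary.pct_missing,
        "n_beats": summary.n_beats,
        "perturbation_adjusted": summary.perturbation_adjusted,
        "usable_for_modelling": summary.usable_for_modelling,
    }


def summaries_to_json(summaries: Iterable[BlockSummary], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump([summary_to_dict(s) for s in summaries], fh, indent=2)
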