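"""Group-level statistics for cohort comparisons.

Everything here operates on tidy per-participant metric tables: rank-based
omnibus and post hoc tests, nonparametric effect sizes, reference z-scoring
and combined scores, bootstrap comparison of correlations, and three-factor
scoring of the AQ50 questionnaire.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from tapsync.core import DegenerateInputError, InputError

__all__ = [
    "GroupComparison",
    "AQ50Factors",
    "AQ50FactorSpec",
    "DEFAULT_AQ50_FACTORS",
    "zscore_by_reference",
    "update_rate",
    "kruskal_wallis",
    "posthoc_tukey_kramer_ranks",
    "cliffs_delta",
    "correlations",
    "bootstrap_corr_difference",
    "aq50_factor_scores",
    "chi_square_counts",
    "wilcoxon_ranksum",
    "group_comparison",
]


# ---------------------------------------------------------------------------
# reference z-scoring and combined measures


def zscore_by_reference(
    table: pd.DataFrame,
    value_col: str = "value",
    group_col: str = "group",
    step_col: str = "condition",
    id_col: str = "participant_id",
    reference_group: str = "CON",
) -> pd.DataFrame:
    """Z-score a metric per step-size against the reference group, then
    average over steps.

    Parameters with different scales across step-sizes become comparable by
    z-scoring each step separately with the reference group's mean and SD;
    the per-participant mean over steps is the combined measure.  Returns a
    table with ``z`` per row plus a ``combined`` column merged back per
    participant.
    """
    out = table.copy()
    zs = []
    for step, sub in out.groupby(step_col, sort=True):
        ref = sub.loc[sub[group_col] == reference_group, value_col]
        if len(ref) < 2:
            raise DegenerateInputError(
                f"reference group needs >=2 values in step {step!r}"
            )
        mu, sd = float(ref.mean()), float(ref.std(ddof=1))
        if sd == 0:
            raise DegenerateInputError(f"reference SD is zero in step {step!r}")
        z = (sub[value_col] - mu) / sd
        zs.append(pd.Series(z, index=sub.index))
    out["z"] = pd.concat(zs).sort_index()
    combined = out.groupby(id_col)["z"].mean().rename("combined")
    return out.merge(combined, on=id_col)


def update_rate(alpha_z: pd.Series, beta_z: pd.Series) -> pd.Series:
    """Combined update-rate score: mean of the (reference-z-scored) phase
    correction from the isochronous experiment and period correction from
    the tempo-switch experiment, indexed by participant.  Missing either
    component leaves the participant missing."""
    df = pd.concat({"alpha_z": alpha_z, "beta_z": beta_z}, axis=1)
    return df.mean(axis=1, skipna=False).rename("update_rate")


# ---------------------------------------------------------------------------
# rank tests and effect sizes


@dataclass(frozen=True)
class GroupComparison:
    """Kruskal-Wallis omnibus plus rank-based Tukey-Kramer post hoc."""

    h_statistic: float
    p_value: float
    df: int
    group_names: tuple
    medians: dict
    iqrs: dict
    posthoc_p: dict = field(default_factory=dict)  # (g1, g2) -> p
    cliffs: dict = field(default_factory=dict)  # (g1, g2) -> delta


def kruskal_wallis(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H with chi-square reference (df = k-1)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise DegenerateInputError("need >=2 groups with >=2 observations each")
    if np.ptp(np.concatenate(groups)) == 0:
        return 0.0, 1.0
    res = sps.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)


def posthoc_tukey_kramer_ranks(groups: Sequence[np.ndarray]) -> np.ndarray:
    """Pairwise p-values from the studentized-range test on group mean ranks.

    This is the standard post hoc convention after a Kruskal-Wallis test in
    common statistical toolboxes: all observations are ranked together
    (ties averaged), and mean-rank differences are referred to the
    studentized range with infinite degrees of freedom, with the
    Tukey-Kramer unequal-n standard error and a tie correction on the rank
    variance.  Returns a k x k symmetric matrix of p-values.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    pooled = np.concatenate(groups)
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)
    sizes = [len(g) for g in groups]
    splits = np.cumsum(sizes)[:-1]
    group_ranks = np.split(ranks, splits)
    mean_ranks = [r.mean() for r in group_ranks]
    # tie-corrected variance of the ranks
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - (counts**3 - counts).sum() / (n_total**3 - n_total)
    var = n_total * (n_total + 1) / 12.0 * tie
    p = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(var / 2.0 * (1.0 / sizes[i] + 1.0 / sizes[j]))
            q = abs(mean_ranks[i] - mean_ranks[j]) / se
            pij = float(sps.studentized_range.sf(q, k, np.inf))
            p[i, j] = p[j, i] = min(pij, 1.0)
    return p


def cliffs_delta(x, y) -> float:
    """Cliff's delta: P(x > y) - P(x < y) over all cross-pairs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise DegenerateInputError("both samples must be non-empty")
    diff = x[:, None] - y[None, :]
    return float((np.sign(diff)).mean())


def group_comparison(
    samples: dict, posthoc: bool = True
) -> GroupComparison:
    """Full omnibus + post hoc + effect-size report for named groups."""
    names = tuple(samples.keys())
    arrays = [np.asarray(samples[n], dtype=float) for n in names]
    h, p = kruskal_wallis(arrays)
    medians = {n: float(np.median(a)) for n, a in zip(names, arrays)}
    iqrs = {n: float(np.subtract(*np.percentile(a, [75, 25]))) for n, a in zip(names, arrays)}
    post, cliffs = {}, {}
    if posthoc:
        pmat = posthoc_tukey_kramer_ranks(arrays)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                post[(names[i], names[j])] = float(pmat[i, j])
                cliffs[(names[i], names[j])] = cliffs_delta(arrays[i], arrays[j])
    return GroupComparison(
        h_statistic=h,
        p_value=p,
        df=len(names) - 1,
        group_names=names,
        medians=medians,
        iqrs=iqrs,
        posthoc_p=post,
        cliffs=cliffs,
    )


def correlations(
    x, y, method: str = "spearman", alternative: str = "two-sided"
) -> tuple[float, float]:
    """Paired correlation coefficient and p-value.

    One-sided alternatives are supported for a-priori directional
    hypotheses.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise InputError("x and y must be paired")
    if len(x) < 4:
        raise DegenerateInputError("need at least 4 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("constant input has no defined correlation")
    if method == "spearman":
        res = sps.spearmanr(x, y, alternative=alternative)
    elif method == "pearson":
        res = sps.pearsonr(x, y, alternative=alternative)
    else:
        raise InputError("method must be 'spearman' or 'pearson'")
    return float(res.statistic), float(res.pvalue)


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    return float(sps.spearmanr(x, y).statistic)


def bootstrap_corr_difference(
    group_a: tuple[np.ndarray, np.ndarray],
    group_b: tuple[np.ndarray, np.ndarray],
    n_boot: int = 1000,
    seed: Optional[int] = None,
    max_retries: int = 100,
) -> dict:
    """Bootstrap test that two groups share one correlation structure.

    Each replicate resamples both groups with replacement, computes the
    Spearman correlation within each group and on the pooled sample, and
    records the three differences (A - pooled, B - pooled, A - B).  The
    reported p-value per contrast is the two-sided tail proportion of zero
    within the surrogate distribution of differences, with the add-one
    correction (b+1)/(B+1).  Degenerate (constant) resamples are redrawn up
    to ``max_retries`` times.
    """
    xa, ya = (np.asarray(v, dtype=float) for v in group_a)
    xb, yb = (np.asarray(v, dtype=float) for v in group_b)
    if len(xa) < 5 or len(xb) < 5:
        raise DegenerateInputError("both groups need at least 5 pairs")
    rng = np.random.default_rng(seed)
    diffs = np.empty((n_boot, 3))
    for b in range(n_boot):
        for _ in range(max_retries):
            ia = rng.integers(0, len(xa), len(xa))
            ib = rng.integers(0, len(xb), len(xb))
            sxa, sya = xa[ia], ya[ia]
            sxb, syb = xb[ib], yb[ib]
            if np.ptp(sxa) and np.ptp(sya) and np.ptp(sxb) and np.ptp(syb):
                break
        else:
            raise DegenerateInputError("could not draw a non-degenerate resample")
        ra = _spearman(sxa, sya)
        rb = _spearman(sxb, syb)
        rall = _spearman(np.concatenate([sxa, sxb]), np.concatenate([sya, syb]))
        diffs[b] = (ra - rall, rb - rall, ra - rb)

    labels = ("a_vs_all", "b_vs_all", "a_vs_b")
    out = {}
    for i, lab in enumerate(labels):
        d = diffs[:, i]
        lo = (np.sum(d <= 0) + 1) / (n_boot + 1)
        hi = (np.sum(d >= 0) + 1) / (n_boot + 1)
        out[lab] = {"p": float(min(1.0, 2 * min(lo, hi))), "mean_diff": float(d.mean())}
    return out


# ---------------------------------------------------------------------------
# AQ50 factor scoring


@dataclass(frozen=True)
class AQ50FactorSpec:
    """Item layout of one AQ50 factor: (item_number, reverse_keyed) pairs.

    Responses are coded 0 (definitely disagree) to 3 (definitely agree);
    reverse-keyed items are scored ``3 - raw`` so higher factor scores
    always mean more autistic traits.
    """

    name: str
    items: tuple[tuple[int, bool], ...]

    @property
    def max_score(self) -> int:
        return 3 * len(self.items)


#: Default three-factor layout (social skill: 12 items, 9 reverse-keyed;
#: communication/mindreading: 6 items, 1 reverse-keyed), with item numbers
#: following the published 50-item ordering of the instrument.  Override
#: with a custom :class:`AQ50FactorSpec` if your export numbers items
#: differently.
DEFAULT_AQ50_FACTORS = {
    "social_skill": AQ50FactorSpec(
        "social_skill",
        (
            (11, True),   # I find social situations easy.
            (13, False),  # I would rather go to a library than to a party.
            (15, True),   # I find myself drawn more strongly to people than to things.
            (17, True),   # I enjoy social chit-chat.
            (22, False),  # I find it hard to make new friends.
            (26, False),  # I frequently find that I don't know how to keep a conversation going.
            (34, True),   # I enjoy doing things spontaneously.
            (38, True),   # I am good at social chit-chat.
            (40, True),   # When I was young, I used to enjoy playing games involving pretending.
            (44, True),   # I enjoy social occasions.
            (47, True),   # I enjoy meeting new people.
            (50, True),   # I find it very easy to play games with children that involve pretending.
        ),
    ),
    "communication_mindreading": AQ50FactorSpec(
        "communication_mindreading",
        (
            (7, False),   # Other people frequently tell me that what I've said is impolite.
            (20, False),  # When reading a story, I find it difficult to work out the characters' intentions.
            (27, True),   # If there is an interruption, I can switch back very quickly.
            (31, False),  # I am often the last to understand the point of a joke.
            (39, False),  # People often tell me that I keep going on and on about the same thing.
            (45, False),  # I find it difficult to work out people's intentions.
        ),
    ),
}


@dataclass(frozen=True)
class AQ50Factors:
    social_skill: int
    communication_mindreading: int


def aq50_factor_scores(
    responses: dict | pd.Series,
    factors: Optional[dict] = None,
) -> AQ50Factors:
    """Score the AQ50 three-factor structure for one respondent.

    ``responses`` maps item number (1..50) to an integer 0..3 response (a
    pandas Series with ``item_<n>`` labels also works).
    """
    if factors is None:
        factors = DEFAULT_AQ50_FACTORS
    if isinstance(responses, pd.Series):
        responses = {
            int(str(k).replace("item_", "")): v for k, v in responses.items()
        }
    scores = {}
    for fname, spec in factors.items():
        total = 0
        for item, reverse in spec.items:
            if item not in responses:
                raise InputError(f"missing response for item {item}")
            raw = responses[item]
            if not float(raw).is_integer() or not 0 <= int(raw) <= 3:
                raise InputError(f"item {item} response must be an integer 0..3")
            raw = int(raw)
            total += (3 - raw) if reverse else raw
        scores[fname] = total
    return AQ50Factors(
        social_skill=scores["social_skill"],
        communication_mindreading=scores["communication_mindreading"],
    )


# ---------------------------------------------------------------------------
# remaining scipy-backed tests behind the module surface


def chi_square_counts(contingency) -> tuple[float, float]:
    """Pearson chi-square on a groups x category count table."""
    table = np.asarray(contingency, dtype=float)
    if table.size == 0 or table.sum() == 0:
        raise DegenerateInputError("empty contingency table")
    if np.any(table < 0):
        raise InputError("counts must be non-negative")
    res = sps.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue)


def wilcoxon_ranksum(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Wilcoxon rank-sum test with tie-corrected normal approximation.

    Returns the rank-sum statistic of the first sample and the p-value
    (equivalent to Mann-Whitney U up to the affine shift
    ``W = U + n_x (n_x + 1) / 2``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise DegenerateInputError("both samples must be non-empty")
    res = sps.mannwhitneyu(x, y, alternative=alternative, method="asymptotic")
    w = float(res.statistic + len(x) * (len(x) + 1) / 2)
    return w, float(res.pvalue)
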