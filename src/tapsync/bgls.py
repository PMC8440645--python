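"""Bounded generalized-least-squares (bGLS) estimation of tapping models.

Two linear models of paced tapping are fitted:

* **Isochronous model** -- ``r_k = -alpha * ehat_{k-1} + t_0 + z_k`` with
  noise ``z_k = n_k + M_k - M_{k-1}``.  The residual is MA(1):
  ``gamma_0 = sigma_T^2 + 2 sigma_M^2``, ``gamma_1 = -sigma_M^2``, zero
  beyond, which is what lets timekeeper and motor noise be separated.
* **Tempo-switch model** -- the period estimate follows
  ``t_k = t_{k-1} - beta * ehat_{k-1}``; differencing removes the unknown
  changing mean and gives
  ``r_k - r_{k-1} = -(alpha+beta) ehat_{k-1} + alpha ehat_{k-2} + z_k`` with
  ``z_k = n_k - n_{k-1} + M_k - 2 M_{k-1} + M_{k-2}`` and MA(2) structure
  ``gamma_0 = 2 sigma_T^2 + 6 sigma_M^2``,
  ``gamma_1 = -(sigma_T^2 + 4 sigma_M^2)``, ``gamma_2 = sigma_M^2``.

Estimation iterates (i) GLS for the regression coefficients under the
current banded covariance, (ii) residual autocovariances mapped back to
``(sigma_T, sigma_M)`` under the bound ``0 <= sigma_M <= sigma_T`` (the
"bounded" in bGLS; the naive unbounded moment estimate is biased), until the
coefficients stabilise.  Missing data are handled by dropping the affected
rows and building the covariance over surviving rows by their true beat
lag, so non-adjacent survivors are uncorrelated exactly as the noise model
says.

The estimators are scikit-learn compatible (``fit``, ``get_params``,
fitted attributes with trailing underscores); the module-level functions
mirror them on the package's domain objects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize
from scipy import stats as sps
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array

from tapsync.core import AlignedTrial, DegenerateInputError, InputError

__all__ = [
    "IsochronousBGLS",
    "SwitchBGLS",
    "IsochronousFit",
    "ExtendedFit",
    "ModelComparison",
    "SwitchSegment",
    "build_regression_iso",
    "fit_bgls_iso",
    "extract_switch_segments",
    "fit_bgls_extended",
    "compare_models",
    "aggregate_fits",
]

_VAR_FLOOR = 1e-10


# ---------------------------------------------------------------------------
# moment maps: residual autocovariances -> (sigma_T^2, sigma_M^2, model gammas)


def _moments_iso(g0: float, g1: float) -> tuple[float, float, np.ndarray]:
    # z = n_k + M_k - M_{k-1}; bound sigma_M <= sigma_T <=> -g1 <= g0/3
    sm2 = float(np.clip(-g1, 0.0, g0 / 3.0))
    st2 = max(g0 - 2.0 * sm2, _VAR_FLOOR)
    return st2, sm2, np.array([st2 + 2 * sm2, -sm2])


def _moments_ext(g0: float, g1: float, g2: float) -> tuple[float, float, np.ndarray]:
    # z = n_k - n_{k-1} + M_k - 2 M_{k-1} + M_{k-2}
    # sigma_M^2 = gamma_2; sigma_T^2 = (gamma_0 - 6 gamma_2)/2; the bound
    # sigma_M <= sigma_T caps gamma_2 at gamma_0/8
    sm2 = float(np.clip(g2, 0.0, g0 / 8.0))
    st2 = max((g0 - 6.0 * sm2) / 2.0, max(sm2, _VAR_FLOOR))
    return st2, sm2, np.array([2 * st2 + 6 * sm2, -(st2 + 4 * sm2), sm2])


def _build_sigma(beat_idx: np.ndarray, gammas: np.ndarray) -> np.ndarray:
    """Banded covariance over surviving rows, keyed by true beat lag."""
    lag = np.abs(beat_idx[:, None] - beat_idx[None, :])
    sigma = np.zeros_like(lag, dtype=float)
    for l, g in enumerate(gammas):
        sigma[lag == l] = g
    return sigma


def _empirical_gammas(resid: np.ndarray, beat_idx: np.ndarray, band: int) -> np.ndarray:
    out = np.empty(band + 1)
    for l in range(band + 1):
        pairs = beat_idx[:, None] - beat_idx[None, :] == l
        if l == 0:
            out[0] = float(np.mean(resid**2))
        else:
            i, j = np.nonzero(pairs)
            out[l] = float(np.mean(resid[i] * resid[j])) if len(i) else 0.0
    return out


def _gaussian_loglik(resid: np.ndarray, sigma: np.ndarray) -> float:
    n = len(resid)
    try:
        c, low = linalg.cho_factor(sigma, check_finite=False)
    except linalg.LinAlgError:
        return -np.inf
    logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
    quad = float(resid @ linalg.cho_solve((c, low), resid, check_finite=False))
    return -0.5 * (n * np.log(2 * np.pi) + logdet + quad)


def _gls_solve(y: np.ndarray, X: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    c, low = linalg.cho_factor(sigma, check_finite=False)
    Si_X = linalg.cho_solve((c, low), X, check_finite=False)
    Si_y = linalg.cho_solve((c, low), y, check_finite=False)
    return np.linalg.solve(X.T @ Si_X, X.T @ Si_y)


def _iterate_bgls(
    y: np.ndarray,
    X: np.ndarray,
    beat_idx: np.ndarray,
    moment_map,
    band: int,
    max_iter: int,
    tol: float,
):
    """Shared bGLS loop; returns (b, st2, sm2, sigma, n_iter, converged, clamped)."""
    n = len(y)
    sigma = np.eye(n)
    b = np.zeros(X.shape[1])
    st2 = sm2 = np.nan
    converged = False
    clamped = False
    for it in range(1, max_iter + 1):
        b_new = _gls_solve(y, X, sigma)
        resid = y - X @ b_new
        g = _empirical_gammas(resid, beat_idx, band)
        if g[0] < 1e-9:  # (near-)noise-free data: OLS is exact
            st2, sm2 = _VAR_FLOOR, 0.0
            sigma = _build_sigma(beat_idx, moment_map(*([g[0]] + [0.0] * band))[2])
            b, converged = b_new, True
            break
        st2, sm2, gam = moment_map(*g)
        if band == 1:
            clamped = clamped or not (-g[0] / 3 <= g[1] <= 0)
        else:
            clamped = clamped or not (0 <= g[2] <= g[0] / 8)
        sigma = _build_sigma(beat_idx, gam)
        if np.max(np.abs(b_new - b)) < tol and it > 1:
            b, converged = b_new, True
            break
        b = b_new
    return b, st2, sm2, sigma, it, converged, clamped


class _BaseBGLS(BaseEstimator):
    """Common fit machinery for the two bGLS estimators."""

    _band: int
    _n_model_params: int

    def __init__(self, max_iter: int = 20, tol: float = 1e-6):
        self.max_iter = max_iter
        self.tol = tol

    def _moment_map(self):
        raise NotImplementedError

    def _design(self, X: np.ndarray) -> np.ndarray:
        return X

    def _unpack(self, b: np.ndarray) -> None:
        raise NotImplementedError

    def fit(self, X, y, beat_index: Optional[Sequence[int]] = None):
        """Fit the model.

        Parameters
        ----------
        X : array (n_rows, n_regressors)
            Lagged perceived asynchronies (see subclass docstrings).
        y : array (n_rows,)
            Demeaned inter-tap intervals (or their differences).
        beat_index : array of int, optional
            Beat number of each row; consecutive numbers mean temporally
            adjacent rows.  Rows surviving around missing taps keep their
            true lag, which is how missing data enter the covariance.
            Defaults to 0..n-1 (complete data).
        """
        X = check_array(X, ensure_2d=True, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if len(y) != X.shape[0]:
            raise InputError("X and y must have the same number of rows")
        if np.isnan(X).any() or np.isnan(y).any():
            raise InputError("masked rows must be removed before fitting")
        beat_idx = (
            np.arange(len(y)) if beat_index is None else np.asarray(beat_index, dtype=int)
        )
        if len(beat_idx) != len(y):
            raise InputError("beat_index must parallel y")
        Xd = self._design(X)
        if len(y) < Xd.shape[1] + 2:
            raise DegenerateInputError("too few usable rows for a bGLS fit")
        b, st2, sm2, sigma, n_iter, converged, clamped = _iterate_bgls(
            y, Xd, beat_idx, self._moment_map(), self._band, self.max_iter, self.tol
        )
        self.coef_ = b
        self.sigma_t_ = float(np.sqrt(st2))
        self.sigma_m_ = float(np.sqrt(sm2))
        self.n_obs_ = len(y)
        self.n_iter_ = n_iter
        self.converged_ = bool(converged)
        self.bound_active_ = bool(clamped)
        self.loglik_ = _gaussian_loglik(y - Xd @ b, sigma)
        self.aic_ = 2 * self._n_model_params - 2 * self.loglik_
        self._unpack(b)
        return self


class IsochronousBGLS(_BaseBGLS):
    """bGLS estimator of the fixed-tempo model ``(alpha, sigma_T, sigma_M)``.

    ``fit(X, y)`` expects ``X[:, 0] = ehat_{k-1}`` (perceived asynchrony one
    beat back) and ``y = r_k - t_0`` (inter-tap interval centred on the
    metronome period), e.g. from :func:`build_regression_iso`.

    Attributes after fitting: ``alpha_``, ``sigma_t_``, ``sigma_m_``,
    ``loglik_``, ``aic_``, ``n_obs_``, ``converged_``, ``bound_active_``.
    """

    _band = 1
    _n_model_params = 3  # alpha, sigma_T, sigma_M

    def _moment_map(self):
        return _moments_iso

    def _unpack(self, b: np.ndarray) -> None:
        self.alpha_ = float(-b[0])


class SwitchBGLS(_BaseBGLS):
    """bGLS estimator of the tempo-tracking model ``(alpha, beta, sigma_T,
    sigma_M)`` on the differenced regression.

    ``fit(X, y)`` expects ``X = [ehat_{k-1}, ehat_{k-2}]`` and
    ``y = r_k - r_{k-1}``.  With ``fit_period_correction=False`` the nested
    fixed-period variant is fitted on the same rows (single regressor
    ``ehat_{k-1} - ehat_{k-2}``, ``beta_ = 0``), which is the reduced model
    of the likelihood-ratio comparison.
    """

    _band = 2

    def __init__(self, max_iter: int = 20, tol: float = 1e-6,
                 fit_period_correction: bool = True):
        super().__init__(max_iter=max_iter, tol=tol)
        self.fit_period_correction = fit_period_correction

    @property
    def _n_model_params(self) -> int:
        return 4 if self.fit_period_correction else 3

    def _moment_map(self):
        return _moments_ext

    def _design(self, X: np.ndarray) -> np.ndarray:
        if X.shape[1] != 2:
            raise InputError("X must have columns [ehat_{k-1}, ehat_{k-2}]")
        if self.fit_period_correction:
            return X
        return (X[:, 0] - X[:, 1])[:, None]

    def _unpack(self, b: np.ndarray) -> None:
        if self.fit_period_correction:
            c1, c2 = b
            self.alpha_ = float(c2)
            self.beta_ = float(-c1 - c2)
        else:
            self.alpha_ = float(-b[0])
            self.beta_ = 0.0


# ---------------------------------------------------------------------------
# record types and domain-object wrappers


@dataclass(frozen=True)
class IsochronousFit:
    alpha: float
    sigma_T: float
    sigma_M: float
    t0: float
    n_obs: int
    converged: bool
    loglik: float
    bound_active: bool = False


@dataclass(frozen=True)
class ExtendedFit:
    alpha: float
    beta: float
    sigma_T: float
    sigma_M: float
    n_obs: int
    converged: bool
    loglik: float
    aic: float
    bound_active: bool = False


@dataclass(frozen=True)
class ModelComparison:
    lrt_stat: float
    lrt_p: float
    delta_aic: float  # AIC(extended) - AIC(reduced); negative favours extended
    n_obs: int


@dataclass(frozen=True)
class SwitchSegment:
    """One complete tempo-change window (default two beats before to seven
    after the change) cut from a switching block."""

    beats: np.ndarray
    e: np.ndarray
    r: np.ndarray
    switch_index: int
    direction: str
    step_size: float


def build_regression_iso(
    trial: AlignedTrial, min_rows: int = 10
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Regression arrays ``(y, X, beat_index)`` for the isochronous model.

    The block mean asynchrony (over all valid beats) defines the perceived
    asynchrony; ``y`` is centred on the metronome period so the regression
    is intercept-free.  Rows where ``r_k`` or ``ehat_{k-1}`` touch a missing
    tap are dropped; blocks with >= 40% missing taps are refused.
    """
    if trial.pct_missing >= 0.40:
        raise DegenerateInputError(
            f"block unusable for modelling ({trial.pct_missing:.0%} missing)"
        )
    valid = trial.valid_mask
    mean_async = float(trial.e[valid].mean())
    rows = np.flatnonzero(valid[1:] & valid[:-1]) + 1  # r_k needs taps k-1, k
    if len(rows) < min_rows:
        raise DegenerateInputError("fewer than the minimum usable rows")
    t0 = trial.metronome.base_period
    y = trial.r[rows] - t0
    X = (trial.e[rows - 1] - mean_async)[:, None]
    return y, X, rows


def fit_bgls_iso(
    trial_or_y,
    X: Optional[np.ndarray] = None,
    beat_index: Optional[np.ndarray] = None,
    max_iter: int = 20,
    tol: float = 1e-6,
) -> IsochronousFit:
    """Fit the isochronous model; accepts an AlignedTrial or (y, X, beats)."""
    if isinstance(trial_or_y, AlignedTrial):
        y, X, beat_index = build_regression_iso(trial_or_y)
        t0 = trial_or_y.metronome.base_period
    else:
        y = np.asarray(trial_or_y, dtype=float)
        t0 = np.nan
        if X is None:
            raise InputError("X required when passing raw arrays")
    est = IsochronousBGLS(max_iter=max_iter, tol=tol).fit(X, y, beat_index=beat_index)
    return IsochronousFit(
        alpha=est.alpha_,
        sigma_T=est.sigma_t_,
        sigma_M=est.sigma_m_,
        t0=float(t0),
        n_obs=est.n_obs_,
        converged=est.converged_,
        loglik=est.loglik_,
        bound_active=est.bound_active_,
    )


def extract_switch_segments(
    trial: AlignedTrial, window: tuple[int, int] = (-2, 7)
) -> list[SwitchSegment]:
    """Complete-data tempo-change segments from one switching block.

    Segments with any missing tap in the window or truncated by the block
    edges are dropped.  The block itself must be usable (< 40% missing).
    """
    if trial.metronome.protocol != "switching":
        raise InputError("switch segments need a switching block")
    if trial.pct_missing >= 0.40:
        raise DegenerateInputError("block unusable for modelling")
    w0, w1 = window
    segments = []
    for j, dr in zip(trial.switch_indices(), trial.switch_directions()):
        lo, hi = j + w0, j + w1
        if lo < 0 or hi >= trial.n_beats:
            continue
        beats = np.arange(lo, hi + 1)
        if not trial.valid_mask[beats].all():
            continue
        segments.append(
            SwitchSegment(
                beats=beats,
                e=trial.e[beats],
                r=trial.r[beats],
                switch_index=int(j),
                direction=dr,
                step_size=trial.metronome.step_size,
            )
        )
    return segments


def _segment_regression(
    segment: SwitchSegment, mean_asynchrony: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    e = segment.e - mean_asynchrony
    r = segment.r
    # y_k = r_k - r_{k-1} exists from the third beat of the segment
    y = r[2:] - r[1:-1]
    X = np.column_stack([e[1:-1], e[:-2]])
    beats = segment.beats[2:]
    return y, X, beats


def fit_bgls_extended(
    segment: SwitchSegment,
    mean_asynchrony: float,
    max_iter: int = 20,
    tol: float = 1e-6,
    min_rows: int = 6,
) -> ExtendedFit:
    """Fit the tempo-switch model to one change segment.

    ``mean_asynchrony`` must come from the *entire* block (the perceived
    asynchrony is relative to it), not from the short segment.
    """
    y, X, beats = _segment_regression(segment, mean_asynchrony)
    if len(y) < min_rows:
        raise DegenerateInputError("segment has fewer than 6 usable difference rows")
    est = SwitchBGLS(max_iter=max_iter, tol=tol).fit(X, y, beat_index=beats)
    return ExtendedFit(
        alpha=est.alpha_,
        beta=est.beta_,
        sigma_T=est.sigma_t_,
        sigma_M=est.sigma_m_,
        n_obs=est.n_obs_,
        converged=est.converged_,
        loglik=est.loglik_,
        aic=est.aic_,
        bound_active=est.bound_active_,
    )


def _profile_loglik(y, X, beat_idx, band, theta):
    """Gaussian log-likelihood profiled over the coefficients at noise
    parameters theta = (log sigma_T^2, log sigma_M^2 ratio)."""
    st2 = np.exp(np.clip(theta[0], -40, 40))
    frac = 1.0 / (1.0 + np.exp(-np.clip(theta[1], -40, 40)))
    sm2 = st2 * frac  # sigma_M^2 in [0, sigma_T^2]
    sigma = _build_sigma(beat_idx, np.array(_model_gammas_from(st2, sm2, band)))
    try:
        b = _gls_solve(y, X, sigma)
    except linalg.LinAlgError:
        return -np.inf
    return _gaussian_loglik(y - X @ b, sigma)


def _model_gammas_from(st2: float, sm2: float, band: int) -> tuple:
    if band == 1:
        return (st2 + 2 * sm2, -sm2)
    return (2 * st2 + 6 * sm2, -(st2 + 4 * sm2), sm2)


def _ml_loglik(y, X, beat_idx, band, starts) -> float:
    best = -np.inf
    for s in starts:
        res = optimize.minimize(
            lambda th: -_profile_loglik(y, X, beat_idx, band, th),
            x0=np.asarray(s, dtype=float),
            method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 200},
        )
        best = max(best, -res.fun)
    return best


def _theta_from(st2: float, sm2: float) -> np.ndarray:
    st2 = max(st2, _VAR_FLOOR)
    frac = np.clip(sm2 / st2, 1e-6, 1 - 1e-6)
    return np.array([np.log(st2), np.log(frac / (1 - frac))])


def compare_models(
    segment: SwitchSegment, mean_asynchrony: float
) -> ModelComparison:
    """Likelihood-ratio test and AIC difference, extended vs reduced model.

    Both models are evaluated on identical rows.  For the comparison the
    likelihood of each model is maximised over its noise parameters (with
    the coefficients profiled out by GLS); the reduced-model optimum is also
    evaluated under the extended model, so the nesting inequality holds
    exactly and the LRT statistic is non-negative.
    """
    y, X, beats = _segment_regression(segment, mean_asynchrony)
    if len(y) < 6:
        raise DegenerateInputError("segment has fewer than 6 usable difference rows")
    ext = SwitchBGLS().fit(X, y, beat_index=beats)
    red = SwitchBGLS(fit_period_correction=False).fit(X, y, beat_index=beats)
    Xr = (X[:, 0] - X[:, 1])[:, None]
    th_red = _theta_from(red.sigma_t_**2, red.sigma_m_**2)
    th_ext = _theta_from(ext.sigma_t_**2, ext.sigma_m_**2)
    ll_red = _ml_loglik(y, Xr, beats, 2, [th_red, th_ext])
    ll_ext = _ml_loglik(y, X, beats, 2, [th_ext, th_red])
    ll_ext = max(ll_ext, ll_red)  # reduced optimum lies inside the extended space
    stat = 2.0 * (ll_ext - ll_red)
    return ModelComparison(
        lrt_stat=float(stat),
        lrt_p=float(sps.chi2.sf(stat, df=1)),
        delta_aic=float((2 * 4 - 2 * ll_ext) - (2 * 3 - 2 * ll_red)),
        n_obs=len(y),
    )


PARAM_COLS = ["alpha", "beta", "sigma_T", "sigma_M"]


def aggregate_fits(
    fits: pd.DataFrame,
    by: Sequence[str] = ("participant_id", "group", "condition"),
    block_col: str = "block_id",
    params: Sequence[str] = tuple(PARAM_COLS),
) -> pd.DataFrame:
    """Average fitted parameters with the fixed order: segments within a
    block first, then blocks within a participant x condition cell.

    Blocks are weighted equally regardless of how many segments survived in
    each; empty cells simply stay absent from the output.
    """
    params = [p for p in params if p in fits.columns]
    if fits.empty:
        return pd.DataFrame(columns=list(by) + params)
    per_block = fits.groupby(list(by) + [block_col], sort=True)[params].mean()
    out = per_block.groupby(list(by), sort=True).mean().reset_index()
    return out
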