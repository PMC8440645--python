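"""Bounded-GLS estimation: regression construction, noise separation,
missing data, model comparison and aggregation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from tapsync import bgls, core, synth


def simulate_iso_trial(alpha=0.4, sigma_T=20.0, sigma_M=8.0, n_beats=100,
                       miss_rate=0.0, seed=0):
    rng = np.random.default_rng(seed)
    m = synth.generate_metronome("isochronous", 500.0, n_beats=n_beats)
    p = synth.TapperParams(alpha=alpha, sigma_T=sigma_T, sigma_M=sigma_M,
                           mean_asynchrony=-30.0, miss_rate=miss_rate)
    taps, _ = synth.simulate_tapper(m, p, rng=rng)
    return core.match_taps_to_beats(m, taps)


class TestRegressionConstruction:
    def test_complete_block_row_count(self):
        trial = simulate_iso_trial(n_beats=100)
        y, X, beats = bgls.build_regression_iso(trial)
        # 100 beats, 3-beat lead-in -> 97 aligned beats -> 96 interval rows
        assert len(y) == trial.n_beats - 1
        assert X.shape == (len(y), 1)

    def test_missing_tap_masks_dependent_rows(self):
        trial = simulate_iso_trial(n_beats=60)
        j = 30
        trial.status[j] = core.STATUS_OMITTED
        trial.e[j] = trial.r[j] = trial.r[j + 1] = trial.d[j] = np.nan
        y, X, beats = bgls.build_regression_iso(trial)
        assert j not in beats and (j + 1) not in beats
        assert (j - 1) in beats and (j + 2) in beats

    def test_noise_free_trial_has_zero_residuals(self):
        m = synth.generate_metronome("isochronous", 500.0, n_beats=50)
        p = synth.TapperParams(alpha=0.4, sigma_T=1e-9, sigma_M=0.0,
                               mean_asynchrony=-30.0)
        taps, _ = synth.simulate_tapper(m, p)
        trial = core.match_taps_to_beats(m, taps)
        y, X, _ = bgls.build_regression_iso(trial)
        b = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.abs(y - X @ b).max() < 1e-8

    def test_unusable_block_refused(self):
        trial = simulate_iso_trial(n_beats=60)
        trial.status[::2] = core.STATUS_OMITTED
        with pytest.raises(core.DegenerateInputError):
            bgls.build_regression_iso(trial)


class TestGLSOracle:
    def test_gls_matches_dense_closed_form(self, rng):
        n = 30
        beats = np.arange(n)
        X = rng.normal(size=(n, 2))
        y = rng.normal(size=n)
        sigma = bgls._build_sigma(beats, np.array([5.0, -1.2]))
        b = bgls._gls_solve(y, X, sigma)
        si = np.linalg.inv(sigma)
        b_ref = np.linalg.inv(X.T @ si @ X) @ X.T @ si @ y
        np.testing.assert_allclose(b, b_ref, atol=1e-10)

    def test_gaussian_loglik_matches_scipy(self, rng):
        n = 12
        sigma = bgls._build_sigma(np.arange(n), np.array([4.0, -1.0]))
        resid = rng.normal(size=n)
        ll = bgls._gaussian_loglik(resid, sigma)
        ll_ref = sps.multivariate_normal(np.zeros(n), sigma).logpdf(resid)
        assert ll == pytest.approx(ll_ref, abs=1e-8)


class TestIsochronousFit:
    def test_zero_motor_noise_reduces_to_ols(self):
        trial = simulate_iso_trial(alpha=0.4, sigma_T=20.0, sigma_M=1e-9,
                                   n_beats=400, seed=2)
        fit = bgls.fit_bgls_iso(trial)
        y, X, _ = bgls.build_regression_iso(trial)
        b_ols = np.linalg.lstsq(X, y, rcond=None)[0]
        # sigma_M^2 is a clamped moment estimate: at true 0 it sits within
        # sampling noise of the lag-1 autocovariance (~gamma_0/sqrt(n))
        assert fit.sigma_M**2 < 3 * fit.sigma_T**2 / np.sqrt(fit.n_obs)
        assert fit.alpha == pytest.approx(float(-b_ols[0]), abs=0.05)

    def test_identity_covariance_fit_is_exactly_ols(self, rng):
        # when the fitted covariance stays diagonal (clamp at sigma_M = 0)
        # the GLS estimate coincides with ordinary least squares
        X = rng.normal(size=(150, 1))
        y = -0.4 * X[:, 0] + rng.normal(size=150)
        est = bgls.IsochronousBGLS().fit(X, y)
        b_ols = np.linalg.lstsq(X, y, rcond=None)[0]
        if est.sigma_m_ == 0.0:
            assert est.alpha_ == pytest.approx(float(-b_ols[0]), abs=1e-9)
        else:
            assert est.alpha_ == pytest.approx(float(-b_ols[0]), abs=0.05)

    def test_uncorrelated_data_gives_zero_alpha(self, rng):
        y = rng.normal(size=200)
        X = rng.normal(size=(200, 1))
        fit = bgls.fit_bgls_iso(y, X=X)
        assert abs(fit.alpha) < 0.2

    def test_recovery_at_cohort_median_parameters(self):
        ests = []
        for seed in range(8):
            fits = [bgls.fit_bgls_iso(simulate_iso_trial(
                alpha=0.37, sigma_T=20.9, sigma_M=8.1, seed=100 + 2 * seed + b))
                for b in range(2)]
            ests.append([np.mean([f.alpha for f in fits]),
                         np.mean([f.sigma_T for f in fits]),
                         np.mean([f.sigma_M for f in fits])])
        mean = np.mean(ests, axis=0)
        assert mean[0] == pytest.approx(0.37, abs=0.08)
        assert mean[1] == pytest.approx(20.9, abs=3.0)
        assert mean[2] == pytest.approx(8.1, abs=4.0)

    def test_intercept_variant_is_equivalent_on_complete_data(self):
        trial = simulate_iso_trial(seed=5)
        y, X, beats = bgls.build_regression_iso(trial)
        fit = bgls.fit_bgls_iso(trial)
        Xi = np.column_stack([X, np.ones(len(y))])
        est = bgls.IsochronousBGLS().fit(Xi, y, beat_index=beats)
        assert float(-est.coef_[0]) == pytest.approx(fit.alpha, abs=0.02)

    def test_motor_noise_bound_respected_when_true_value_near_bound(self):
        for seed in range(5):
            trial = simulate_iso_trial(alpha=0.4, sigma_T=12.0, sigma_M=10.0,
                                       seed=50 + seed)
            fit = bgls.fit_bgls_iso(trial)
            assert fit.sigma_M <= fit.sigma_T + 1e-9

    def test_missing_data_fit_stays_close_to_complete_fit(self):
        complete = simulate_iso_trial(alpha=0.4, n_beats=400, seed=7)
        gappy = simulate_iso_trial(alpha=0.4, n_beats=400, miss_rate=0.1, seed=7)
        f1 = bgls.fit_bgls_iso(complete)
        f2 = bgls.fit_bgls_iso(gappy)
        assert f2.alpha == pytest.approx(f1.alpha, abs=0.15)
        assert f2.n_obs < f1.n_obs

    def test_sklearn_estimator_contract(self):
        est = bgls.IsochronousBGLS(max_iter=25)
        assert est.get_params()["max_iter"] == 25
        est.set_params(tol=1e-5)
        trial = simulate_iso_trial()
        y, X, beats = bgls.build_regression_iso(trial)
        est.fit(X, y, beat_index=beats)
        for attr in ("alpha_", "sigma_t_", "sigma_m_", "loglik_", "converged_"):
            assert hasattr(est, attr)
        with pytest.raises(core.InputError):
            est.fit(X[:10], y[:9])


def simulate_switch_trial(alpha=0.3, beta=0.4, sigma_T=15.0, sigma_M=5.0,
                          step=90.0, n_beats=100, seed=0):
    rng = np.random.default_rng(seed)
    m = synth.generate_metronome("switching", 500.0, step_size=step,
                                 n_beats=n_beats, rng=rng)
    p = synth.TapperParams(alpha=alpha, beta=beta, sigma_T=sigma_T,
                           sigma_M=sigma_M, mean_asynchrony=-30.0)
    taps, _ = synth.simulate_tapper(m, p, rng=rng)
    return core.match_taps_to_beats(m, taps)


def block_mean_async(trial):
    return float(trial.e[trial.valid_mask].mean())


class TestSwitchSegments:
    def test_segment_count_follows_switch_schedule(self):
        trial = simulate_switch_trial(seed=1)
        segs = bgls.extract_switch_segments(trial)
        n_eligible = sum(
            1 for j in trial.switch_indices()
            if j - 2 >= 0 and j + 7 < trial.n_beats
        )
        assert len(segs) == n_eligible
        assert all(len(s.beats) == 10 for s in segs)

    def test_missing_tap_in_window_drops_that_segment(self):
        trial = simulate_switch_trial(seed=2)
        before = bgls.extract_switch_segments(trial)
        j = before[1].switch_index + 3
        trial.status[j] = core.STATUS_OMITTED
        trial.e[j] = np.nan
        after = bgls.extract_switch_segments(trial)
        assert len(after) == len(before) - 1

    def test_switch_near_block_edge_dropped(self):
        trial = simulate_switch_trial(seed=3)
        last = trial.switch_indices()[-1]
        if last + 7 >= trial.n_beats:
            assert all(s.switch_index != last for s in bgls.extract_switch_segments(trial))


class TestExtendedFit:
    def test_noise_free_segment_recovers_alpha_beta_exactly(self):
        rng = np.random.default_rng(4)
        m = synth.generate_metronome("switching", 500.0, step_size=90.0,
                                     n_beats=100, rng=rng)
        p = synth.TapperParams(alpha=0.3, beta=0.4, sigma_T=1e-9, sigma_M=0.0,
                               mean_asynchrony=-30.0)
        taps, _ = synth.simulate_tapper(m, p, rng=rng)
        trial = core.match_taps_to_beats(m, taps)
        # the perceived asynchrony must be taken relative to the tapper's
        # true offset for exact recovery (the empirical block mean differs
        # by O(transition fraction), which the noise otherwise swamps)
        for seg in bgls.extract_switch_segments(trial):
            fit = bgls.fit_bgls_extended(seg, mean_asynchrony=-30.0)
            assert fit.alpha == pytest.approx(0.3, abs=1e-6)
            assert fit.beta == pytest.approx(0.4, abs=1e-6)

    def test_beta_zero_data_matches_reduced_model(self):
        alphas_ext, alphas_red, betas = [], [], []
        for seed in range(6):
            trial = simulate_switch_trial(alpha=0.5, beta=0.0, seed=20 + seed)
            ma = block_mean_async(trial)
            for seg in bgls.extract_switch_segments(trial):
                y, X, beats = bgls._segment_regression(seg, ma)
                ext = bgls.SwitchBGLS().fit(X, y, beat_index=beats)
                red = bgls.SwitchBGLS(fit_period_correction=False).fit(
                    X, y, beat_index=beats)
                alphas_ext.append(ext.alpha_)
                alphas_red.append(red.alpha_)
                betas.append(ext.beta_)
        assert np.mean(betas) == pytest.approx(0.0, abs=0.1)
        assert np.mean(alphas_ext) == pytest.approx(np.mean(alphas_red), abs=0.1)

    def test_noisy_segments_recover_parameters_on_average(self):
        alphas, betas = [], []
        for seed in range(10):
            trial = simulate_switch_trial(alpha=0.3, beta=0.4, seed=40 + seed)
            ma = block_mean_async(trial)
            for seg in bgls.extract_switch_segments(trial):
                fit = bgls.fit_bgls_extended(seg, ma)
                alphas.append(fit.alpha)
                betas.append(fit.beta)
        assert np.mean(alphas) == pytest.approx(0.3, abs=0.12)
        assert np.mean(betas) == pytest.approx(0.4, abs=0.12)

    def test_segment_too_short_refused(self):
        trial = simulate_switch_trial(seed=5)
        seg = bgls.extract_switch_segments(trial)[0]
        short = bgls.SwitchSegment(
            beats=seg.beats[:6], e=seg.e[:6], r=seg.r[:6],
            switch_index=seg.switch_index, direction=seg.direction,
            step_size=seg.step_size,
        )
        with pytest.raises(core.DegenerateInputError):
            bgls.fit_bgls_extended(short, 0.0)


class TestModelComparison:
    def test_nesting_and_formula(self):
        trial = simulate_switch_trial(alpha=0.3, beta=0.5, seed=6)
        ma = block_mean_async(trial)
        for seg in bgls.extract_switch_segments(trial)[:3]:
            cmp = bgls.compare_models(seg, ma)
            assert cmp.lrt_stat >= 0.0
            assert cmp.delta_aic == pytest.approx(2.0 - cmp.lrt_stat, abs=1e-9)
            assert 0.0 <= cmp.lrt_p <= 1.0

    def test_strong_period_correction_detected(self):
        trial = simulate_switch_trial(alpha=0.2, beta=0.6, sigma_T=8.0,
                                      sigma_M=2.0, seed=7)
        ma = block_mean_async(trial)
        ps = [bgls.compare_models(s, ma).lrt_p
              for s in bgls.extract_switch_segments(trial)]
        assert np.mean(np.array(ps) < 0.05) > 0.5

    def test_null_pvalues_not_degenerate(self):
        ps = []
        for seed in range(4):
            trial = simulate_switch_trial(alpha=0.5, beta=0.0, seed=60 + seed)
            ma = block_mean_async(trial)
            ps += [bgls.compare_models(s, ma).lrt_p
                   for s in bgls.extract_switch_segments(trial)]
        ps = np.array(ps)
        # under the null p-values spread over (0, 1); crude calibration check
        assert np.mean(ps < 0.05) < 0.35
        assert np.mean(ps > 0.5) > 0.2


class TestAggregation:
    def test_single_fit_cell_is_identity(self):
        fits = pd.DataFrame(
            [{"participant_id": "p1", "group": "CON", "condition": "step90",
              "block_id": 1, "alpha": 0.3, "beta": 0.4, "sigma_T": 20.0,
              "sigma_M": 5.0}]
        )
        agg = bgls.aggregate_fits(fits)
        assert agg.loc[0, "beta"] == pytest.approx(0.4)

    def test_blocks_weighted_equally_not_by_segment_count(self):
        rows = []
        for b, betas in ((1, [0.2, 0.4]), (2, [0.6, 0.6, 0.6, 0.6])):
            rows += [{"participant_id": "p1", "group": "CON",
                      "condition": "step90", "block_id": b, "alpha": 0.3,
                      "beta": v, "sigma_T": 20.0, "sigma_M": 5.0}
                     for v in betas]
        agg = bgls.aggregate_fits(pd.DataFrame(rows))
        # block means 0.3 and 0.6 -> 0.45, not the segment-weighted 0.5
        assert agg.loc[0, "beta"] == pytest.approx(0.45)

    def test_empty_cells_stay_absent(self):
        agg = bgls.aggregate_fits(pd.DataFrame())
        assert agg.empty
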