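"""Model-free statistics: persistence, AR structure, switch dynamics, ROC."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from tapsync import core, modelfree, synth


def ar_series(phis, n, rng):
    x = np.zeros(n + 100)
    for k in range(len(phis), len(x)):
        x[k] = sum(p * x[k - i - 1] for i, p in enumerate(phis)) + rng.normal()
    return x[100:]


class TestLag1Correlation:
    def test_perfect_overcorrection_alternation(self):
        e = np.tile([30.0, -30.0], 10)
        assert modelfree.lag1_correlation(e) == pytest.approx(-1.0)

    def test_white_noise_near_zero(self, rng):
        e = rng.normal(0, 20, 2000)
        assert abs(modelfree.lag1_correlation(e)) < 0.08

    def test_pairs_straddling_missing_are_dropped(self):
        e = np.array([1.0, 2.0, np.nan, 4.0, 5.0] * 5)
        r = modelfree.lag1_correlation(e)
        assert np.isfinite(r)

    def test_simulated_tapper_tracks_one_minus_alpha(self, rng):
        m = synth.generate_metronome("isochronous", 500.0, n_beats=2000)
        p = synth.TapperParams(alpha=0.31, sigma_T=20.0, sigma_M=1e-9,
                               mean_asynchrony=-30.0)
        taps, _ = synth.simulate_tapper(m, p, rng=rng)
        trial = core.match_taps_to_beats(m, taps)
        r = modelfree.lag1_correlation(core.perceived_asynchrony(trial))
        assert r == pytest.approx(0.69, abs=0.06)

    def test_insufficient_pairs_rejected(self):
        with pytest.raises(core.DegenerateInputError):
            modelfree.lag1_correlation(np.arange(5.0))


class TestStepwiseAR:
    def test_ar1_selects_one_lag_and_recovers_coefficient(self):
        rng = np.random.default_rng(0)
        x = ar_series((0.6,), 200, rng)
        fit = modelfree.fit_ar_stepwise(x)
        assert fit.n_selected_predictors == 1
        # fixed 4-lag coefficients are reported regardless of the path
        assert fit.coefficients.shape == (4,)
        b_oracle = np.linalg.lstsq(
            np.column_stack([x[3:-1], x[2:-2], x[1:-3], x[:-4]]), x[4:], rcond=None
        )[0]
        np.testing.assert_allclose(fit.coefficients, b_oracle, atol=1e-8)
        assert fit.coefficients[0] == pytest.approx(0.6, abs=0.15)

    def test_white_noise_usually_selects_nothing(self):
        # the 0.1 entry rule admits a spurious lag in ~10% of series
        selected = [
            modelfree.fit_ar_stepwise(
                np.random.default_rng(s).normal(size=300)
            ).n_selected_predictors
            for s in range(30)
        ]
        assert np.mean(np.array(selected) == 0) >= 0.75

    def test_group_level_uses_one_predictor_per_subject(self):
        rng = np.random.default_rng(2)
        series = [ar_series((0.5,), 150, rng) for _ in range(4)]
        fit = modelfree.fit_ar_stepwise(series, level="group")
        assert fit.level == "group"
        assert fit.coefficients.shape == (4, 4)  # subjects x lags
        assert fit.n_selected_predictors >= 1
        assert np.all(np.abs(fit.coefficients[:, 0] - 0.5) < 0.25)

    def test_rows_with_missing_lags_dropped_listwise(self):
        rng = np.random.default_rng(3)
        x = ar_series((0.6,), 300, rng)
        x[::37] = np.nan
        fit = modelfree.fit_ar_stepwise(x)
        assert np.isfinite(fit.coefficients).all()


class TestAlignSwitch:
    def _trials(self, alpha, beta, n_blocks=2, seed=0):
        rng = np.random.default_rng(seed)
        trials = []
        for _ in range(n_blocks):
            m = synth.generate_metronome("switching", 500.0, step_size=90.0,
                                         n_beats=100, rng=rng)
            p = synth.TapperParams(alpha=alpha, beta=beta, sigma_T=1e-9,
                                   sigma_M=0.0, mean_asynchrony=-30.0)
            taps, _ = synth.simulate_tapper(m, p, rng=rng)
            trials.append(core.match_taps_to_beats(m, taps))
        return trials

    def test_baseline_beats_sit_on_old_tempo(self):
        traj = modelfree.align_switch(self._trials(0.4, 0.3), "deceleration")
        # the two pre-change beats average exactly to the old period by
        # construction of the baseline alignment; each is close to it
        assert traj.mean[:2].mean() == pytest.approx(455.0, abs=1e-9)
        np.testing.assert_allclose(traj.mean[:2], 455.0, atol=5.0)

    def test_full_correction_reaches_new_tempo_at_beat_one(self):
        # alpha = beta = 1 makes the coupled error/period system nilpotent:
        # the surprise at beat 0 is fully absorbed by the next tap
        traj = modelfree.align_switch(self._trials(1.0, 1.0), "deceleration")
        assert traj.mean[2] == pytest.approx(455.0, abs=1e-6)  # beat 0: surprise
        np.testing.assert_allclose(traj.mean[3:], 545.0, atol=1e-6)

    def test_no_correction_keeps_producing_old_tempo_intervals(self):
        # a zero-gain tapper never updates: inter-tap intervals stay on the
        # first tempo through every switch (its delays drift off the beat,
        # so switch windows are not analysable; check the forward model)
        rng = np.random.default_rng(1)
        m = synth.generate_metronome("switching", 500.0, step_size=90.0,
                                     n_beats=40, rng=rng, first_tempo="short")
        p = synth.TapperParams(alpha=0.0, beta=0.0, sigma_T=1e-9, sigma_M=0.0,
                               mean_asynchrony=-30.0)
        _, state = synth.simulate_tapper(m, p, rng=rng)
        r = state.r[state.first_beat + 1:]
        np.testing.assert_allclose(r, 455.0, atol=1e-6)

    def test_under_correction_adapts_only_partially_within_seven_beats(self):
        traj = modelfree.align_switch(self._trials(0.3, 0.15, seed=2),
                                      "acceleration")
        post = traj.mean[2:]
        gap0 = abs(post[0] - 455.0)  # surprise beat: near the 90 ms step
        gap7 = abs(post[-1] - 455.0)
        assert gap0 > 60.0
        assert gap7 < gap0 / 2  # clear movement toward the new tempo
        assert gap7 > 2.0  # but not fully adapted

    def test_participants_with_too_few_segments_excluded(self):
        trials = self._trials(0.4, 0.3)
        traj = modelfree.align_switch(
            trials, "acceleration", participant_ids=["a", "b"], min_repetitions=1
        )
        assert set(traj.participant_ids) <= {"a", "b"}
        with pytest.raises(core.DegenerateInputError):
            modelfree.align_switch(
                trials, "acceleration", participant_ids=["a", "b"], min_repetitions=99
            )


class TestSeparability:
    def test_disjoint_samples_fully_separable(self):
        res = modelfree.separability(np.full(20, 600.0), np.full(20, 400.0))
        assert res.auc == pytest.approx(1.0)
        assert res.diff_means == pytest.approx(200.0)

    def test_identical_samples_at_chance(self, rng):
        x = rng.normal(500, 20, 200)
        res = modelfree.separability(x, x.copy())
        assert res.d_prime == pytest.approx(0.0)
        assert res.auc == pytest.approx(0.5)
        assert res.diff_means == pytest.approx(0.0)

    def test_gaussian_example_matches_closed_form(self):
        rng = np.random.default_rng(7)
        d1 = rng.normal(525, 20, 500)
        d2 = rng.normal(475, 20, 500)
        res = modelfree.separability(d1, d2)
        assert res.d_prime == pytest.approx(2.5, abs=0.2)
        assert res.auc == pytest.approx(sps.norm.cdf(2.5 / np.sqrt(2)), abs=0.02)

    def test_dprime_shift_invariant_diff_means_not_scale_normalized(self, rng):
        d1 = rng.normal(540, 15, 300)
        d2 = rng.normal(460, 15, 300)
        a = modelfree.separability(d1, d2)
        b = modelfree.separability(d1 + 100, d2 + 100)
        assert b.d_prime == pytest.approx(a.d_prime)
        assert b.diff_means == pytest.approx(a.diff_means)
        # doubling the spread about the means halves d' but not diff_means
        c = modelfree.separability(
            d1.mean() + 2 * (d1 - d1.mean()), d2.mean() + 2 * (d2 - d2.mean())
        )
        assert c.d_prime == pytest.approx(a.d_prime / 2, rel=1e-6)
        assert c.diff_means == pytest.approx(a.diff_means, rel=1e-6)

    @settings(max_examples=40, deadline=None)
    @given(seed=st.integers(0, 10_000), ties=st.booleans())
    def test_threshold_sweep_auc_equals_pairwise_oracle(self, seed, ties):
        rng = np.random.default_rng(seed)
        short = rng.normal(480, 25, 40)
        long_ = rng.normal(520, 25, 50)
        if ties:
            short = np.round(short, -1)
            long_ = np.round(long_, -1)
        res = modelfree.separability(long_, short)
        less = np.mean(short[:, None] < long_[None, :])
        eq = np.mean(short[:, None] == long_[None, :])
        assert res.auc == pytest.approx(less + 0.5 * eq, abs=1e-12)

    def test_orientation_is_anchored_to_tempo_identity(self):
        # anti-tracking delays give AUC below 0.5, deliberately not folded
        res = modelfree.separability(np.array([1.0, 2, 3]), np.array([4.0, 5, 6]))
        assert res.auc == 0.0

    def test_delay_pooling_excludes_post_switch_transient(self):
        rng = np.random.default_rng(4)
        m = synth.generate_metronome("switching", 500.0, step_size=90.0,
                                     n_beats=100, rng=rng)
        p = synth.TapperParams(alpha=0.5, beta=0.5, sigma_T=10.0, sigma_M=3.0,
                               mean_asynchrony=-30.0)
        taps, _ = synth.simulate_tapper(m, p, rng=rng)
        trial = core.match_taps_to_beats(m, taps)
        d_long, d_short = modelfree.delay_samples_by_tempo([trial])
        assert d_long.mean() > d_short.mean()
        n_kept = len(d_long) + len(d_short)
        n_defined = np.sum(~np.isnan(trial.d))
        assert n_kept < n_defined  # transient beats were dropped
        with pytest.raises(core.InputError):
            modelfree.delay_samples_by_tempo([trial], exclude_after_switch=7)
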