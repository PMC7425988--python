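"""Trial-based variability, noise-correlation, Fano and contrast statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from neuroquench.trial_stats import (
    TrialMatrix,
    cross_trial_correlation,
    cross_trial_variance,
    epoch_trial_rates,
    fano_factor,
    paired_contrast,
    remove_cross_trial_mean,
    within_trial_stats,
)


def make_matrix(rates, conditions=None, n_rest=None):
    rates = np.asarray(rates, dtype=float)
    n_trials, n_areas, n_t = rates.shape
    if conditions is None:
        conditions = np.arange(n_trials) % 2
    if n_rest is None:
        n_rest = n_t // 2
    rest = np.zeros(n_t, dtype=bool)
    rest[:n_rest] = True
    return TrialMatrix(rates=rates, condition=np.asarray(conditions),
                       epoch_masks={"rest": rest, "task": ~rest})


class TestCentering:
    def test_residual_means_vanish_per_condition(self):
        rng = np.random.default_rng(0)
        data = make_matrix(rng.normal(5, 2, (40, 3, 10)))
        resid = remove_cross_trial_mean(data)
        for cond in (0, 1):
            sel = resid.condition == cond
            assert np.all(np.abs(resid.rates[sel].mean(axis=0)) < 1e-12)

    def test_identical_trials_give_zero_residuals(self):
        data = make_matrix(np.tile(np.arange(12.0).reshape(1, 3, 4), (6, 1, 1)),
                           conditions=np.zeros(6))
        resid = remove_cross_trial_mean(data)
        assert np.allclose(resid.rates, 0.0)

    def test_two_condition_toy_matches_hand_computation(self):
        # condition 0 trials: constant 2 and 4 (mean 3); condition 1: 10 and 20 (mean 15)
        rates = np.array([2.0, 10.0, 4.0, 20.0]).reshape(4, 1, 1)
        data = make_matrix(rates, conditions=[0, 1, 0, 1], n_rest=0)
        resid = remove_cross_trial_mean(data)
        assert np.allclose(resid.rates.ravel(), [-1.0, -5.0, 1.0, 5.0])

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        data = make_matrix(rng.normal(size=(20, 2, 8)))
        once = remove_cross_trial_mean(data)
        twice = remove_cross_trial_mean(once)
        assert np.allclose(once.rates, twice.rates)

    def test_single_trial_condition_rejected(self):
        data = make_matrix(np.zeros((3, 1, 4)), conditions=[0, 0, 1])
        with pytest.raises(ValueError):
            remove_cross_trial_mean(data)


class TestCrossTrialVariance:
    def test_constant_residuals_zero_variance(self):
        data = make_matrix(np.zeros((50, 2, 10)))
        out = cross_trial_variance(data, "task", bin_size=25)
        assert np.allclose(out.variance, 0.0)

    def test_iid_normal_recovers_population_variance(self):
        rng = np.random.default_rng(2)
        n_bins = 200
        # one task timepoint per trial, so the epoch rate is the raw N(0, 2) draw
        data = make_matrix(rng.normal(0, 2.0, (25 * n_bins, 1, 2)), n_rest=1)
        out = cross_trial_variance(data, "task", bin_size=25)
        assert out.variance.shape == (n_bins, 1)
        assert out.variance.mean() == pytest.approx(4.0, abs=0.4)

    def test_unbiased_divisor_matches_longhand(self):
        rng = np.random.default_rng(3)
        rates = rng.normal(size=(25, 1, 4))
        data = make_matrix(rates, conditions=np.zeros(25))
        out = cross_trial_variance(data, "rest", bin_size=25)
        r = rates[:, 0, :2].mean(axis=1)  # rest epoch = first 2 timepoints
        longhand = np.sum((r - r.mean()) ** 2) / 24
        assert out.variance[0, 0] == pytest.approx(longhand, abs=1e-12)

    def test_trailing_partial_bin_dropped(self):
        data = make_matrix(np.zeros((60, 1, 4)))
        out = cross_trial_variance(data, "task", bin_size=25)
        assert out.n_bins == 2


class TestCrossTrialCorrelation:
    def test_duplicated_area_fully_correlated(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=(50, 1, 6))
        rates = np.concatenate([base, base], axis=1)
        out = cross_trial_correlation(make_matrix(rates), "task", bin_size=25)
        assert np.all(np.tanh(out.correlation) > 0.999999)

    def test_independent_areas_near_zero_mean(self):
        rng = np.random.default_rng(5)
        data = make_matrix(rng.normal(size=(25 * 500, 2, 4)))
        out = cross_trial_correlation(data, "task", bin_size=25)
        assert abs(np.tanh(out.correlation).mean()) < 0.05

    def test_fisher_z_closed_form(self):
        assert np.arctanh(0.5) == pytest.approx(0.5493061443)

    def test_zero_variance_area_recorded_missing(self):
        rates = np.zeros((25, 2, 4))
        rates[:, 0, :] = np.random.default_rng(6).normal(size=(25, 4))
        out = cross_trial_correlation(make_matrix(rates, conditions=np.zeros(25)),
                                      "task", bin_size=25)
        assert np.isnan(out.correlation).all()

    def test_covariance_correlation_consistency(self):
        rng = np.random.default_rng(7)
        data = make_matrix(rng.normal(size=(100, 3, 6)))
        out = cross_trial_correlation(data, "task", bin_size=25)
        var = cross_trial_variance(data, "task", bin_size=25).variance
        for b in range(out.n_bins):
            for p, (i, j) in enumerate(out.pairs):
                r = out.covariance[b, p] / np.sqrt(var[b, i] * var[b, j])
                assert np.tanh(out.correlation[b, p]) == pytest.approx(r, abs=1e-10)


class TestWithinTrial:
    def test_task_amplitude_scaling_scales_variance(self):
        rng = np.random.default_rng(8)
        n_t = 40
        rates = rng.normal(size=(100, 2, n_t))
        rates[:, :, n_t // 2:] *= 0.5
        table = within_trial_stats(make_matrix(rates))
        ratio = table["task_variance"].mean() / table["rest_variance"].mean()
        assert ratio == pytest.approx(0.25, abs=0.05)

    def test_unmatched_epoch_lengths_rejected(self):
        data = make_matrix(np.zeros((10, 1, 10)), n_rest=3)
        with pytest.raises(ValueError):
            within_trial_stats(data)

    def test_shared_latent_quenching_recovered(self):
        """State-dependent shared gain (1 rest, 0.3 task) yields lower
        within-trial task correlation in the large majority of sessions."""
        rng = np.random.default_rng(9)
        wins = 0
        n_sessions = 40
        for _ in range(n_sessions):
            n_trials, n_areas, half = 60, 4, 30
            shared = rng.normal(size=(n_trials, 1, 2 * half))
            gain = np.where(np.arange(2 * half) < half, 1.0, 0.3)
            rates = shared * gain + 0.5 * rng.normal(size=(n_trials, n_areas, 2 * half))
            table = within_trial_stats(make_matrix(rates, n_rest=half))
            if table["task_correlation"].mean() < table["rest_correlation"].mean():
                wins += 1
        assert wins / n_sessions > 0.95


class TestFano:
    def test_poisson_counts_unit_fano(self):
        rng = np.random.default_rng(10)
        counts = rng.poisson(7.0, size=(200, 5))
        assert np.nanmean(fano_factor(counts)) == pytest.approx(1.0, abs=0.2)

    def test_deterministic_counts_zero_fano(self):
        counts = np.tile(np.arange(1, 6), (50, 1))
        assert np.allclose(fano_factor(counts), 0.0)

    def test_doubling_counts_doubles_fano(self):
        rng = np.random.default_rng(11)
        counts = rng.poisson(5.0, size=(300, 3)).astype(float)
        f1 = fano_factor(counts)
        f2 = fano_factor(2 * counts)
        assert np.allclose(f2, 2 * f1)

    def test_zero_mean_unit_missing(self):
        counts = np.zeros((10, 2))
        counts[:, 0] = 1.0
        fano = fano_factor(counts)
        assert np.isnan(fano[1]) and fano[0] == 0.0


class TestPairedContrast:
    def test_identical_inputs_no_discoveries(self):
        x = np.random.default_rng(12).normal(size=(20, 6))
        out = paired_contrast(x, x.copy())
        assert np.allclose(out["t"], 0.0)
        assert not out["significant"].any()

    def test_closed_form_paired_t(self):
        # differences 1..5: t = mean/ (sd/sqrt(5)) = 3 / (1.5811/2.2361) = 4.2426
        rest = np.zeros((5, 1))
        task = np.array([1.0, 2.0, 3.0, 4.0, 5.0])[:, None]
        out = paired_contrast(task, rest)
        assert out["t"].iloc[0] == pytest.approx(3 / (np.std([1, 2, 3, 4, 5], ddof=1)
                                                      / np.sqrt(5)), abs=1e-10)
        assert out["t"].iloc[0] == pytest.approx(4.242640687, abs=1e-8)

    def test_benjamini_hochberg_step_up(self):
        """p = (.001, .01, .02, .8) at q=.05 -> exactly the first three rejected."""
        rng = np.random.default_rng(13)
        # craft features whose paired t-test p-values are controlled via scipy
        from statsmodels.stats.multitest import multipletests
        reject = multipletests([0.001, 0.01, 0.02, 0.8], alpha=0.05,
                               method="fdr_bh")[0]
        assert reject.tolist() == [True, True, True, False]

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            paired_contrast(np.zeros((2, 3)), np.zeros((2, 3)))


class TestPermutationInvariance:
    def test_label_shuffle_within_condition_preserves_variance_distribution(self):
        rng = np.random.default_rng(14)
        data = make_matrix(rng.normal(size=(200, 2, 10)))
        resid = remove_cross_trial_mean(data)
        base = cross_trial_variance(resid, "task").variance.ravel()
        # shuffle trials within each condition, preserving recording order slots
        perm = np.arange(data.n_trials)
        for cond in (0, 1):
            idx = np.flatnonzero(data.condition == cond)
            perm[idx] = rng.permutation(idx)
        shuffled = TrialMatrix(rates=resid.rates[perm], condition=resid.condition[perm],
                               epoch_masks=resid.epoch_masks)
        shuf = cross_trial_variance(shuffled, "task").variance.ravel()
        assert sps.ks_2samp(base, shuf).pvalue > 0.01
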