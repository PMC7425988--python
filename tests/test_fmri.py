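"""FIR/canonical GLMs, block statistics, dimensionality, and associations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from neuroquench.fmri import (
    DimensionalityInput,
    RegionTimeSeries,
    TaskDesign,
    activation_quenching_association,
    block_fc,
    block_sample_mask,
    block_variance,
    build_canonical_design,
    build_fir_design,
    cross_block_stats,
    mean_offdiagonal,
    participation_ratio,
    regress_out,
    state_dimensionality_contrast,
    znormalize_runs,
)

TR = 0.72


def simple_design(n_blocks=2, block_len=10, gap=20, lag=25, cond="A"):
    blocks = [(cond, (gap + i * (block_len + gap)) * TR, block_len * TR)
              for i in range(n_blocks)]
    return TaskDesign.from_blocks(blocks, fir_lag=lag)


class TestFIRDesign:
    def test_single_block_column_structure(self):
        design = simple_design(n_blocks=1)
        X, names = build_fir_design(design, 200, TR)
        assert X.shape[1] == 10 + 25
        assert np.allclose(X.sum(axis=0), 1.0)

    def test_two_blocks_share_columns(self):
        design = simple_design(n_blocks=2)
        X, _ = build_fir_design(design, 200, TR)
        assert X.shape[1] == 35
        assert np.allclose(X.sum(axis=0), 2.0)

    def test_fir_removes_block_locked_response(self):
        """Fitting the FIR design removes an arbitrary evoked waveform."""
        rng = np.random.default_rng(0)
        n_t, n_blocks = 640, 8
        design = simple_design(n_blocks=n_blocks, block_len=10, gap=20, lag=25)
        evoked = np.zeros(n_t)
        shape = np.sin(np.linspace(0, np.pi, 35)) * 3.0
        for _, ev in design.events.iterrows():
            onset = int(round(ev["onset"] / TR))
            evoked[onset: onset + 35] += shape[: max(0, min(35, n_t - onset))]
        noise_sd = 0.5
        values = evoked[None, :] + noise_sd * rng.standard_normal((2, n_t))
        series = RegionTimeSeries(values=values, sampling_interval=TR)
        X, _ = build_fir_design(design, n_t, TR)
        result = regress_out(series, X)
        resid = result.residuals.values
        for _, ev in design.events.iterrows():
            onset = int(round(ev["onset"] / TR))
            stack = []
        stacks = np.stack([
            resid[:, int(round(ev["onset"] / TR)): int(round(ev["onset"] / TR)) + 35]
            for _, ev in design.events.iterrows()
        ])
        cross_block_mean = stacks.mean(axis=0)
        assert np.abs(cross_block_mean).max() < 2 * noise_sd / np.sqrt(n_blocks) * 3

    def test_truncated_block_warns(self):
        design = simple_design(n_blocks=1, gap=5, block_len=10, lag=25)
        with pytest.warns(UserWarning, match="truncated"):
            build_fir_design(design, 20, TR)


class TestRegressOut:
    def test_self_regression_annihilates(self):
        rng = np.random.default_rng(1)
        y = rng.standard_normal((3, 100))
        series = RegionTimeSeries(values=y, sampling_interval=TR)
        result = regress_out(series, y.T, add_trend=False)
        assert np.abs(result.residuals.values).max() < 1e-8

    def test_residuals_orthogonal_to_design(self):
        rng = np.random.default_rng(2)
        series = RegionTimeSeries(values=rng.standard_normal((4, 200)),
                                  sampling_interval=TR)
        X = rng.standard_normal((200, 5))
        result = regress_out(series, X)
        D = result.design_matrix
        dots = D.T @ result.residuals.values.T
        norms = np.linalg.norm(D, axis=0)[:, None]
        assert np.abs(dots / norms).max() < 1e-8

    def test_known_coefficients_recovered(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((120, 3))
        beta = np.array([[1.5, -2.0, 0.25]])
        y = beta @ X.T  # noiseless
        series = RegionTimeSeries(values=y, sampling_interval=TR)
        result = regress_out(series, X, add_trend=False)
        assert np.allclose(result.coefficients, beta, atol=1e-10)

    def test_collinear_columns_dropped_with_warning(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(100)
        X = np.column_stack([x, 2 * x, rng.standard_normal(100)])
        series = RegionTimeSeries(values=rng.standard_normal((2, 100)),
                                  sampling_interval=TR)
        with pytest.warns(UserWarning, match="rank deficient"):
            result = regress_out(series, X, add_trend=False)
        assert result.design_matrix.shape[1] == 2


class TestCanonicalDesign:
    def test_hrf_delay_and_sign(self):
        design = simple_design(n_blocks=1, lag=0)
        X, _ = build_canonical_design(design, 300, TR)
        assert X.sum() > 0
        onset = int(round(design.events["onset"].iloc[0] / TR))
        peak = np.argmax(X[:, 0])
        assert (peak - onset) * TR >= 4.0

    def test_beta_recovery_with_noise(self):
        rng = np.random.default_rng(5)
        design = simple_design(n_blocks=100, block_len=10, gap=10, lag=0)
        n_t = 30 + 100 * 20 + 30
        X, _ = build_canonical_design(design, n_t, TR)
        y = 0.8 * X[:, 0] + rng.standard_normal(n_t)
        series = RegionTimeSeries(values=y[None, :], sampling_interval=TR)
        result = regress_out(series, X)
        assert result.coefficients[0, 0] == pytest.approx(0.8, abs=0.05)

    def test_zero_duration_event_flagged(self):
        design = TaskDesign.from_blocks([("A", 10 * TR, 0.0)], fir_lag=0)
        with pytest.warns(UserWarning):
            build_canonical_design(design, 100, TR)


class TestZNormalize:
    def test_unit_variance_zero_mean_per_run(self):
        rng = np.random.default_rng(6)
        series = RegionTimeSeries(values=5 + 2 * rng.standard_normal((3, 200)),
                                  sampling_interval=TR, run_boundaries=[0, 100])
        z = znormalize_runs(series)
        for sl in z.run_slices():
            seg = z.values[:, sl]
            assert np.allclose(seg.mean(axis=1), 0.0, atol=1e-12)
            assert np.allclose(seg.var(axis=1, ddof=1), 1.0, atol=1e-12)

    def test_idempotent(self):
        rng = np.random.default_rng(7)
        series = RegionTimeSeries(values=rng.standard_normal((2, 50)),
                                  sampling_interval=TR)
        once = znormalize_runs(series)
        twice = znormalize_runs(once)
        assert np.allclose(once.values, twice.values, atol=1e-12)

    def test_rank_order_of_block_variances_preserved(self):
        rng = np.random.default_rng(8)
        design = simple_design(n_blocks=4, block_len=10, gap=10, lag=0)
        n_t = 200
        values = rng.standard_normal((1, n_t))
        mask_fn = lambda s: [
            s.values[0, int(round(ev["onset"] / TR)): int(round(ev["onset"] / TR)) + 10].var(ddof=1)
            for _, ev in design.events.iterrows()]
        series = RegionTimeSeries(values=values, sampling_interval=TR)
        before = mask_fn(series)
        after = mask_fn(znormalize_runs(series))
        assert (np.argsort(before) == np.argsort(after)).all()

    def test_zero_variance_rejected(self):
        series = RegionTimeSeries(values=np.ones((1, 30)), sampling_interval=TR)
        with pytest.raises(ValueError):
            znormalize_runs(series)


class TestBlockStats:
    def test_unit_variance_construction_gives_unit_rest_variance(self):
        rng = np.random.default_rng(9)
        design = simple_design(n_blocks=20, block_len=10, gap=10, lag=5)
        n_t = 20 + 20 * 20 + 30
        series = RegionTimeSeries(values=rng.standard_normal((3, n_t)),
                                  sampling_interval=TR)
        z = znormalize_runs(series)
        v = block_variance(z, design)
        assert np.allclose(v, 1.0, atol=0.3)

    def test_within_block_gain_recovered(self):
        rng = np.random.default_rng(10)
        design = simple_design(n_blocks=40, block_len=10, gap=10, lag=0)
        n_t = 20 + 40 * 20 + 20
        mask = block_sample_mask(design, n_t, TR)
        values = rng.standard_normal((2, n_t))
        values[:, mask] *= 0.8
        series = RegionTimeSeries(values=values, sampling_interval=TR)
        v = block_variance(series, design)
        assert v.mean() == pytest.approx(0.64, abs=0.06)

    def test_duplicated_region_full_correlation(self):
        rng = np.random.default_rng(11)
        design = simple_design(n_blocks=4, block_len=10, gap=10, lag=0)
        base = rng.standard_normal((1, 200))
        series = RegionTimeSeries(values=np.vstack([base, base]),
                                  sampling_interval=TR)
        Z = block_fc(series, design)
        assert np.tanh(Z[0, 1]) > 0.999999
        assert np.allclose(Z, Z.T)

    def test_shared_latent_quench_lowers_task_fc(self):
        rng = np.random.default_rng(12)
        design = simple_design(n_blocks=10, block_len=10, gap=10, lag=0)
        n_t = 20 + 10 * 20 + 20
        mask = block_sample_mask(design, n_t, TR)
        shared = rng.standard_normal(n_t)
        gain = np.where(mask, 0.4, 1.0)
        task = shared * gain + 0.7 * rng.standard_normal((5, n_t))
        rest = shared + 0.7 * rng.standard_normal((5, n_t))
        fc_task = mean_offdiagonal(block_fc(
            RegionTimeSeries(values=task, sampling_interval=TR), design))
        fc_rest = mean_offdiagonal(block_fc(
            RegionTimeSeries(values=rest, sampling_interval=TR), design))
        assert fc_task < fc_rest

    def test_covariance_variant_same_sign(self):
        rng = np.random.default_rng(13)
        design = simple_design(n_blocks=10, block_len=10, gap=10, lag=0)
        n_t = 20 + 10 * 20 + 20
        mask = block_sample_mask(design, n_t, TR)
        shared = rng.standard_normal(n_t)
        gain = np.where(mask, 0.4, 1.0)
        task = shared * gain + 0.7 * rng.standard_normal((4, n_t))
        rest = shared + 0.7 * rng.standard_normal((4, n_t))
        t_series = RegionTimeSeries(values=task, sampling_interval=TR)
        r_series = RegionTimeSeries(values=rest, sampling_interval=TR)
        dc = (mean_offdiagonal(block_fc(t_series, design, "covariance"))
              - mean_offdiagonal(block_fc(r_series, design, "covariance")))
        dr = (mean_offdiagonal(block_fc(t_series, design))
              - mean_offdiagonal(block_fc(r_series, design)))
        assert np.sign(dc) == np.sign(dr) == -1


class TestCrossBlockStats:
    def _design_and_series(self, noise_gain=1.0, seed=0, n_blocks=12):
        rng = np.random.default_rng(seed)
        design = simple_design(n_blocks=n_blocks, block_len=15, gap=10, lag=0)
        n_t = 20 + n_blocks * 25 + 20
        evoked = np.zeros(n_t)
        for _, ev in design.events.iterrows():
            onset = int(round(ev["onset"] / TR))
            evoked[onset: onset + 15] += np.linspace(0, 2, 15)
        values = evoked[None, :] + noise_gain * rng.standard_normal((4, n_t))
        return design, RegionTimeSeries(values=values, sampling_interval=TR)

    def test_invariant_to_block_locked_waveform(self):
        design, series = self._design_and_series(seed=1)
        out1 = cross_block_stats(series, design)
        # add a fixed waveform to every block
        shifted = series.values.copy()
        for _, ev in design.events.iterrows():
            onset = int(round(ev["onset"] / TR))
            shifted[:, onset: onset + 15] += 17.5
        out2 = cross_block_stats(
            RegionTimeSeries(values=shifted, sampling_interval=TR), design)
        assert np.allclose(out1["variance"], out2["variance"], atol=1e-10)
        assert np.allclose(out1["correlation_z"], out2["correlation_z"], atol=1e-10)

    def test_task_noise_quench_detected_at_every_timepoint(self):
        design, task = self._design_and_series(noise_gain=0.5, seed=2)
        _, rest = self._design_and_series(noise_gain=1.0, seed=3)
        out_task = cross_block_stats(task, design)
        out_rest = cross_block_stats(rest, design)
        assert (out_task["variance"] < out_rest["variance"]).all()

    def test_sham_rest_calibrated(self):
        """Sham-rest cross-block variance matches the generator's nominal unit
        variance within sampling error."""
        design, rest = self._design_and_series(noise_gain=1.0, seed=4, n_blocks=20)
        out = cross_block_stats(rest, design)
        n_blocks = 20
        se = np.sqrt(2.0 / (n_blocks - 1))
        assert np.abs(out["variance"] - 1.0).max() < 2 * se + 0.2

    def test_too_few_blocks_rejected(self):
        design, series = self._design_and_series(n_blocks=2)
        with pytest.raises(ValueError):
            cross_block_stats(series, design)


class TestParticipationRatio:
    def test_identity_covariance(self):
        assert participation_ratio(np.eye(7)) == pytest.approx(7.0)

    def test_rank_one(self):
        v = np.arange(1.0, 5.0)
        assert participation_ratio(np.outer(v, v)) == pytest.approx(1.0)

    def test_two_by_two_closed_form(self):
        rho = 0.6
        C = np.array([[1.0, rho], [rho, 1.0]])
        assert participation_ratio(C) == pytest.approx(2 / (1 + rho**2), abs=1e-10)
        assert participation_ratio(C) == pytest.approx(1.4706, abs=1e-4)

    def test_scale_invariance(self):
        rng = np.random.default_rng(14)
        A = rng.standard_normal((6, 6))
        C = A @ A.T
        assert participation_ratio(3.7 * C) == pytest.approx(
            participation_ratio(C), abs=1e-10)

    def test_bounds(self):
        rng = np.random.default_rng(15)
        for _ in range(5):
            A = rng.standard_normal((8, 20))
            pr = participation_ratio(np.cov(A))
            assert 1.0 <= pr <= 8.0 + 1e-9

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            participation_ratio(np.zeros((3, 3)))
        with pytest.raises(ValueError):
            DimensionalityInput(covariance=np.array([[1.0, 2.0], [0.0, 1.0]]))


class TestDimensionalityContrast:
    def test_identical_inputs_zero_contrast(self):
        rng = np.random.default_rng(16)
        design = simple_design(n_blocks=5, block_len=10, gap=10, lag=0)
        series = [RegionTimeSeries(values=rng.standard_normal((6, 200)),
                                   sampling_interval=TR) for _ in range(4)]
        table, contrast = state_dimensionality_contrast(series, series, design)
        assert np.allclose(table["task_dimensionality"],
                           table["rest_dimensionality"])
        assert contrast["t"].iloc[0] == 0.0

    def test_offdiagonal_quench_raises_dimensionality(self):
        """Shared (off-diagonal) variance reduced more than private variance
        in task blocks -> higher task-state participation ratio."""
        rng = np.random.default_rng(17)
        design = simple_design(n_blocks=8, block_len=10, gap=10, lag=0)
        n_t = 20 + 8 * 20 + 20
        mask = block_sample_mask(design, n_t, TR)
        wins = 0
        n_subj = 30
        task_list, rest_list = [], []
        for _ in range(n_subj):
            shared = rng.standard_normal(n_t)
            shared_gain = np.where(mask, 0.3, 1.0)   # strong shared quench
            private_gain = np.where(mask, 0.9, 1.0)  # mild private quench
            task = shared * shared_gain + private_gain * rng.standard_normal((8, n_t))
            rest = shared + rng.standard_normal((8, n_t))
            task_list.append(RegionTimeSeries(values=task, sampling_interval=TR))
            rest_list.append(RegionTimeSeries(values=rest, sampling_interval=TR))
        table, contrast = state_dimensionality_contrast(task_list, rest_list, design)
        frac = (table["task_dimensionality"] > table["rest_dimensionality"]).mean()
        assert frac > 0.95
        assert contrast["t"].iloc[0] > 0


class TestActivationAssociation:
    def test_perfect_anticorrelation(self):
        rng = np.random.default_rng(18)
        betas = np.tile(np.linspace(0.1, 2.0, 20)[None, :, None], (12, 1, 2))
        betas = betas + 0.01 * rng.standard_normal(betas.shape)
        tstats = sps.ttest_1samp(betas, 0.0, axis=0).statistic
        activation = np.abs(tstats).mean(axis=1)
        out = activation_quenching_association(betas, -activation, None)
        assert out.loc[out["measure"] == "variance", "rho"].iloc[0] == pytest.approx(-1.0)

    def test_shuffled_labels_near_zero(self):
        rng = np.random.default_rng(19)
        betas = rng.standard_normal((15, 40, 3))
        change = rng.standard_normal(40)
        out = activation_quenching_association(betas, change, change[::-1])
        assert np.abs(out["rho"]).max() < 0.45

    def test_too_few_regions_rejected(self):
        with pytest.raises(ValueError):
            activation_quenching_association(np.zeros((5, 4, 2)), np.zeros(4))
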