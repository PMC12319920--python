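"""ROI aggregation, percent change, mixed test, FDR, BOLD arm."""

import numpy as np
import pandas as pd
import pytest

from dfmri.acquisition import REST, STIMULUS, BlockDesign
from dfmri.funcstats import (
    bold_condition_average,
    bold_epoch_normalize,
    bold_glm,
    condition_mixed_test,
    fdr_adjust,
    max_abs_change,
    percent_change,
    roi_aggregate,
    significance_stars,
)
from dfmri.synth import BOLDSeriesSpec, synthesize_bold


def make_mixed_rows(
    rng,
    n_subjects=4,
    n_runs=3,
    n_deltas=5,
    effect=0.0,
    subject_sd=0.5,
    run_sd=0.5,
    noise_sd=1.0,
):
    rows = []
    for s in range(n_subjects):
        bs = rng.normal(scale=subject_sd)
        for r in range(n_runs):
            br = rng.normal(scale=run_sd)
            for d in range(n_deltas):
                for cond in (REST, STIMULUS):
                    val = (
                        10.0
                        + bs
                        + br
                        + 0.1 * d
                        + (effect if cond == STIMULUS else 0.0)
                        + rng.normal(scale=noise_sd)
                    )
                    rows.append(
                        dict(value=val, condition=cond, delta=d, run=r, subject=s)
                    )
    return pd.DataFrame(rows)


class TestRoiAggregate:
    def test_uniform_roi(self):
        labels = np.zeros((4, 4), dtype=int)
        labels[:2] = 1
        vol = np.where(labels == 1, 3.5, 0.0)
        df = roi_aggregate(vol, labels)
        assert len(df) == 1
        assert df.iloc[0]["mean"] == 3.5
        assert df.iloc[0]["sd"] == 0.0
        assert df.iloc[0]["n_voxels"] == 8

    def test_half_masked_roi_counts_valid_voxels_only(self):
        labels = np.ones((4, 4), dtype=int)
        valid = np.zeros((4, 4), dtype=bool)
        valid[:2] = True
        df = roi_aggregate(np.arange(16.0).reshape(4, 4), labels, valid)
        assert df.iloc[0]["n_voxels"] == 8
        assert df.iloc[0]["mean"] == np.arange(8.0).mean()

    def test_empty_roi_dropped_with_warning(self):
        labels = np.ones((2, 2), dtype=int)
        with pytest.warns(UserWarning, match="empty"):
            df = roi_aggregate(np.ones((2, 2)), labels, np.zeros((2, 2), bool))
        assert df.empty

    def test_misaligned_labels_rejected(self):
        with pytest.raises(ValueError, match="align"):
            roi_aggregate(np.ones((2, 2)), np.ones((3, 3), dtype=int))


class TestPercentChange:
    def test_no_change_is_zero(self):
        assert percent_change(1.0, 1.0) == 0.0

    def test_hand_computed_decrease(self):
        assert percent_change(1.000, 0.989) == pytest.approx(-1.1, abs=1e-12)

    def test_zero_rest_flagged(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(percent_change(0.0, 1.0))

    def test_max_abs_keeps_sign(self):
        changes = [0.2, -1.1, 0.9, -0.3, 0.5]
        deltas = [9.5, 15, 20, 25, 30]
        chg, delta = max_abs_change(changes, deltas)
        assert chg == -1.1
        assert delta == 15


class TestConditionMixedTest:
    def test_single_subject_rejected(self):
        rng = np.random.default_rng(0)
        df = make_mixed_rows(rng, n_subjects=1)
        with pytest.raises(ValueError, match="subjects"):
            condition_mixed_test(df)

    def test_single_run_rejected(self):
        rng = np.random.default_rng(0)
        df = make_mixed_rows(rng, n_runs=1)
        with pytest.raises(ValueError, match="runs"):
            condition_mixed_test(df)

    def test_detects_injected_effect(self):
        rng = np.random.default_rng(1)
        df = make_mixed_rows(rng, effect=2.0)
        res = condition_mixed_test(df)
        assert res.p_value < 0.001

    def test_null_effect_usually_not_significant(self):
        rng = np.random.default_rng(2)
        ps = [
            condition_mixed_test(make_mixed_rows(rng)).p_value for _ in range(20)
        ]
        assert np.mean(np.array(ps) < 0.05) <= 0.2


class TestFdr:
    def test_bh_hand_enumerated_example(self):
        # step-up: q3 = 0.04; q2 = min(0.02*3/2, 0.04) = 0.03; q1 = 0.03
        q = fdr_adjust([0.01, 0.02, 0.04])
        assert np.allclose(q, [0.03, 0.03, 0.04])

    def test_all_ones_stay_one_and_single_p_identity(self):
        assert np.allclose(fdr_adjust([1.0, 1.0, 1.0]), 1.0)
        assert fdr_adjust([0.03])[0] == pytest.approx(0.03)
        assert fdr_adjust([]).size == 0

    def test_q_at_least_p_and_step_up_monotone(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=40)
        q = fdr_adjust(p)
        assert np.all(q >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_stars_convention(self):
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.009) == "**"
        assert significance_stars(0.0009) == "***"
        assert significance_stars(0.06) == ""


class TestBoldEpochNormalize:
    def test_constant_series_normalizes_to_one(self, bold_design):
        series = np.full(336, 250.0)
        epochs, response = bold_epoch_normalize(series, bold_design)
        assert epochs.shape == (6, 56)
        assert np.allclose(response, 1.0)

    def test_boxcar_plateau_at_normalized_amplitude(self, bold_design):
        spec = BOLDSeriesSpec(design=bold_design, amplitude_pct=1.2, noise_pct=0.0)
        series = synthesize_bold(spec)
        _, response = bold_epoch_normalize(series, bold_design)
        assert np.allclose(response[:28], 1.0)
        assert np.allclose(response[28:], 1.012)

    def test_drift_leaves_within_epoch_slope(self, bold_design):
        # pure linear ramp: normalization removes the level per epoch, the
        # within-epoch slope survives; response is increasing and crosses 1
        # just after the baseline window
        t = np.arange(336, dtype=float)
        series = 100.0 + 0.05 * t
        _, response = bold_epoch_normalize(series, bold_design)
        assert np.all(np.diff(response) > 0)
        assert response[20] < 1.0 < response[28]

    def test_short_series_rejected(self, bold_design):
        with pytest.raises(ValueError, match="epochs"):
            bold_epoch_normalize(np.ones(100), bold_design)


class TestBoldConditionAverage:
    def test_noise_free_boxcar_gives_exact_change(self, bold_design):
        spec = BOLDSeriesSpec(design=bold_design, amplitude_pct=1.2, noise_pct=0.0)
        avg = bold_condition_average(synthesize_bold(spec), bold_design)
        assert avg.percent_change == pytest.approx(1.2, abs=1e-12)

    def test_label_swap_flips_sign(self, bold_design):
        rng = np.random.default_rng(0)
        series = rng.normal(100.0, 1.0, size=336)
        fwd = bold_condition_average(series, bold_design)
        # swapping rest and stimulus labels == reversing each epoch's halves
        swapped = series.reshape(6, 56)[:, list(range(28, 56)) + list(range(28))]
        rev = bold_condition_average(swapped.ravel(), bold_design)
        assert np.sign(rev.percent_change) == -np.sign(fwd.percent_change)
        assert rev.stim_mean == pytest.approx(fwd.rest_mean)

    def test_null_series_type_one_error_calibrated(self, bold_design):
        rng = np.random.default_rng(1)
        rejections = 0
        n = 500
        for _ in range(n):
            series = rng.normal(100.0, 1.0, size=336)
            if bold_condition_average(series, bold_design).p_value < 0.05:
                rejections += 1
        assert 0.03 <= rejections / n <= 0.07


class TestBoldGlm:
    def _series(self, design, amp_mask, amplitude, noise, rng, shape=(6, 6, 2)):
        from dfmri.acquisition import schedule_block

        boxcar = (schedule_block(design).labels == STIMULUS).astype(float)
        series = np.full(shape + (boxcar.size,), 100.0)
        series = series + amplitude * boxcar * amp_mask[..., None]
        if noise:
            series = series + rng.normal(scale=noise, size=series.shape)
        return series

    def test_strong_noise_free_activation_recovered_exactly(self, bold_design):
        rng = np.random.default_rng(0)
        amp = np.zeros((6, 6, 2))
        amp[2:4, 2:4, :] = 1.0
        series = self._series(bold_design, amp, 5.0, 0.0, rng)
        res = bold_glm(series, bold_design, np.ones((6, 6, 2), bool))
        assert np.array_equal(res.activation_mask, amp.astype(bool))
        assert res.cluster_sizes == [8]

    def test_fwe_false_positive_rate_bounded(self, bold_design):
        rng = np.random.default_rng(1)
        n_sims, families_with_fp = 200, 0
        mask = np.ones((5, 5, 2), bool)
        for _ in range(n_sims):
            series = self._series(
                bold_design, np.zeros((5, 5, 2)), 0.0, 1.0, rng, shape=(5, 5, 2)
            )
            res = bold_glm(series, bold_design, mask)
            families_with_fp += int(res.activation_mask.any())
        rate = families_with_fp / n_sims
        # one-sided binomial slack around the nominal 0.05 bound
        assert rate <= 0.05 + 2.58 * np.sqrt(0.05 * 0.95 / n_sims)

    def test_detection_increases_with_amplitude(self, bold_design):
        rng = np.random.default_rng(2)
        amp_mask = np.ones((4, 4, 1))
        detected = []
        for amplitude in (0.1, 0.5, 2.0):
            frac = []
            for _ in range(10):
                series = self._series(
                    bold_design, amp_mask, amplitude, 1.0, rng, shape=(4, 4, 1)
                )
                res = bold_glm(series, bold_design, np.ones((4, 4, 1), bool))
                frac.append(res.activation_mask.mean())
            detected.append(np.mean(frac))
        assert detected[0] <= detected[1] <= detected[2]
        assert detected[2] > 0.9

    def test_depth_mask_excludes_low_signal_voxels(self, bold_design):
        series = np.full((4, 4, 1, 336), 100.0)
        series[0, :, :, :] = 5.0  # below 10% of cortical signal
        cortex = np.zeros((4, 4, 1), bool)
        cortex[2:] = True
        res = bold_glm(series, bold_design, np.ones((4, 4, 1), bool), cortex_mask=cortex)
        assert not res.analysis_mask[0].any()
        assert res.analysis_mask[1:].all()

    def test_length_mismatch_rejected(self, bold_design):
        with pytest.raises(ValueError, match="volumes"):
            bold_glm(np.ones((2, 2, 1, 100)), bold_design, np.ones((2, 2, 1), bool))
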