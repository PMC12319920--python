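"""Ground-truth substrates, exchange-kurtosis closed form, signal synthesis."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from dfmri.acquisition import BlockDesign, schedule_block
from dfmri.synth import (
    BOLDSeriesSpec,
    KargerSubstrate,
    PhantomSpec,
    RegionSpec,
    StudyConfig,
    UndefinedKurtosisError,
    add_rician_noise,
    karger_ground_truth,
    karger_mk,
    make_study,
    substrate_from_moments,
    synthesize_bold,
    synthesize_dwi,
)


class TestKargerGroundTruth:
    def test_two_compartment_closed_form(self):
        # MD = sum f D; K0 = 3 f1 f2 (D1 - D2)^2 / MD^2 evaluated by hand
        sub = KargerSubstrate(fractions=(0.5, 0.5), diffusivities=(1.0, 0.5), t_ex=50.0)
        md, _ = karger_ground_truth(sub, 10.0)
        assert md == pytest.approx(0.75, abs=1e-15)
        assert sub.k0 == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_single_compartment_has_zero_kurtosis(self):
        sub = KargerSubstrate(fractions=(1.0,), diffusivities=(0.7,), t_ex=50.0)
        for delta in (1.0, 10.0, 100.0):
            md, mk = karger_ground_truth(sub, delta)
            assert md == pytest.approx(0.7)
            assert mk == pytest.approx(0.0, abs=1e-15)

    def test_exchange_kurtosis_at_table_parameters(self):
        # frozen from an independent high-precision evaluation (mpmath, 50 dps)
        assert karger_mk(0.86, 53.8, 9.5) == pytest.approx(
            0.8115383697711005, abs=1e-12
        )
        assert karger_mk(0.86, 53.8, 30.0) == pytest.approx(
            0.7201613625170572, abs=1e-12
        )

    def test_zero_md_with_variance_is_undefined(self):
        sub = KargerSubstrate(fractions=(0.5, 0.5), diffusivities=(0.0, 0.0), t_ex=50.0)
        assert sub.k0 == 0.0  # degenerate but defined
        bad = KargerSubstrate.__new__(KargerSubstrate)
        object.__setattr__(bad, "fractions", (0.5, 0.5))
        object.__setattr__(bad, "diffusivities", (1.0, -1.0))
        object.__setattr__(bad, "t_ex", 50.0)
        with pytest.raises(UndefinedKurtosisError):
            bad.k0

    def test_substrate_from_moments_roundtrip(self):
        sub = substrate_from_moments(0.70, 0.86, 53.8)
        assert sub.md == pytest.approx(0.70, abs=1e-15)
        assert sub.k0 == pytest.approx(0.86, rel=1e-12)
        assert sub.t_ex == 53.8

    @given(
        k0=st.floats(0.05, 2.5),
        t_ex=st.floats(5.0, 200.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_exchange_kurtosis_limits_and_monotonicity(self, k0, t_ex):
        deltas = np.geomspace(1e-4 * t_ex, 200 * t_ex, 80)
        mk = karger_mk(k0, t_ex, deltas)
        assert np.all(np.diff(mk) < 0)  # strictly decreasing in Delta
        assert np.all(mk <= k0 + 1e-12)
        assert mk[0] == pytest.approx(k0, rel=1e-3)  # MK -> K0 as Delta -> 0
        # long-time tail 2 K0 t_ex / Delta within 1% at Delta = 100 t_ex
        # (the exact relative deviation there is 1/x - tiny = 1%, a boundary)
        tail = karger_mk(k0, t_ex, 100.0 * t_ex)
        assert abs(tail / (2.0 * k0 / 100.0) - 1.0) <= 0.01 + 1e-9

    def test_md_time_independent_mk_scales_with_delta_over_tex(self):
        sub = substrate_from_moments(0.7, 0.86, 50.0)
        md1, mk1 = karger_ground_truth(sub, 10.0)
        md2, _ = karger_ground_truth(sub, 30.0)
        assert md1 == md2
        sub2 = substrate_from_moments(0.7, 0.86, 100.0)
        _, mk2 = karger_ground_truth(sub2, 20.0)  # same Delta/t_ex ratio
        assert mk1 == pytest.approx(mk2, rel=1e-12)


class TestSynthesizeDWI:
    def test_b0_volumes_equal_s0_without_noise(
        self, uniform_phantom, default_scheme, dwi_schedule
    ):
        series = synthesize_dwi(
            uniform_phantom, default_scheme, dwi_schedule, noise=False
        )
        b0_vols = np.flatnonzero(
            default_scheme.bvalues[dwi_schedule.measurement_ids] == 0
        )
        assert np.all(series[..., b0_vols] == uniform_phantom.s0)

    def test_noise_free_output_is_seed_independent(
        self, uniform_phantom, default_scheme, dwi_schedule
    ):
        a = synthesize_dwi(uniform_phantom, default_scheme, dwi_schedule, 1, noise=False)
        b = synthesize_dwi(uniform_phantom, default_scheme, dwi_schedule, 2, noise=False)
        assert np.array_equal(a, b)

    def test_noisy_output_is_reproducible_by_seed(
        self, uniform_phantom, default_scheme, dwi_schedule
    ):
        a = synthesize_dwi(uniform_phantom, default_scheme, dwi_schedule, 5)
        b = synthesize_dwi(uniform_phantom, default_scheme, dwi_schedule, 5)
        c = synthesize_dwi(uniform_phantom, default_scheme, dwi_schedule, 6)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_rician_bias_at_snr_20(self):
        # magnitude mean exceeds the noise-free signal by the Rician bias;
        # independent oracle: the analytic Rice mean from scipy.stats
        s0, snr = 100.0, 20.0
        sigma = s0 / snr
        rng = np.random.default_rng(0)
        draws = add_rician_noise(np.full(1000, s0), sigma, rng)
        exact_mean = stats.rice.mean(b=s0 / sigma, scale=sigma)
        assert draws.mean() == pytest.approx(exact_mean, rel=3e-3)
        bias = exact_mean - s0
        assert 0 < bias < 0.015 * s0

    def test_nonpositive_snr_rejected(self):
        sub = substrate_from_moments(0.7, 0.8, 50.0)
        with pytest.raises(ValueError, match="SNR"):
            PhantomSpec(
                labels=np.ones((1, 1, 1), dtype=int),
                regions={1: RegionSpec("r", sub, sub, snr=0.0)},
            )


class TestSynthesizeBOLD:
    def test_constant_series_without_response_drift_noise(self, bold_design):
        spec = BOLDSeriesSpec(
            design=bold_design, amplitude_pct=0.0, noise_pct=0.0,
            drift_pct_per_min=0.0,
        )
        series = synthesize_bold(spec)
        assert series.shape == (336,)
        assert np.all(series == spec.baseline)

    def test_boxcar_amplitude_exact(self, bold_design):
        spec = BOLDSeriesSpec(design=bold_design, amplitude_pct=1.2, noise_pct=0.0)
        series = synthesize_bold(spec)
        labels = schedule_block(bold_design).labels
        assert np.all(series[labels == "stimulus"] == pytest.approx(101.2))
        assert np.all(series[labels == "rest"] == pytest.approx(100.0))

    def test_fixed_seed_is_deterministic(self, bold_design):
        spec = BOLDSeriesSpec(design=bold_design, noise_pct=1.0, seed=3)
        assert np.array_equal(synthesize_bold(spec), synthesize_bold(spec))


class TestMakeStudy:
    def test_run_count_arithmetic_full_protocol(self, tmp_path):
        # 10 subjects x 5 runs with two subjects at 4 runs -> 48
        cfg = StudyConfig(grid=(4, 4, 2), include_bold=False, noise=False, seed=0)
        manifest = make_study(cfg, tmp_path / "study")
        assert manifest["n_runs"] == 48
        paws = [r["forepaw"] for r in manifest["runs"]]
        assert set(paws) == {"left", "right"}

    def test_smallest_study_contents(self, tmp_path):
        cfg = StudyConfig(
            n_rats=1, runs_per_rat=1, rats_with_fewer=0, grid=(4, 4, 2), seed=1
        )
        manifest = make_study(cfg, tmp_path / "study")
        assert manifest["n_runs"] == 1
        run = manifest["runs"][0]
        assert len(run["dwi"]) == 5  # one series per diffusion time
        assert "bold" in run
        for rel in run["dwi"].values():
            assert (tmp_path / "study" / rel).exists()

    def test_same_seed_gives_byte_identical_manifests(self, tmp_path):
        cfg = StudyConfig(
            n_rats=1, runs_per_rat=2, rats_with_fewer=0, grid=(4, 4, 2),
            include_bold=False, seed=9,
        )
        make_study(cfg, tmp_path / "a")
        make_study(cfg, tmp_path / "b")
        ma = (tmp_path / "a" / "manifest.json").read_bytes()
        mb = (tmp_path / "b" / "manifest.json").read_bytes()
        assert ma == mb
        # and the volumes themselves agree
        import nibabel as nib

        rel = json.loads(ma)["runs"][0]["dwi"]["9.5"]
        va = np.asarray(nib.load(tmp_path / "a" / rel).dataobj)
        vb = np.asarray(nib.load(tmp_path / "b" / rel).dataobj)
        assert np.array_equal(va, vb)

    def test_effect_signs_in_region_table(self, tmp_path):
        cfg = StudyConfig(
            n_rats=1, runs_per_rat=1, rats_with_fewer=0, grid=(8, 8, 4),
            include_bold=False, seed=2,
        )
        manifest = make_study(cfg, tmp_path / "study")
        effects = {r["name"]: (r["md_pct"], r["mk_pct"]) for r in manifest["regions"]}
        assert effects["S1FL"][0] < 0 and effects["S1FL"][1] < 0
        for name in ("S2", "Tha", "CPu", "Hip"):
            assert effects[name][0] > 0
        for name in ("M2", "RSC"):
            assert effects[name] == (0.0, 0.0)
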