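import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from perturbstance.errors import InvalidParameterError, UnreachableTargetError
from perturbstance.hreflex import (
    RecruitmentCurve,
    calibrate_intensity,
    extract_hm,
    hm_table,
    peak_to_peak,
)
from perturbstance.synth import HMCurveParams, generate_hm_curve_samples
from perturbstance.synth.hmcurve import h_response


@pytest.fixture(scope="module")
def curve():
    return generate_hm_curve_samples(HMCurveParams(), np.linspace(0, 60, 50))


class TestCalibrate:
    def test_default_target_hits_25_pct_of_m_max(self, curve):
        i = calibrate_intensity(curve)
        h_at_i = h_response(HMCurveParams(), [i])[0]
        assert h_at_i / curve.m_max_mv == pytest.approx(0.25, abs=0.01)

    def test_brute_force_oracle_agrees_within_one_grid_step(self, curve):
        i = calibrate_intensity(curve, 0.25)
        dense = np.linspace(0, HMCurveParams().h_peak_intensity, 200001)
        h = h_response(HMCurveParams(), dense)
        target = 0.25 * curve.m_max_mv
        oracle = dense[np.argmax(h >= target)]
        step = curve.intensity[1] - curve.intensity[0]
        assert abs(i - oracle) < step

    def test_zero_target_returns_curve_origin(self, curve):
        i = calibrate_intensity(curve, 0.0)
        assert i <= HMCurveParams().h_threshold_intensity

    def test_unreachable_target_reports_max_fraction(self, curve):
        with pytest.raises(UnreachableTargetError) as exc:
            calibrate_intensity(curve, 0.99)
        assert 0 < exc.value.max_fraction < 0.99

    def test_monotone_in_target_fraction(self, curve):
        i1 = calibrate_intensity(curve, 0.10)
        i2 = calibrate_intensity(curve, 0.25)
        i3 = calibrate_intensity(curve, 0.40)
        assert i1 < i2 < i3

    def test_too_few_points_rejected(self):
        c = RecruitmentCurve([1, 2, 3], [0, 1, 2], [0, 0, 1])
        with pytest.raises(InvalidParameterError):
            calibrate_intensity(c)


class TestPeakToPeak:
    def test_sine_gives_twice_amplitude(self):
        t = np.arange(600) / 1000.0
        x = 1.3 * np.sin(2 * np.pi * 50 * t)
        assert peak_to_peak(x, (0, 100)) == pytest.approx(2.6, rel=1e-3)

    def test_constant_gives_zero(self):
        assert peak_to_peak(np.full(600, 3.0), (0, 100)) == 0.0

    def test_empty_window_rejected(self):
        with pytest.raises(Exception):
            peak_to_peak(np.zeros(600), (100, 100))

    @given(offset=st.floats(min_value=-50, max_value=50))
    @settings(max_examples=25, deadline=None)
    def test_offset_invariance(self, offset):
        rng = np.random.default_rng(1)
        x = rng.normal(size=600)
        a = peak_to_peak(x, (0, 100))
        b = peak_to_peak(x + offset, (0, 100))
        assert a == pytest.approx(b, rel=1e-9)

    def test_inserted_wavelet_recovered_within_2_pct(self):
        from perturbstance.synth import generate_emg_trial

        ch, _ = generate_emg_trial("predicted", "posterior", "LLR", None,
                                   {"SOL": 0.0}, seed=1, pre_ms=100.0,
                                   post_ms=500.0, stim_time_ms=100.0,
                                   h_p2p_mv=1.6, m_p2p_mv=6.0)
        h = peak_to_peak(ch["SOL"], (125, 155))
        assert h == pytest.approx(1.6, rel=0.02)


class TestExtractHm:
    def test_unstimulated_trial_rejected(self, segmented_trials):
        t = next(t for t in segmented_trials if t.stim_phase == "none")
        with pytest.raises(InvalidParameterError):
            extract_hm(t, 45.0)

    def test_each_stimulated_trial_yields_one_result(self, segmented_trials):
        stim = [t for t in segmented_trials if t.stim_phase != "none"]
        table = hm_table(stim)
        assert len(table) == len(stim)
        assert set(table.phase) <= {"SLR", "MLR", "LLR"}

    def test_llr_modulation_ratio_recovered(self):
        # cohort seed 5: mean H in LLR-cheated / LLR-predicted reproduces the
        # configured modulation factor within 5 %
        from perturbstance.constants import PLATFORM_CHANNEL
        from perturbstance.segmentation import detect_onsets, segment
        from perturbstance.synth import CohortConfig, generate_cohort

        cfg = CohortConfig(n_subjects=4, trials_per_phase=3, n_anterior=0,
                           h_factor_sd_frac=0.02, seed=5)
        coh = generate_cohort(cfg)
        trials = []
        for rec in coh.iter_trial_recordings():
            if rec.meta["stim_phase"] != "LLR":
                continue
            ons = detect_onsets(rec.channels[PLATFORM_CHANNEL], 0.05)
            trials += segment(rec, ons, metadata=[rec.meta] * len(ons))
        table = hm_table(trials)
        g = table.groupby("condition")["h_mv"].mean()
        factor = cfg.h_modulation["LLR"]["cheated"]
        assert g["cheated"] / g["predicted"] == pytest.approx(factor, rel=0.05)
        # M-wave amplitudes remain unchanged across conditions
        m = table.groupby("condition")["m_mv"].mean()
        assert m.max() - m.min() < 0.05 * m.mean()
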