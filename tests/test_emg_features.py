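import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from perturbstance.emg_features import (
    MvcReference,
    build_phase_windows,
    detect_reflex_peaks,
    extract_mvc_reference,
    features_table,
    integrated_duration_s,
    normalize_features,
    rectified_integral,
)
from perturbstance.errors import (
    DegenerateBmrWindowError,
    InvalidParameterError,
    WindowBoundsError,
    ZeroMvcError,
)


class TestPhaseWindows:
    def test_bmr_ends_at_cop_peak(self):
        w = build_phase_windows(344.0)
        assert w.bmr == (120.0, 344.0)

    def test_cop_peak_at_120_rejected(self):
        with pytest.raises(DegenerateBmrWindowError):
            build_phase_windows(120.0)

    def test_windows_tile_with_only_the_0_30_gap(self):
        w = build_phase_windows(344.0).as_dict()
        assert w["PRE"] == (-100.0, 0.0)
        assert w["SLR"][0] == 30.0
        for a, b in (("SLR", "MLR"), ("MLR", "LLR"), ("LLR", "BMR")):
            assert w[a][1] == w[b][0]


class TestRectifiedIntegral:
    def test_constant_positive(self):
        epoch = np.full(600, 2.0)
        assert rectified_integral(epoch, (30, 60)) == pytest.approx(0.06, abs=1e-12)

    def test_constant_negative_rectified(self):
        epoch = np.full(600, -2.0)
        assert rectified_integral(epoch, (30, 60)) == pytest.approx(0.06, abs=1e-12)

    def test_out_of_epoch_window_rejected(self):
        with pytest.raises(WindowBoundsError):
            rectified_integral(np.zeros(600), (480, 520))

    def test_against_dense_riemann_oracle(self, rng):
        # oracle: trapezoid of the piecewise-linear |x| on a 1000x finer grid
        epoch = rng.normal(size=600)
        window = (30, 60)
        i0, i1 = 130, 160
        fine_t = np.linspace(i0, i1, (i1 - i0) * 1000 + 1)
        fine_x = np.interp(fine_t, np.arange(600), np.abs(epoch))
        oracle = np.trapezoid(fine_x, dx=(fine_t[1] - fine_t[0]) / 1000.0)
        mine = rectified_integral(epoch, window)
        assert mine == pytest.approx(oracle, rel=1e-9)

    @given(b=st.integers(min_value=-99, max_value=498))
    @settings(max_examples=30, deadline=None)
    def test_additivity(self, b):
        rng = np.random.default_rng(b + 1000)
        epoch = rng.normal(size=600)
        a, c = -100, 499
        if not (a < b < c):
            return
        left = rectified_integral(epoch, (a, b))
        right = rectified_integral(epoch, (b, c))
        whole = rectified_integral(epoch, (a, c))
        assert left + right == pytest.approx(whole, rel=1e-9)


class TestNormalization:
    def _mvc(self, amp=2.0):
        return MvcReference("SOL", amp, amp * 0.1, 0.1, 0)

    def test_time_normalization(self):
        mean_mv, _ = normalize_features(0.06, 0.030, self._mvc())
        assert mean_mv == pytest.approx(2.0)

    def test_self_normalization_is_100_pct(self):
        mvc = self._mvc(2.0)
        _, pct = normalize_features(2.0 * 0.030, 0.030, mvc)
        assert pct == pytest.approx(100.0)

    def test_homogeneity(self):
        mvc = self._mvc()
        _, p1 = normalize_features(0.06, 0.030, mvc)
        _, p2 = normalize_features(0.12, 0.030, mvc)
        assert p2 == pytest.approx(2 * p1)

    def test_scale_equivariance(self):
        # scaling raw EMG and MVC together leaves %MVC unchanged
        _, p1 = normalize_features(0.06, 0.030, self._mvc(2.0))
        _, p2 = normalize_features(0.60, 0.030, self._mvc(20.0))
        assert p1 == pytest.approx(p2)

    def test_zero_mvc_names_muscle(self):
        with pytest.raises(ZeroMvcError) as exc:
            normalize_features(0.06, 0.030, MvcReference("TA", 0.0, 0.0, 0.1, 0))
        assert exc.value.muscle == "TA"


class TestMvcReference:
    def test_argmax_trial_selected(self):
        trials = [np.sin(np.linspace(0, 10, 3000)) * a for a in (1.0, 2.0, 3.0)]
        ref = extract_mvc_reference(trials, "SOL")
        assert ref.trial_index == 2

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        trials = [rng.normal(0, a, 3000) for a in (1.0, 3.0, 2.0)]
        r1 = extract_mvc_reference(trials, "SOL")
        r2 = extract_mvc_reference(trials[::-1], "SOL")
        assert r1.mean_amplitude_mv == pytest.approx(r2.mean_amplitude_mv)

    def test_all_zero_rejected(self):
        with pytest.raises(ZeroMvcError):
            extract_mvc_reference([np.zeros(3000)], "SOL")

    def test_edge_peak_clipped_window(self):
        # peak at sample 10: window clipped, checked against a manual integral
        x = np.zeros(3000)
        x[10] = 5.0
        ref = extract_mvc_reference([x], "SOL")
        manual = np.trapezoid(np.abs(x[0:61]), dx=1e-3)
        assert ref.iemg_mvs == pytest.approx(manual)
        assert ref.duration_s == pytest.approx(0.060)


class TestReflexPeaks:
    def test_noise_free_ensemble_recovers_burst_centers(self):
        from perturbstance.synth import ReflexBurstSpec, generate_emg_trial

        bursts = {"SOL": [ReflexBurstSpec("SLR", 45.0, 4.0, 3.0),
                          ReflexBurstSpec("MLR", 72.0, 4.0, 3.0),
                          ReflexBurstSpec("LLR", 100.0, 4.0, 3.0)]}
        lv = {"SOL": {"PRE": 0.2, "SLR": 0.27, "MLR": 0.30, "LLR": 0.41, "BMR": 0.34}}
        trials = []
        for s in range(60):  # large ensemble stands in for the noise-free case
            ch, _ = generate_emg_trial("predicted", "posterior", "none", bursts,
                                       lv, seed=s, pre_ms=100.0, post_ms=500.0)
            trials.append(ch["SOL"])
        peaks = detect_reflex_peaks(trials)
        assert peaks.slr_ms == pytest.approx(45.0, abs=3.0)
        assert peaks.mlr_ms == pytest.approx(72.0, abs=3.0)
        assert peaks.llr_ms == pytest.approx(100.0, abs=3.0)

    def test_flat_ensemble_ties_to_window_start(self):
        trials = [np.zeros(600), np.zeros(600)]
        peaks = detect_reflex_peaks(trials)
        assert peaks.low_confidence
        assert (peaks.slr_ms, peaks.mlr_ms, peaks.llr_ms) == (30.0, 60.0, 85.0)

    def test_too_few_trials_rejected(self):
        with pytest.raises(InvalidParameterError):
            detect_reflex_peaks([np.zeros(600)])

    def test_noisy_cohort_peaks_inside_windows(self, small_cohort, segmented_trials):
        fam = [t for t in segmented_trials
               if t.subject == "S01" and t.condition == "predicted"
               and t.stim_phase == "none"]
        peaks = detect_reflex_peaks(fam)
        assert 30 <= peaks.slr_ms < 60
        assert 60 <= peaks.mlr_ms < 85
        assert 85 <= peaks.llr_ms < 120


class TestFeaturesTable:
    def test_stimulated_trials_excluded(self, segmented_trials, mvc_refs):
        t = features_table([t for t in segmented_trials if t.subject == "S01"],
                           mvc_refs["S01"])
        stim_ids = {tr.meta["trial_id"] for tr in segmented_trials
                    if tr.stim_phase != "none"}
        assert not set(t.trial_id) & stim_ids

    def test_all_values_nonnegative(self, segmented_trials, mvc_refs):
        t = features_table([t for t in segmented_trials if t.subject == "S01"],
                           mvc_refs["S01"])
        assert (t[["iemg_mvs", "mean_mv", "pct_mvc"]] >= 0).all().all()

    def test_pct_mvc_consistent_with_iemg(self, segmented_trials, mvc_refs):
        t = features_table([t for t in segmented_trials if t.subject == "S01"],
                           mvc_refs["S01"])
        for _, row in t.head(50).iterrows():
            ref = mvc_refs["S01"][row.muscle]
            dur = row.iemg_mvs / row.mean_mv if row.mean_mv > 0 else None
            if dur:
                expect = row.mean_mv / ref.mean_amplitude_mv * 100.0
                assert row.pct_mvc == pytest.approx(expect, rel=1e-9)

    def test_window_amplitudes_recover_subject_truth(self, small_cohort,
                                                     segmented_trials):
        # compare window-mean rectified amplitude against generator truth,
        # bypassing the (noisy) MVC reference estimate
        sv = small_cohort.subject_table
        sid, cond = "S01", "predicted"
        trials = [t for t in segmented_trials
                  if t.subject == sid and t.condition == cond and t.stim_phase == "none"]
        for muscle in ("SOL", "TA"):
            amp = small_cohort.mvc_amp[(sid, muscle)]
            for phase, win in (("PRE", (-100, 0)), ("LLR", (85, 120))):
                got = np.mean([
                    rectified_integral(t.channels[muscle], win)
                    / integrated_duration_s(win, n_samples=600) for t in trials])
                pct = sv[(sv.subject == sid) & (sv.condition == cond)
                         & (sv.variable == f"emg_{muscle}_{phase}")]["value"].iloc[0]
                target = max(pct, 0.0) / 100.0 * amp
                assert got == pytest.approx(target, rel=0.25, abs=1e-4)
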