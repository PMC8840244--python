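import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from shallowbp.preprocess import (
    BandpassSpec,
    BPLabels,
    DegenerateSegmentError,
    NormalizationContext,
    PreprocessConfig,
    QualityThresholds,
    assess_quality,
    compute_derivatives,
    correct_baseline,
    detect_peaks,
    extract_bp_labels,
    normalize_abp,
    normalize_unit_range,
    preprocess_store,
)
from shallowbp.segment_io import SegmentRecord, WaveformSegment
from shallowbp.synth import SyntheticConfig, generate, inject_drift


class TestPeakDetection:
    @pytest.mark.parametrize(
        "x, idx, prom",
        [
            ([0, 1, 0, 2, 0], [1, 3], [1, 2]),
            ([0, 1, 2, 3], [], []),
            ([0, 2, 2, 0], [1], [2]),  # plateau contributes its first sample
        ],
    )
    def test_local_maxima_and_prominences(self, x, idx, prom):
        ps = detect_peaks(x)
        assert ps.indices.tolist() == idx
        assert ps.prominences.tolist() == prom

    def test_intervals_are_successive_differences(self):
        ps = detect_peaks([0, 3, 0, 2, 0, 5, 0])
        assert ps.intervals.tolist() == [2, 2]


class TestBaselineCorrection:
    def test_pulse_train_with_ramp_preserves_range(self):
        t = np.arange(1076)
        x = np.sin(2 * np.pi * t / 90.0) ** 8 + 0.001 * t
        y, fit = correct_baseline(x)
        assert fit.branch == "peak-driven"
        assert y.min() == pytest.approx(0.0, abs=1e-12)
        assert np.ptp(y) == pytest.approx(np.ptp(x), rel=1e-12)

    def test_constant_input_flagged_degenerate(self):
        x = np.full(100, 5.0)
        y, fit = correct_baseline(x)
        assert fit.branch == "degenerate"
        assert np.array_equal(y, x)

    def test_sinusoidal_drift_removal_improves_correlation(self):
        t = np.arange(1076)
        clean = np.sin(2 * np.pi * t / 90.0) ** 8
        drift = 0.5 * np.sin(2 * np.pi * 0.2 * t / 125.0)
        y, _ = correct_baseline(clean + drift)
        assert np.corrcoef(y, clean)[0, 1] > np.corrcoef(clean + drift, clean)[0, 1]

    def test_min_zero_range_preserved_on_many_synthetic_segments(self):
        store, _ = generate(
            SyntheticConfig(n_records=50, seed=21, drift_amplitude=0.3)
        )
        checked = 0
        for rec in store:
            for kind in ("PPG", "ABP", "ECG"):
                x = rec.channel(kind).samples
                y, fit = correct_baseline(x)
                if fit.branch == "degenerate":
                    continue
                assert y.min() == pytest.approx(0.0, abs=1e-9)
                assert np.ptp(y) == pytest.approx(np.ptp(x), rel=1e-9)
                checked += 1
        assert checked >= 140


class TestNormalization:
    @pytest.mark.parametrize(
        "x, expected",
        [([1, 2, 3], [0, 0.5, 1]), ([-10, 0, 30], [0, 0.25, 1])],
    )
    def test_matches_direct_min_max(self, x, expected):
        assert np.allclose(normalize_unit_range(x), expected)

    @settings(max_examples=100, derandomize=True)
    @given(
        st.lists(st.floats(-1e4, 1e4), min_size=3, max_size=64).filter(
            lambda v: max(v) - min(v) > 1e-6
        )
    )
    def test_affine_invariance_oracle(self, x):
        x = np.asarray(x)
        expected = (x - x.min()) / np.ptp(x)
        assert np.allclose(normalize_unit_range(x), expected, atol=1e-9)

    def test_idempotent(self):
        x = normalize_unit_range([3.0, 1.0, 7.0, 5.0])
        assert np.allclose(normalize_unit_range(x), x, atol=1e-12)

    def test_constant_segment_rejected(self):
        with pytest.raises(DegenerateSegmentError):
            normalize_unit_range([2.0, 2.0, 2.0])

    def test_global_abp_scaling_is_linear_and_invertible(self):
        ctx = NormalizationContext(global_sbp_max=200.0)
        seg = np.array([60.0, 120.0])
        out = normalize_abp(seg, ctx)
        assert np.allclose(out, [0.3, 0.6])
        assert np.allclose(out * ctx.global_sbp_max, seg)
        assert np.allclose(normalize_abp(2 * seg, ctx), 2 * out)

    def test_relative_amplitude_across_segments_preserved(self):
        ctx = NormalizationContext(global_sbp_max=200.0)
        a = normalize_abp(np.array([50.0, 100.0]), ctx)
        b = normalize_abp(np.array([100.0, 200.0]), ctx)
        assert np.allclose(b, 2 * a)


class TestDerivatives:
    def test_output_lengths_are_1024(self):
        t = np.arange(1076) / 125.0
        ppg, vpg, apg = compute_derivatives(np.sin(2 * np.pi * 1.5 * t) + 2)
        assert len(ppg) == len(vpg) == len(apg) == 1024

    def test_vpg_aligns_with_analytic_derivative(self):
        t = np.arange(1076) / 125.0
        _, vpg, _ = compute_derivatives(np.sin(2 * np.pi * 1.5 * t))
        ref = normalize_unit_range(np.cos(2 * np.pi * 1.5 * np.arange(1024) / 125.0))
        lags = range(-3, 4)
        cors = [np.corrcoef(np.roll(vpg, k)[8:-8], ref[8:-8])[0, 1] for k in lags]
        best = list(lags)[int(np.argmax(cors))]
        assert abs(best) <= 1
        assert max(cors) > 0.99

    def test_constant_input_reported_degenerate(self):
        with pytest.raises(DegenerateSegmentError):
            compute_derivatives(np.full(1076, 3.0))

    def test_insufficient_margin_names_requirement(self):
        with pytest.raises(ValueError, match="margin"):
            compute_derivatives(np.sin(np.arange(1030) * 0.1))

    def test_reflect_mode_accepts_exact_1024(self):
        t = np.arange(1024) / 125.0
        ppg, vpg, apg = compute_derivatives(
            np.sin(2 * np.pi * 1.5 * t) + 2, pad_mode="reflect"
        )
        assert len(ppg) == len(vpg) == len(apg) == 1024

    def test_linear_phase_group_delay(self):
        spec = BandpassSpec(order=51)
        assert spec.group_delay == 25
        with pytest.raises(ValueError):
            BandpassSpec(order=50)


class TestLabels:
    def test_extrema_on_two_level_signal(self):
        abp = np.tile(np.r_[np.full(30, 70.0), np.full(30, 130.0)], 5)
        lab = extract_bp_labels(abp, method="extrema")
        assert lab.sbp == 130 and lab.dbp == 70
        assert lab.map == pytest.approx(90.0)

    def test_peak_mean_recovers_generator_targets(self, clean_store):
        store, truth = clean_store
        for rec, (_, row) in zip(store, truth.iterrows()):
            lab = extract_bp_labels(rec.channel("ABP").samples)
            assert lab.sbp == pytest.approx(row.sbp, abs=2.0)
            assert lab.dbp == pytest.approx(row.dbp, abs=2.0)

    def test_map_always_between_dbp_and_sbp(self, clean_store):
        store, _ = clean_store
        for rec in store.records[:20]:
            lab = extract_bp_labels(rec.channel("ABP").samples)
            assert lab.dbp <= lab.map <= lab.sbp

    def test_flat_waveform_is_label_failure(self):
        with pytest.raises(ValueError):
            extract_bp_labels(np.full(1024, 80.0))

    def test_invalid_ordering_rejected(self):
        with pytest.raises(ValueError):
            BPLabels(sbp=70, dbp=80, map=75)


def _labels(sbp, dbp):
    return BPLabels(sbp=sbp, dbp=dbp, map=dbp + (sbp - dbp) / 3)


class TestQuality:
    def test_low_sbp_rejected_by_range_rule(self, clean_store):
        store, _ = clean_store
        d = assess_quality(store.records[0], _labels(75, 55))
        assert not d.accepted and d.reason == "sbp_range"

    def test_wide_pulse_pressure_rejected(self, clean_store):
        store, _ = clean_store
        d = assess_quality(store.records[0], _labels(185, 55))
        assert not d.accepted and d.reason == "pulse_pressure"

    def test_blank_channel_rejected(self, clean_store):
        store, _ = clean_store
        rec = store.records[0]
        blank = rec.with_channels(
            PPG=WaveformSegment(np.zeros(rec.n_samples), rec.fs, "PPG")
        )
        d = assess_quality(blank, _labels(120, 70))
        assert not d.accepted and d.reason == "blank"

    def test_clean_uniform_record_accepted(self, clean_store):
        store, truth = clean_store
        rec = store.records[0]
        lab = extract_bp_labels(rec.channel("ABP").samples)
        assert assess_quality(rec, lab).accepted

    def test_monotone_in_thresholds(self, mixed_store):
        store, _ = mixed_store
        thr = QualityThresholds()
        loose = thr.loosened()
        for rec in store.records[:40]:
            try:
                lab = extract_bp_labels(rec.channel("ABP").samples)
            except ValueError:
                lab = None
            if assess_quality(rec, lab, thr).accepted and lab is not None:
                assert assess_quality(rec, lab, loose).accepted


class TestStorePipeline:
    def test_distorted_records_rejected_clean_kept(self, mixed_store):
        store, truth = mixed_store
        result = preprocess_store(store)
        rejected = set(result.report.loc[result.report.rule != "accept", "segment_id"])
        distorted = set(truth.loc[truth.distorted, "segment_id"])
        assert len(rejected & distorted) >= 18
        assert len(rejected - distorted) <= 2

    def test_loosened_thresholds_accept_all_clean(self, clean_store):
        store, _ = clean_store
        cfg = PreprocessConfig(thresholds=QualityThresholds().loosened())
        result = preprocess_store(store, cfg)
        assert len(result.store) == len(store)

    def test_normalized_abp_in_unit_interval_with_max_one(self, clean_store):
        store, _ = clean_store
        result = preprocess_store(store)
        abp = result.store.channel_matrix("ABP")
        assert abp.max() == pytest.approx(1.0)
        assert abp.min() > 0

    def test_deterministic_given_config(self, clean_store):
        store, _ = clean_store
        r1 = preprocess_store(store)
        r2 = preprocess_store(store)
        assert np.array_equal(
            r1.store.channel_matrix("PPG"), r2.store.channel_matrix("PPG")
        )
        assert r1.labels.equals(r2.labels)

    def test_frozen_context_reused_for_heldout_data(self, clean_store):
        store, _ = clean_store
        first = preprocess_store(store.subset(range(40)))
        second = preprocess_store(store.subset(range(40, 60)), context=first.context)
        assert second.context.global_sbp_max == first.context.global_sbp_max

    def test_history_flag_appended(self, clean_store):
        store, _ = clean_store
        result = preprocess_store(store)
        assert result.store.history[-1] == "preprocessed"
        assert len(result.store.history) == len(store.history) + 1


class TestDriftInjection:
    def test_zero_amplitude_is_identity(self, clean_store):
        store, _ = clean_store
        rec = store.records[0]
        assert inject_drift(rec, 0.0) is rec

    def test_injected_sinusoid_is_exact_difference(self, clean_store):
        store, _ = clean_store
        rec = store.records[0]
        drifted = inject_drift(rec, 0.5, freq=0.2)
        diff = drifted.channel("PPG").samples - rec.channel("PPG").samples
        t = np.arange(rec.n_samples) / rec.fs
        expected = 0.5 * np.ptp(rec.channel("PPG").samples) * np.sin(2 * np.pi * 0.2 * t)
        assert np.allclose(diff, expected)

    def test_baseline_correction_recovers_clean_signal(self, clean_store):
        store, _ = clean_store
        rec = store.records[1]
        clean = rec.channel("PPG").samples
        drifted = inject_drift(rec, 0.5, freq=0.2).channel("PPG").samples
        corrected, _ = correct_baseline(drifted)
        assert np.corrcoef(corrected, clean)[0, 1] > np.corrcoef(drifted, clean)[0, 1]
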