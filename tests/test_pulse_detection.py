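"""Isolated-peak detection, threshold sweeps, grouping and ICI classes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_snr_series
from dolphinpam.pulse_detection import (
    PeakEvent,
    PulseSequence,
    classify_mean_ici,
    detect_peaks,
    group_peaks,
    threshold_sensitivity,
)


def brute_force_peaks(snr, th):
    """Direct transcription of the two-sided rule, index by index."""
    return [
        i
        for i in range(1, len(snr) - 1)
        if snr[i] >= th and snr[i - 1] < th and snr[i + 1] < th
    ]


class TestDetectPeaks:
    def test_single_isolated_peak(self):
        series = make_snr_series([2, 12, 3])
        peaks = detect_peaks(series, 10.0)
        assert len(peaks) == 1
        assert peaks[0].time_s == pytest.approx(0.003)  # center of window 1
        assert peaks[0].snr_db == 12.0

    def test_all_below_threshold_empty(self):
        assert detect_peaks(make_snr_series([1, 2, 3, 2, 1]), 10.0) == []

    def test_adjacent_supra_threshold_windows_yield_no_peak(self):
        # literal two-sided rule: a plateau is not an isolated transient
        assert detect_peaks(make_snr_series([2, 12, 12, 3]), 10.0) == []

    def test_local_max_mode_recovers_plateau_edge(self):
        series = make_snr_series([2, 12, 11, 3])
        assert detect_peaks(series, 10.0) == []
        relaxed = detect_peaks(series, 10.0, mode="local_max")
        assert len(relaxed) == 1 and relaxed[0].snr_db == 12.0

    def test_first_and_last_windows_never_peak(self):
        assert detect_peaks(make_snr_series([20, 1, 20]), 10.0) == []

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            detect_peaks(make_snr_series([]), 10.0)

    @given(
        snr=st.lists(st.floats(min_value=-20, max_value=30), min_size=3, max_size=60),
        th=st.floats(min_value=-5, max_value=25),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_rule(self, snr, th):
        series = make_snr_series(snr)
        got = [p.time_s for p in detect_peaks(series, th)]
        expected = [series.window_centers[i] for i in brute_force_peaks(snr, th)]
        assert got == pytest.approx(expected)

    def test_time_shift_equivariance(self, rng):
        snr = rng.normal(0, 8, 200)
        base = [p.time_s for p in detect_peaks(make_snr_series(list(snr)), 10.0)]
        shifted_vals = np.concatenate([[-50.0] * 5, snr])
        shifted = [p.time_s for p in detect_peaks(make_snr_series(list(shifted_vals)), 10.0)]
        # every base peak reappears 5 windows later (new peaks can only
        # arise at the old boundary)
        expected = [t + 5 * 0.002 for t in base]
        assert all(any(abs(s - e) < 1e-9 for s in shifted) for e in expected)


class TestThresholdSensitivity:
    def test_noise_only_counts_fall_to_zero(self, rng):
        series = make_snr_series(list(rng.normal(0, 3, 1000)))
        curve = threshold_sensitivity(series, np.arange(0.0, 30.0, 1.0))
        assert curve.n_peaks[-1] == 0
        assert curve.n_above[-1] == 0

    def test_injected_spike_detected_across_thresholds(self):
        snr = [0.0] * 50
        snr[25] = 20.0
        curve = threshold_sensitivity(make_snr_series(snr), np.arange(1.0, 20.5, 1.0))
        assert np.all(curve.n_peaks == 1)

    def test_criterion1_counts_monotone_non_increasing(self, rng):
        series = make_snr_series(list(rng.normal(5, 5, 500)))
        curve = threshold_sensitivity(series, np.linspace(-5, 25, 61))
        assert np.all(np.diff(curve.n_above) <= 0)

    def test_empty_grid_rejected(self, rng):
        with pytest.raises(ValueError):
            threshold_sensitivity(make_snr_series([1, 2, 3]), np.array([]))

    def test_knee_sits_between_noise_decay_and_signal_plateau(self, rng):
        # noise windows ~N(0,2) dB plus 20 isolated 25 dB spikes: the knee
        # must land above the noise bulk and below the spike level
        snr = rng.normal(0, 2, 2000)
        snr[::100] = 25.0
        curve = threshold_sensitivity(make_snr_series(list(snr)), np.arange(0.0, 30.0, 0.5))
        assert 2.0 < curve.suggested_th_db < 25.0


class TestGroupPeaks:
    @staticmethod
    def peaks_at(times):
        return [PeakEvent(time_s=t, snr_db=15.0) for t in times]

    def test_gap_splits_into_two_sequences(self):
        seqs = group_peaks(self.peaks_at([0.0, 0.1, 0.2, 3.0, 3.1, 3.2]), max_gap_s=2.0)
        assert len(seqs) == 2
        for s in seqs:
            assert s.n_peaks == 3
            assert s.mean_ici_s == pytest.approx(0.1)

    def test_empty_and_undersized_inputs(self):
        assert group_peaks([]) == []
        assert group_peaks(self.peaks_at([0.0, 0.1]), min_peaks=3) == []

    def test_sequence_metrics(self):
        (seq,) = group_peaks(self.peaks_at([1.0, 1.5, 2.5]))
        assert seq.duration_s == pytest.approx(1.5)
        assert seq.mean_ici_s == pytest.approx(0.75)
        assert seq.mean_snr_db == pytest.approx(15.0)
        assert seq.category == "ECT"

    def test_unsorted_peaks_rejected(self):
        with pytest.raises(ValueError):
            group_peaks(self.peaks_at([1.0, 0.5, 2.0]))


class TestClassifyMeanIci:
    @pytest.mark.parametrize(
        "ici,expected",
        [
            (0.50, "ECT"),
            (0.23, "ECT"),
            (0.22, "BPS"),  # ECT requires strictly longer than 0.22 s
            (0.10, "BPS"),
            (0.018, "BPS"),
            (0.017, "FB"),  # FB includes the boundary
            (0.010, "FB"),
        ],
    )
    def test_category_assignment(self, ici, expected):
        assert classify_mean_ici(ici) == expected

    def test_non_positive_ici_rejected(self):
        with pytest.raises(ValueError):
            classify_mean_ici(0.0)

    def test_boundary_sweep_has_exactly_two_transitions(self):
        grid = np.round(np.arange(0.001, 0.5001, 0.001), 3)
        cats = [classify_mean_ici(g) for g in grid]
        transitions = [
            (grid[i], cats[i - 1], cats[i])
            for i in range(1, len(cats))
            if cats[i] != cats[i - 1]
        ]
        assert len(transitions) == 2
        assert transitions[0] == (pytest.approx(0.018), "FB", "BPS")
        assert transitions[1] == (pytest.approx(0.221), "BPS", "ECT")

    @given(st.floats(min_value=1e-4, max_value=10.0))
    @settings(max_examples=300, deadline=None)
    def test_partition_total_and_exclusive(self, ici):
        assert classify_mean_ici(ici) in {"FB", "BPS", "ECT"}

    def test_pulse_sequence_category_consistent_with_rule(self):
        seq = PulseSequence(
            peak_times_s=np.array([0.0, 0.1, 0.2]), peak_snrs_db=np.array([12.0, 13.0, 11.0])
        )
        assert seq.category == classify_mean_ici(seq.mean_ici_s)
        assert len(seq.icis_s) == seq.n_peaks - 1


class TestDetectAndClassify:
    """End-to-end detection on ground-truthed synthetic scenes."""

    def test_injected_bps_train_recovered(self):
        from dolphinpam.synthetic_data import ClickTrainSpec, SceneSpec, render_scene

        spec = SceneSpec(
            duration_s=3.0,
            seed=1,
            events=(ClickTrainSpec(onset_s=0.501, n_clicks=10, ici_s=0.1, per_click_snr_db=20.0),),
        )
        rec, truth = render_scene(spec)
        from dolphinpam.pulse_detection import detect_and_classify

        (seq,) = detect_and_classify(rec, th_db=10.0)
        assert seq.category == "BPS"
        assert seq.n_peaks == 10
        assert seq.mean_ici_s == pytest.approx(0.1, abs=0.002)
        assert seq.mean_snr_db == pytest.approx(20.0, abs=1.5)

    def test_feeding_buzz_recovered(self):
        from dolphinpam.pulse_detection import detect_and_classify
        from dolphinpam.synthetic_data import ClickTrainSpec, SceneSpec, render_scene

        spec = SceneSpec(
            duration_s=1.0,
            seed=5,
            events=(ClickTrainSpec(onset_s=0.101, n_clicks=30, ici_s=0.008, per_click_snr_db=20.0),),
        )
        rec, _ = render_scene(spec)
        (seq,) = detect_and_classify(rec, th_db=10.0)
        assert seq.category == "FB"
        assert seq.n_peaks == 30

    def test_pure_noise_scene_yields_no_sequences_at_auto_threshold(self):
        from dolphinpam.pulse_detection import detect_and_classify
        from dolphinpam.synthetic_data import SceneSpec, render_scene

        rec, _ = render_scene(SceneSpec(duration_s=2.0, seed=4))
        assert detect_and_classify(rec) == []
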