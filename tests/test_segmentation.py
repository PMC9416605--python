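"""Five-stage division algorithm: peaks, cycles, slots, homogenization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from semgband import (
    SegmentationError,
    SegmentationParams,
    SessionRecord,
    derive_cycles,
    detect_cycle_peaks,
    homogenize,
    read_segments,
    segment_session,
    split_channels,
    split_cycle_into_movements,
    synth_session,
    voltage_to_adc,
    write_segments,
)
from tests.conftest import best_label


class TestSplitChannels:
    def test_eight_channel_record(self, rng):
        record = SessionRecord(rng.integers(0, 4096, size=(8, 100)))
        volts = split_channels(record)
        assert volts.shape == (8, 100)

    def test_four_channel_record(self, rng):
        record = SessionRecord(rng.integers(0, 4096, size=(4, 100)))
        assert split_channels(record).shape == (4, 100)

    def test_recombination_inverts(self, rng):
        record = SessionRecord(rng.integers(0, 4096, size=(8, 100)))
        assert np.array_equal(voltage_to_adc(split_channels(record)), record.channels)


class TestDetectPeaks:
    def test_flat_trace_raises(self):
        with pytest.raises(SegmentationError, match="flat"):
            detect_cycle_peaks(np.zeros(100_000))

    def test_peaks_near_ground_truth(self, default_session):
        trace = split_channels(default_session.record)[0]
        peaks = detect_cycle_peaks(trace)
        truth = [i["peak"] for i in default_session.instances if i["movement"] == "M2"]
        assert len(peaks) == 3
        assert np.abs(np.asarray(peaks) - np.asarray(truth)).max() <= 250  # +/-250 ms @1 kHz

    def test_single_cycle_single_peak(self):
        from semgband import CohortSpec, ProtocolTiming

        ss = synth_session("S01", "left", CohortSpec(timing=ProtocolTiming(cycles=1)), seed=3)
        peaks = detect_cycle_peaks(split_channels(ss.record)[0], n_cycles=1)
        assert len(peaks) == 1

    def test_too_few_bursts_raises(self, default_session):
        trace = split_channels(default_session.record)[0]
        with pytest.raises(SegmentationError, match="qualifying"):
            detect_cycle_peaks(trace, n_cycles=5)


class TestDeriveCycles:
    def test_equally_spaced_peaks_arithmetic(self):
        peaks = [21500, 107500, 193500]
        cw = derive_cycles(peaks, trace_length=260_000, peak_slot_fraction=0.5)
        assert cw.cycle_samples == 86_000
        assert cw.slot_samples == pytest.approx(86_000 / 6)
        for p, (s, e) in zip(peaks, cw.windows):
            assert s <= p < e

    def test_gap_deduction(self):
        cw = derive_cycles([21500, 107500, 193500], trace_length=260_000,
                           intercycle_gap_s=2.0, peak_slot_fraction=0.5)
        assert cw.cycle_samples == 84_000

    def test_single_peak_fallback(self):
        # record ends 4.5 slots after the peak (peak mid-slot-2 with f = 0.5)
        slot, peak = 14_000, 21_000
        cw = derive_cycles([peak], trace_length=peak + int(4.5 * slot),
                           peak_slot_fraction=0.5)
        assert cw.cycle_samples == pytest.approx(6 * slot)
        assert cw.windows == [(0, 84_000)]

    def test_uneven_peaks_overlap_error(self):
        with pytest.raises(SegmentationError, match="overlap"):
            derive_cycles([10_000, 20_000, 25_000], trace_length=40_000,
                          peak_slot_fraction=0.5)

    def test_windows_cover_ground_truth_movements(self, default_session):
        trace = split_channels(default_session.record)[0]
        peaks = detect_cycle_peaks(trace)
        cw = derive_cycles(peaks, trace.size, intercycle_gap_s=2.0,
                           peak_slot_fraction=SegmentationParams().peak_slot_fraction)
        by_cycle = {}
        for inst in default_session.instances:
            by_cycle.setdefault(inst["cycle"], []).append(inst)
        for (s, e), cycle in zip(cw.windows, sorted(by_cycle)):
            starts = [i["start"] for i in by_cycle[cycle]]
            ends = [i["end"] for i in by_cycle[cycle]]
            # window covers at least 95% of the cycle's ground-truth span
            span = max(ends) - min(starts)
            covered = min(e, max(ends)) - max(s, min(starts))
            assert covered >= 0.95 * span


class TestSplitSix:
    def test_equal_division(self):
        slots = split_cycle_into_movements(np.zeros((4, 84_000)))
        assert [s.shape[-1] for s in slots] == [14_000] * 6

    def test_remainder_goes_to_last_slots(self):
        slots = split_cycle_into_movements(np.zeros(83_999))
        lengths = [s.shape[-1] for s in slots]
        assert sum(lengths) == 83_999
        assert max(lengths) - min(lengths) <= 1
        assert lengths == sorted(lengths)  # longer slots at the end

    def test_window_too_short(self):
        with pytest.raises(SegmentationError):
            split_cycle_into_movements(np.zeros(5))


class TestHomogenize:
    def test_symmetric_trim(self):
        x = np.arange(14_000)
        out = homogenize(x)
        assert out.shape[-1] == 13_000
        assert out[0] == 500 and out[-1] == 13_499

    def test_exact_length_unchanged(self):
        x = np.arange(13_000)
        assert np.array_equal(homogenize(x), x)

    def test_odd_difference_trims_back(self):
        x = np.arange(13_001)
        out = homogenize(x)
        assert out[0] == 0 and out[-1] == 12_999

    def test_short_input_raises_unless_padded(self):
        with pytest.raises(SegmentationError, match="shorter"):
            homogenize(np.zeros(12_000))
        padded = homogenize(np.zeros(12_999), pad=True)
        assert padded.shape[-1] == 13_000

    @settings(max_examples=30, derandomize=True)
    @given(st.integers(13_000, 20_000))
    def test_output_length_invariant(self, n):
        assert homogenize(np.zeros((4, n))).shape == (4, 13_000)


class TestSegmentSession:
    def test_default_session_yields_18_segments(self, default_segments):
        assert len(default_segments) == 18
        for seg in default_segments:
            assert seg.samples.shape == (4, 13_000)

    def test_labels_match_ground_truth(self, default_session, default_segments):
        for seg in default_segments:
            truth = best_label(default_session.instances, seg.source_range)
            assert seg.movement == truth["movement"]
            assert seg.cycle == truth["cycle"]

    def test_slot_overlap_with_ground_truth(self, default_session, default_segments):
        """>=90% of each segment's samples fall inside its true movement slot."""
        for seg in default_segments:
            a, b = seg.source_range
            truth = best_label(default_session.instances, seg.source_range)
            overlap = min(b, truth["end"]) - max(a, truth["start"])
            assert overlap >= 0.9 * (b - a)

    def test_two_arm_record_yields_36(self, default_session):
        left = synth_session("S01", "left", seed=21)
        right = synth_session("S01", "right", seed=22)
        stacked = SessionRecord(np.vstack([left.record.channels, right.record.channels]),
                                subject_id="S01")
        segments = segment_session(stacked)
        assert len(segments) == 36
        assert {s.arm for s in segments} == {"left", "right"}

    def test_label_recovery_across_seeds(self):
        """Label recovery holds across independently seeded sessions."""
        correct = total = 0
        for i in range(3):
            ss = synth_session(f"P{i}", "left", seed=400 + i)
            for seg in segment_session(ss.record):
                truth = best_label(ss.instances, seg.source_range)
                correct += truth["movement"] == seg.movement
                total += 1
        assert correct / total >= 0.95

    def test_error_names_failing_stage(self, rng):
        record = SessionRecord(np.full((4, 100_000), 2048))  # flat at reference
        with pytest.raises(SegmentationError, match="detect_cycle_peaks"):
            segment_session(record)


class TestSegmentIO:
    def test_round_trip_via_manifest(self, tmp_path, default_segments):
        subset = default_segments[:6]
        write_segments(subset, tmp_path)
        back = read_segments(tmp_path)
        assert len(back) == 6
        for orig, loaded in zip(subset, back):
            assert loaded.movement == orig.movement
            assert loaded.cycle == orig.cycle
            assert loaded.samples.shape == orig.samples.shape
            assert np.allclose(loaded.samples, orig.samples, atol=1e-6)
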