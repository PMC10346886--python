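"""Re-referencing, filtering, segmentation, labeling, artifact rejection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.signal import periodogram

from eegselect.montage import CHANNELS_1020
from eegselect.preprocess import (
    Segment,
    filter_signal,
    label_segments,
    preprocess_recording,
    reject_artifacts,
    rereference,
    segment_recording,
)
from eegselect.synthetic import Recording, SeizureAnnotation, inject_artifacts

from conftest import FS


def _recording(signal, fs=FS, annotations=()):
    return Recording(
        patient_id="pt",
        channel_labels=CHANNELS_1020[: signal.shape[0]],
        sampling_rate=fs,
        signal=signal,
        annotations=list(annotations),
    )


class TestRereference:
    def test_19_channels_become_18(self, recording):
        out = rereference(recording, "FP2")
        assert len(out.channel_labels) == 18
        assert "FP2" not in out.channel_labels
        # order of the remaining labels is preserved
        assert out.channel_labels == tuple(c for c in CHANNELS_1020 if c != "FP2")

    def test_all_channels_equal_reference_gives_zero(self):
        sig = np.tile(np.random.default_rng(0).standard_normal(256), (19, 1))
        out = rereference(_recording(sig), "FP2")
        assert np.abs(out.signal).max() == 0.0

    def test_subtraction_oracle(self):
        rng = np.random.default_rng(1)
        sig = rng.standard_normal((19, 512))
        out = rereference(_recording(sig), "FP2")
        ref = sig[CHANNELS_1020.index("FP2")]
        for i, ch in enumerate(out.channel_labels):
            np.testing.assert_array_equal(out.signal[i], sig[CHANNELS_1020.index(ch)] - ref)

    def test_missing_reference_raises(self, recording):
        with pytest.raises(ValueError, match="reference"):
            rereference(recording, "XX")


class TestFilter:
    def _response(self, freq, fs=256.0, seconds=20.0):
        t = np.arange(int(seconds * fs)) / fs
        sig = np.tile(np.sin(2 * np.pi * freq * t), (19, 1))
        out = filter_signal(_recording(sig, fs), (1.0, 40.0), 50.0)
        mid = out.signal[0, int(2 * fs) : -int(2 * fs)]  # avoid edge transients
        return np.sqrt(2) * mid.std()

    def test_passband_preserves_amplitude(self):
        assert self._response(10.0) == pytest.approx(1.0, rel=0.10)

    def test_notch_removes_mains(self):
        assert self._response(50.0) ** 2 <= 0.01  # power <= 1% of input

    def test_stopband_attenuation(self):
        gain10 = self._response(10.0)
        for f in (0.25, 60.0):
            assert 20 * np.log10(self._response(f) / gain10) <= -20.0

    def test_white_noise_high_frequency_power_suppressed(self):
        rng = np.random.default_rng(2)
        sig = rng.standard_normal((19, int(60 * 256)))
        out = filter_signal(_recording(sig, 256.0), (1.0, 40.0), 50.0)
        f, p = periodogram(out.signal[3], 256.0)
        assert p[f > 60].sum() / p.sum() <= 0.01

    def test_low_sampling_rate_raises(self):
        sig = np.zeros((19, 1000))
        with pytest.raises(ValueError, match="sampling rate"):
            filter_signal(_recording(sig, fs=110.0), (1.0, 60.0))


class TestSegmentation:
    @pytest.mark.parametrize("duration_s,expected", [(60, 5), (20, 1), (19, 0), (45, 3)])
    def test_segment_counts(self, duration_s, expected):
        sig = np.zeros((19, int(duration_s * FS)))
        segs = segment_recording(_recording(sig), 20.0, 10.0)
        assert len(segs) == expected

    def test_segment_geometry(self):
        sig = np.zeros((19, int(65 * FS)))
        segs = segment_recording(_recording(sig), 20.0, 10.0)
        assert [s.start for s in segs] == [0.0, 10.0, 20.0, 30.0, 40.0]
        for s in segs:
            assert s.data.shape == (19, int(20 * FS))

    @given(duration=st.floats(min_value=0.0, max_value=500.0))
    @settings(max_examples=60, deadline=None)
    def test_count_matches_brute_force_enumeration(self, duration):
        """Property: count equals the number of window placements k*step with
        k*step + window within the recording, enumerated directly."""
        fs = 101.0
        n = int(duration * fs)
        rec = Recording("p", ("FP1", "FP2"), fs, np.zeros((2, n)))
        segs = segment_recording(rec, 20.0, 10.0)
        win, hop = int(round(20 * fs)), int(round(10 * fs))
        brute = sum(1 for k in range(n // hop + 1) if k * hop + win <= n)
        assert len(segs) == brute


class TestLabeling:
    def _segments(self, starts, window=20.0):
        return [
            Segment("p", s, window, ("FP1",), np.zeros((1, int(window * FS))), FS)
            for s in starts
        ]

    @pytest.mark.parametrize(
        "seg_start,expected",
        [
            (20.0, "ictal"),  # [20, 40) partially overlaps [25, 30)
            (0.0, "non_ictal"),  # [0, 20) ends before onset
            (30.0, "non_ictal"),  # half-open: touching the offset is no overlap
            (5.0, "non_ictal"),  # [5, 25) ends exactly at the onset
        ],
    )
    def test_half_open_overlap_rule(self, seg_start, expected):
        ann = [SeizureAnnotation(25.0, 30.0)]
        (seg,) = label_segments(self._segments([seg_start]), ann)
        assert seg.label == expected

    def test_every_interior_seizure_sample_covered_by_ictal_segment(self, cohort):
        """Any seizure sample at least one window from the end lies in >=1
        ictal segment."""
        for _, rec in cohort:
            segs = label_segments(segment_recording(rec), rec.annotations)
            ictal = [(s.start, s.end) for s in segs if s.label == "ictal"]
            for ann in rec.annotations:
                for t in np.arange(ann.onset, min(ann.offset, rec.duration - 20.0), 1.0):
                    assert any(a <= t < b for a, b in ictal)


class TestRejection:
    def test_clean_background_not_rejected(self, segments):
        assert all(not s.rejected for s in segments)

    def test_flatline_segments_rejected_with_reason(self, recording):
        noisy = inject_artifacts(recording, 40.0, seed=5)
        segs = preprocess_recording(noisy)
        flats = [a for a in noisy.artifacts if a.kind == "flatline"]
        assert flats
        for art in flats:
            inside = [
                s for s in segs if s.start >= art.onset + 1 and s.end <= art.offset - 1
            ]
            for s in inside:
                assert s.rejected and s.reject_reason == "flatline"

    def test_high_amplitude_segments_rejected(self, recording):
        noisy = inject_artifacts(recording, 40.0, seed=5)
        segs = preprocess_recording(noisy)
        bigs = [a for a in noisy.artifacts if a.kind == "high_amplitude"]
        assert bigs
        for art in bigs:
            overlapping = [
                s for s in segs if s.start < art.offset and art.onset < s.end
            ]
            assert any(s.rejected and s.reject_reason == "amplitude" for s in overlapping)

    def test_pure_sinusoid_rejected_as_dominant(self):
        t = np.arange(int(20 * FS)) / FS
        seg = Segment(
            "p", 0.0, 20.0, ("FP1",), 30 * np.sin(2 * np.pi * 10 * t)[None, :], FS
        )
        (out,) = reject_artifacts([seg])
        assert out.rejected and out.reject_reason == "dominant component"

    def test_rejection_is_idempotent_and_label_blind(self, recording):
        noisy = inject_artifacts(recording, 40.0, seed=5)
        segs = preprocess_recording(noisy)
        first = [(s.rejected, s.reject_reason) for s in segs]
        reject_artifacts(segs)
        assert [(s.rejected, s.reject_reason) for s in segs] == first
        # label-blind: flags are identical whatever the labels say
        for s in segs:
            s.label = "ictal"
        reject_artifacts(segs)
        assert [(s.rejected, s.reject_reason) for s in segs] == first
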