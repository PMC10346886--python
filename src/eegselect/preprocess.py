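"""Preprocessing: re-referencing, filtering, epoching, labeling, rejection.

Raw 19-channel recordings are referenced to FP2 (leaving 18 analysis
channels), bandpass filtered to 1-40 Hz with a 50 Hz notch, cut into 20 s
segments with 10 s overlap, labeled ictal / non-ictal against the seizure
annotations, and screened by automated artifact-rejection criteria.

All intervals are half-open ``[start, end)`` in seconds from recording start.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .synthetic import Recording, SeizureAnnotation

WINDOW_S = 20.0
STEP_S = 10.0

#: Default artifact-rejection thresholds.
AMPLITUDE_MAX_UV = 500.0
FLATLINE_STD_UV = 0.1
DOMINANCE_FRACTION = 0.5
DOMINANCE_BAND = (1.0, 40.0)


@dataclass
class Segment:
    """One labeled 20 s epoch of referenced, filtered EEG."""

    patient_id: str
    start: float
    duration: float
    channel_labels: tuple[str, ...]
    data: np.ndarray  # (n_channels, n_samples), microvolts
    sampling_rate: float
    label: str | None = None  # "ictal" | "non_ictal"
    rejected: bool = False
    reject_reason: str | None = None

    @property
    def end(self) -> float:
        return self.start + self.duration


def rereference(recording: Recording, reference_label: str = "FP2") -> Recording:
    """Subtract the reference channel and drop it, preserving channel order."""
    if reference_label not in recording.channel_labels:
        raise ValueError(f"reference channel {reference_label!r} not in recording")
    ref_idx = recording.channel_labels.index(reference_label)
    keep = [i for i in range(len(recording.channel_labels)) if i != ref_idx]
    return Recording(
        patient_id=recording.patient_id,
        channel_labels=tuple(recording.channel_labels[i] for i in keep),
        sampling_rate=recording.sampling_rate,
        signal=recording.signal[keep] - recording.signal[ref_idx],
        annotations=list(recording.annotations),
        artifacts=list(recording.artifacts),
    )


def filter_signal(
    recording: Recording,
    band: tuple[float, float] = (1.0, 40.0),
    notch: float | None = 50.0,
    *,
    order: int = 4,
    notch_q: float = 30.0,
) -> Recording:
    """Zero-phase bandpass + notch filtering.

    Forward-backward (``filtfilt``) application of a Butterworth bandpass and
    an IIR notch; zero phase shift, squared magnitude response.
    """
    fs = recording.sampling_rate
    if fs <= 2 * band[1]:
        raise ValueError(f"sampling rate {fs} Hz too low for band edge {band[1]} Hz")
    sos = sps.butter(order, band, btype="bandpass", fs=fs, output="sos")
    filtered = sps.sosfiltfilt(sos, recording.signal, axis=1)
    if notch is not None and notch < fs / 2:
        b, a = sps.iirnotch(notch, notch_q, fs=fs)
        filtered = sps.filtfilt(b, a, filtered, axis=1)
    return Recording(
        patient_id=recording.patient_id,
        channel_labels=recording.channel_labels,
        sampling_rate=fs,
        signal=filtered,
        annotations=list(recording.annotations),
        artifacts=list(recording.artifacts),
    )


def segment_recording(
    recording: Recording,
    window: float = WINDOW_S,
    step: float = STEP_S,
) -> list[Segment]:
    """Cut into overlapping windows; segment k covers [k*step, k*step+window).

    A trailing stretch shorter than ``window`` is dropped; a recording shorter
    than one window yields an empty list.
    """
    fs = recording.sampling_rate
    n = recording.signal.shape[1]
    win = int(round(window * fs))
    hop = int(round(step * fs))
    segments = []
    for k in range((n - win) // hop + 1 if n >= win else 0):
        i0 = k * hop
        segments.append(
            Segment(
                patient_id=recording.patient_id,
                start=i0 / fs,
                duration=window,
                channel_labels=recording.channel_labels,
                data=recording.signal[:, i0 : i0 + win],
                sampling_rate=fs,
            )
        )
    return segments


def label_segments(
    segments: list[Segment],
    annotations: list[SeizureAnnotation],
) -> list[Segment]:
    """Label each segment ictal iff it overlaps any seizure with positive measure.

    Intervals are half-open, so a segment starting exactly at a seizure's
    offset (or ending at its onset) is non-ictal.
    """
    for seg in segments:
        ictal = any(
            seg.start < ann.offset and ann.onset < seg.end for ann in annotations
        )
        seg.label = "ictal" if ictal else "non_ictal"
    return segments


def reject_artifacts(
    segments: list[Segment],
    *,
    amplitude_max_uv: float = AMPLITUDE_MAX_UV,
    flatline_std_uv: float = FLATLINE_STD_UV,
    dominance_fraction: float = DOMINANCE_FRACTION,
) -> list[Segment]:
    """Flag segments failing any automated noise criterion.

    Criteria (a segment is rejected iff at least one fires, in this order of
    reporting): peak absolute amplitude above ``amplitude_max_uv``; any
    channel flat (std below ``flatline_std_uv``); a single frequency bin
    carrying more than ``dominance_fraction`` of a channel's 1-40 Hz power
    (non-physiological dominant component).  Criteria are label-blind and
    idempotent; flags and reasons are set in place and returned.
    """
    from .features import compute_psd

    for seg in segments:
        reason = None
        if np.abs(seg.data).max() > amplitude_max_uv:
            reason = "amplitude"
        elif (seg.data.std(axis=1) < flatline_std_uv).any():
            reason = "flatline"
        else:
            freqs, psd = compute_psd(seg.data, seg.sampling_rate)
            band = (freqs >= DOMINANCE_BAND[0]) & (freqs <= DOMINANCE_BAND[1])
            band_power = psd[:, band].sum(axis=1)
            peak = psd[:, band].max(axis=1)
            ok = band_power > 0
            if np.any(peak[ok] > dominance_fraction * band_power[ok]):
                reason = "dominant component"
        seg.rejected = reason is not None
        seg.reject_reason = reason
    return segments


def preprocess_recording(
    recording: Recording,
    *,
    reference: str = "FP2",
    band: tuple[float, float] = (1.0, 40.0),
    notch: float | None = 50.0,
    window: float = WINDOW_S,
    step: float = STEP_S,
    amplitude_max_uv: float = AMPLITUDE_MAX_UV,
    flatline_std_uv: float = FLATLINE_STD_UV,
    dominance_fraction: float = DOMINANCE_FRACTION,
) -> list[Segment]:
    """Full preprocessing chain: reference, filter, segment, label, flag.

    Returns all segments (including rejected ones, flagged); downstream
    feature extraction operates on the accepted subset.
    """
    ref = rereference(recording, reference)
    filt = filter_signal(ref, band, notch)
    segments = segment_recording(filt, window, step)
    label_segments(segments, filt.annotations)
    reject_artifacts(
        segments,
        amplitude_max_uv=amplitude_max_uv,
        flatline_std_uv=flatline_std_uv,
        dominance_fraction=dominance_fraction,
    )
    return segments


def accepted(segments: list[Segment]) -> list[Segment]:
    """The non-rejected segments."""
    return [s for s in segments if not s.rejected]
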