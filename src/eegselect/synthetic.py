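"""Seeded synthetic EEG cohorts with focal seizures.

The generator emulates the statistical structure a seizure-detection pipeline
relies on, at desk scale: a 19-channel 10-20 montage (later referenced to
FP2), 1/f-like background activity with a patient-specific posterior alpha
rhythm, and focal seizures expressed as amplitude-modulated theta/alpha-band
chirps on a patient-specific electrode subset with spatial leakage to
neighbouring electrodes.  Optional artifact episodes (amplifier dropout,
high-amplitude transients, mains contamination) provide inputs for the
automated rejection criteria downstream.

Everything is driven by explicit integer seeds: equal seeds give
bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .montage import (
    ADJACENCY,
    ANALYSIS_CHANNELS,
    CHANNELS_1020,
    FOCAL_CHANNEL_MAP,
    FOCUS_ZONES,
    HEMISPHERES,
)

#: Desk-scale defaults: a cohort small enough to run end-to-end on one CPU
#: while preserving >=5 seizures per patient and the focus-zone strata mix.
DEFAULT_ZONE_DISTRIBUTION = {
    "temporal": 0.75,
    "frontal": 0.12,
    "parietal": 0.065,
    "occipital": 0.065,
}
DEFAULT_SAMPLING_RATE = 256.0
DEFAULT_SEIZURE_RATE = 10.0  # events/hour at desk scale
MIN_SEIZURES = 5
DEFAULT_MIN_GAP_S = 60.0
EDGE_MARGIN_S = 30.0


class SimulationError(ValueError):
    """Raised when requested cohort parameters are infeasible."""


@dataclass(frozen=True)
class SeizureAnnotation:
    """One annotated seizure, half-open interval [onset, offset) in seconds."""

    onset: float
    offset: float
    vigilance: str | None = None
    seizure_class: str | None = None

    def __post_init__(self):
        if not 0 <= self.onset < self.offset:
            raise ValueError(f"invalid seizure interval [{self.onset}, {self.offset})")


@dataclass(frozen=True)
class ArtifactAnnotation:
    """Injected artifact episode kept as metadata for test oracles."""

    kind: str  # flatline | high_amplitude | mains
    onset: float
    offset: float
    channels: tuple[str, ...]


@dataclass(frozen=True)
class PatientProfile:
    patient_id: str
    focus_zone: str
    hemisphere: str
    focal_channels: tuple[str, ...]
    seizure_rate: float
    background_params: dict = field(compare=False)
    seed: int = 0

    def __post_init__(self):
        if self.focus_zone not in FOCUS_ZONES:
            raise ValueError(f"unknown focus zone {self.focus_zone!r}")
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(f"unknown hemisphere {self.hemisphere!r}")
        if not self.focal_channels:
            raise ValueError("focal_channels must be non-empty")
        bad = set(self.focal_channels) - set(ANALYSIS_CHANNELS)
        if bad:
            raise ValueError(f"focal channels outside the analysis montage: {bad}")
        if self.seizure_rate <= 0:
            raise ValueError("seizure_rate must be > 0")


@dataclass
class Recording:
    """Continuous multi-channel EEG in microvolts with annotations."""

    patient_id: str
    channel_labels: tuple[str, ...]
    sampling_rate: float
    signal: np.ndarray  # (n_channels, n_samples)
    annotations: list[SeizureAnnotation] = field(default_factory=list)
    artifacts: list[ArtifactAnnotation] = field(default_factory=list)

    def __post_init__(self):
        self.channel_labels = tuple(self.channel_labels)
        if self.signal.ndim != 2 or self.signal.shape[0] != len(self.channel_labels):
            raise ValueError("signal must be (n_channels, n_samples)")
        if self.sampling_rate <= 100:
            raise ValueError("sampling_rate must exceed 100 Hz")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite samples")
        last = 0.0
        for ann in self.annotations:
            if ann.onset < last:
                raise ValueError("annotations must be sorted and non-overlapping")
            if ann.offset > self.duration + 1e-9:
                raise ValueError("annotation extends past end of recording")
            last = ann.offset

    @property
    def duration(self) -> float:
        return self.signal.shape[1] / self.sampling_rate

    def copy(self) -> "Recording":
        return Recording(
            patient_id=self.patient_id,
            channel_labels=self.channel_labels,
            sampling_rate=self.sampling_rate,
            signal=self.signal.copy(),
            annotations=list(self.annotations),
            artifacts=list(self.artifacts),
        )


# ---------------------------------------------------------------------------
# profiles


def sample_profiles(
    n_patients: int,
    seed: int,
    zone_distribution: dict[str, float] | None = None,
    hemisphere_distribution: dict[str, float] | None = None,
    seizure_rate: float = DEFAULT_SEIZURE_RATE,
) -> list[PatientProfile]:
    """Draw patient profiles whose strata match the target zone distribution.

    Zone counts are assigned by largest-remainder apportionment of the target
    distribution, then shuffled, so the realized frequencies track the target
    as closely as integer counts allow.
    """
    if n_patients < 1:
        raise SimulationError("n_patients must be >= 1")
    zone_distribution = dict(zone_distribution or DEFAULT_ZONE_DISTRIBUTION)
    hemisphere_distribution = dict(hemisphere_distribution or {"left": 0.5, "right": 0.5})
    rng = np.random.default_rng(seed)

    zones = _apportion(zone_distribution, n_patients)
    rng.shuffle(zones)
    hemis = [
        str(rng.choice(list(hemisphere_distribution), p=_norm(hemisphere_distribution)))
        for _ in range(n_patients)
    ]

    profiles = []
    for i, (zone, hemi) in enumerate(zip(zones, hemis)):
        beta = float(rng.uniform(0.8, 1.6))
        background = {
            "one_over_f_exponent": beta,
            "noise_uv": float(rng.uniform(15.0, 25.0)),
            "alpha_freq_hz": float(rng.uniform(8.5, 11.5)),
            "alpha_posterior_uv": float(rng.uniform(8.0, 14.0)),
            "alpha_anterior_uv": float(rng.uniform(2.0, 4.0)),
        }
        profiles.append(
            PatientProfile(
                patient_id=f"pt{i:03d}",
                focus_zone=zone,
                hemisphere=hemi,
                focal_channels=FOCAL_CHANNEL_MAP[(zone, hemi)],
                seizure_rate=seizure_rate,
                background_params=background,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return profiles


def _norm(dist: dict[str, float]) -> list[float]:
    total = sum(dist.values())
    return [v / total for v in dist.values()]


def _apportion(dist: dict[str, float], n: int) -> list[str]:
    keys = list(dist)
    weights = np.array([dist[k] for k in keys], float)
    weights = weights / weights.sum()
    ideal = weights * n
    counts = np.floor(ideal).astype(int)
    remainder = ideal - counts
    for idx in np.argsort(-remainder)[: n - counts.sum()]:
        counts[idx] += 1
    out: list[str] = []
    for k, c in zip(keys, counts):
        out.extend([k] * int(c))
    return out


# ---------------------------------------------------------------------------
# signal synthesis


def _pink_noise(rng: np.random.Generator, n: int, exponent: float, fs: float) -> np.ndarray:
    """Gaussian 1/f^exponent noise, unit standard deviation.

    The spectral shaping is floored below 0.5 Hz so the process models
    broadband EEG background rather than being dominated by sub-delta drift
    (which the acquisition high-pass removes in real recordings anyway).
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.maximum(freqs, 0.5) ** (-exponent / 2.0)
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _narrowband_noise(
    rng: np.random.Generator, n: int, fs: float, center: float, bandwidth: float = 1.5
) -> np.ndarray:
    """Unit-std Gaussian process with a Gaussian spectral peak at ``center``.

    Models physiological rhythms (alpha in particular), whose power is
    spread over ~1-2 Hz rather than concentrated in a pure tone; a pure
    sinusoid would (correctly) trip the dominant-component rejection rule.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    sigma = bandwidth / 2.355  # FWHM -> standard deviation
    mask = np.exp(-0.5 * ((freqs - center) / sigma) ** 2)
    x = np.fft.irfft(spec * mask, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _seizure_waveform(
    rng: np.random.Generator,
    n: int,
    fs: float,
    band: tuple[float, float],
    amplitude: float,
) -> np.ndarray:
    """Amplitude-modulated chirp sweeping downward through ``band``.

    Mimics the rhythmic build-up and slowing of a focal ictal discharge:
    a Tukey envelope ramps the rhythm in and out, while the instantaneous
    frequency drifts from near the top of the band towards its bottom.
    """
    from scipy.signal import windows

    t = np.arange(n) / fs
    f_hi = band[1] - 0.5 * (band[1] - band[0]) * rng.uniform(0.0, 0.3)
    f_lo = band[0] + 0.5 * (band[1] - band[0]) * rng.uniform(0.0, 0.3)
    freq = np.linspace(f_hi, f_lo, n)
    phase = 2 * np.pi * np.cumsum(freq) / fs + rng.uniform(0, 2 * np.pi)
    envelope = windows.tukey(n, alpha=0.4)
    # slow waxing-waning modulation typical of ictal rhythms
    modulation = 1.0 + 0.3 * np.sin(2 * np.pi * rng.uniform(0.1, 0.3) * t)
    return amplitude * envelope * modulation * np.sin(phase)


def _place_intervals(
    rng: np.random.Generator,
    durations: np.ndarray,
    total: float,
    min_gap: float,
    margin: float,
) -> list[tuple[float, float]]:
    """Place non-overlapping intervals with a minimum gap, uniformly at random."""
    n = len(durations)
    occupied = durations.sum() + min_gap * (n - 1) + 2 * margin
    free = total - occupied
    if free < 0:
        raise SimulationError(
            f"cannot place {n} events totalling {durations.sum():.0f}s "
            f"with {min_gap:.0f}s gaps in a {total:.0f}s recording"
        )
    cuts = np.sort(rng.uniform(0, free, size=n))
    starts = []
    cursor = margin
    for i in range(n):
        start = cursor + cuts[i] - (cuts[i - 1] if i else 0.0)
        starts.append(start)
        cursor = start + durations[i] + min_gap
    return [(s, s + d) for s, d in zip(starts, durations)]


def generate_recording(
    profile: PatientProfile,
    hours: float,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
    *,
    seizure_band: tuple[float, float] = (4.0, 9.0),
    seizure_amplitude: float = 40.0,
    leakage: float = 0.2,
    min_gap_s: float = DEFAULT_MIN_GAP_S,
    min_seizures: int = MIN_SEIZURES,
) -> Recording:
    """Synthesize one patient's continuous recording with annotated seizures."""
    rng = np.random.default_rng(profile.seed)
    fs = float(sampling_rate)
    n = int(round(hours * 3600 * fs))
    bp = profile.background_params

    posterior = {"T5", "P3", "Pz", "P4", "T6", "O1", "O2"}
    signal = np.empty((len(CHANNELS_1020), n))
    for i, ch in enumerate(CHANNELS_1020):
        x = bp["noise_uv"] * _pink_noise(rng, n, bp["one_over_f_exponent"], fs)
        amp = bp["alpha_posterior_uv"] if ch in posterior else bp["alpha_anterior_uv"]
        # RMS-equivalent to a sinusoid of amplitude `amp`
        x += (amp / np.sqrt(2)) * _narrowband_noise(rng, n, fs, bp["alpha_freq_hz"])
        signal[i] = x

    n_seiz = max(min_seizures, int(rng.poisson(profile.seizure_rate * hours)))
    durations = rng.uniform(25.0, 70.0, size=n_seiz)
    intervals = _place_intervals(rng, durations, hours * 3600, min_gap_s, EDGE_MARGIN_S)

    # spatial projection: focal channels get the full discharge, their scalp
    # neighbours a leakage fraction
    gains = np.zeros(len(CHANNELS_1020))
    for focal in profile.focal_channels:
        gains[CHANNELS_1020.index(focal)] = 1.0
    for focal in profile.focal_channels:
        for nb in ADJACENCY[focal]:
            idx = CHANNELS_1020.index(nb)
            if gains[idx] == 0.0 and nb != "FP2":
                gains[idx] = leakage

    annotations = []
    for onset, offset in intervals:
        i0, i1 = int(round(onset * fs)), int(round(offset * fs))
        wave = _seizure_waveform(rng, i1 - i0, fs, seizure_band, seizure_amplitude)
        signal[:, i0:i1] += gains[:, None] * wave[None, :]
        annotations.append(
            SeizureAnnotation(
                onset=i0 / fs,
                offset=i1 / fs,
                vigilance=str(rng.choice(["awake", "sleep"])),
                seizure_class="focal",
            )
        )

    return Recording(
        patient_id=profile.patient_id,
        channel_labels=CHANNELS_1020,
        sampling_rate=fs,
        signal=signal,
        annotations=annotations,
    )


def generate_cohort(
    n_patients: int,
    hours_per_patient: float,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
    seed: int = 0,
    *,
    zone_distribution: dict[str, float] | None = None,
    hemisphere_distribution: dict[str, float] | None = None,
    seizure_rate: float = DEFAULT_SEIZURE_RATE,
    seizure_band: tuple[float, float] = (4.0, 9.0),
    seizure_amplitude: float = 40.0,
    min_gap_s: float = DEFAULT_MIN_GAP_S,
) -> list[tuple[PatientProfile, Recording]]:
    """Generate a seeded cohort of patients and their recordings.

    Raises :class:`SimulationError` when the recording is too short to hold
    the minimum number of seizures with the configured gaps.
    """
    profiles = sample_profiles(
        n_patients,
        seed,
        zone_distribution=zone_distribution,
        hemisphere_distribution=hemisphere_distribution,
        seizure_rate=seizure_rate,
    )
    return [
        (
            p,
            generate_recording(
                p,
                hours_per_patient,
                sampling_rate,
                seizure_band=seizure_band,
                seizure_amplitude=seizure_amplitude,
                min_gap_s=min_gap_s,
            ),
        )
        for p in profiles
    ]


def iter_cohort(
    n_patients: int,
    hours_per_patient: float,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
    seed: int = 0,
    **kwargs,
):
    """Like :func:`generate_cohort` but yields patients one at a time.

    Use this when recordings are processed and discarded immediately, to keep
    peak memory to a single recording.
    """
    profiles = sample_profiles(
        n_patients,
        seed,
        zone_distribution=kwargs.pop("zone_distribution", None),
        hemisphere_distribution=kwargs.pop("hemisphere_distribution", None),
        seizure_rate=kwargs.pop("seizure_rate", DEFAULT_SEIZURE_RATE),
    )
    for p in profiles:
        yield p, generate_recording(p, hours_per_patient, sampling_rate, **kwargs)


# ---------------------------------------------------------------------------
# artifacts

ARTIFACT_KINDS = ("flatline", "high_amplitude", "mains")


def inject_artifacts(
    recording: Recording,
    artifact_rate: float,
    seed: int,
    *,
    mains_freq: float = 50.0,
    clearance_s: float = 30.0,
) -> Recording:
    """Return a copy of ``recording`` with artifact episodes added.

    Three artifact classes are injected, all kept in ``recording.artifacts``
    so tests can locate them exactly:

    - ``flatline``: amplifier dropout — every channel driven to zero, so the
      episode stays flat after re-referencing;
    - ``high_amplitude``: large slow transients (>|500| uV) on a random
      channel subset;
    - ``mains``: strong 50 Hz contamination on all non-reference channels.

    Episodes avoid annotated seizures by ``clearance_s`` seconds and never
    overlap each other.  ``artifact_rate`` of 0 returns an unmodified copy.
    """
    if artifact_rate < 0:
        raise ValueError("artifact_rate must be >= 0")
    out = recording.copy()
    if artifact_rate == 0:
        return out
    rng = np.random.default_rng(seed)
    fs = out.sampling_rate
    n_events = int(rng.poisson(artifact_rate * out.duration / 3600.0))
    if n_events == 0:
        return out

    # free intervals away from seizures
    busy = [(a.onset - clearance_s, a.offset + clearance_s) for a in out.annotations]
    free: list[tuple[float, float]] = []
    cursor = EDGE_MARGIN_S
    for lo, hi in busy + [(out.duration - EDGE_MARGIN_S, out.duration)]:
        if lo > cursor:
            free.append((cursor, lo))
        cursor = max(cursor, hi)

    episodes = []
    for _ in range(n_events):
        kind = str(rng.choice(ARTIFACT_KINDS))
        dur = float(rng.uniform(25.0, 40.0) if kind != "high_amplitude" else rng.uniform(5.0, 15.0))
        for _attempt in range(50):
            spans = [(lo, hi) for lo, hi in free if hi - lo >= dur]
            if not spans:
                break
            lo, hi = spans[int(rng.integers(len(spans)))]
            start = float(rng.uniform(lo, hi - dur))
            if all(start + dur <= s or start >= e for s, e, _ in episodes):
                episodes.append((start, start + dur, kind))
                break

    t = np.arange(out.signal.shape[1]) / fs
    non_ref = [i for i, ch in enumerate(out.channel_labels) if ch != "FP2"]
    for start, end, kind in sorted(episodes):
        i0, i1 = int(round(start * fs)), int(round(end * fs))
        if kind == "flatline":
            out.signal[:, i0:i1] = 0.0
            chans = out.channel_labels
        elif kind == "high_amplitude":
            k = int(rng.integers(1, 5))
            idx = rng.choice(non_ref, size=k, replace=False)
            # movement-like transient: in-band 3 Hz burst so it survives the
            # 1-40 Hz bandpass and trips the amplitude criterion
            env = np.sin(np.pi * np.arange(i1 - i0) / max(i1 - i0, 1))
            carrier = np.sin(2 * np.pi * 3.0 * t[i0:i1])
            out.signal[np.asarray(idx)[:, None], np.arange(i0, i1)[None, :]] += 900.0 * env * carrier
            chans = tuple(out.channel_labels[i] for i in idx)
        else:  # mains
            hum = 300.0 * np.sin(2 * np.pi * mains_freq * t[i0:i1])
            out.signal[non_ref, i0:i1] += hum
            chans = tuple(out.channel_labels[i] for i in non_ref)
        out.artifacts.append(ArtifactAnnotation(kind, i0 / fs, i1 / fs, chans))
    return out
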