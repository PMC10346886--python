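"""End-to-end orchestration: synthetic cohort -> segment feature table.

Recordings are processed one patient at a time (generate, preprocess,
extract, discard), keeping peak memory to a single recording regardless of
cohort size.
"""

from __future__ import annotations

import logging
from typing import Iterable

import pandas as pd

from .features import extract_features
from .preprocess import accepted, preprocess_recording
from .synthetic import PatientProfile, Recording, inject_artifacts, iter_cohort

logger = logging.getLogger(__name__)


def cohort_manifest(profiles: Iterable[PatientProfile]) -> pd.DataFrame:
    """Per-patient strata table (patient -> zone, hemisphere, focal set)."""
    return pd.DataFrame(
        {
            "patient_id": p.patient_id,
            "focus_zone": p.focus_zone,
            "hemisphere": p.hemisphere,
            "focal_channels": "+".join(p.focal_channels),
            "seizure_rate": p.seizure_rate,
            "seed": p.seed,
        }
        for p in profiles
    )


def recording_features(recording: Recording, **preprocess_kwargs) -> pd.DataFrame:
    """Preprocess one recording and extract the full feature table.

    The out-of-range columns emitted here are placeholders fit on the
    recording's own non-ictal segments; the split protocol recomputes them
    from each split's training rows before any model sees the table.
    """
    segments = preprocess_recording(recording, **preprocess_kwargs)
    ok = accepted(segments)
    n_rej = len(segments) - len(ok)
    if n_rej:
        logger.info("%s: rejected %d/%d segments", recording.patient_id, n_rej, len(segments))
    if not ok:
        raise ValueError(f"all segments of {recording.patient_id} were rejected")
    return extract_features(ok, mode="full")


def build_cohort_table(
    n_patients: int,
    hours_per_patient: float,
    sampling_rate: float = 256.0,
    seed: int = 0,
    artifact_rate: float = 0.0,
    **cohort_kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a cohort and return (feature table, manifest).

    The feature table holds all 17 families per analysis channel plus the
    (patient_id, start, label) keys; the manifest carries each patient's
    stratum for split stratification.
    """
    tables = []
    profiles = []
    for profile, recording in iter_cohort(
        n_patients, hours_per_patient, sampling_rate, seed, **cohort_kwargs
    ):
        if artifact_rate > 0:
            recording = inject_artifacts(recording, artifact_rate, seed=profile.seed + 1)
        tables.append(recording_features(recording))
        profiles.append(profile)
    table = pd.concat(tables, ignore_index=True)
    logger.info(
        "cohort table: %d rows (%d ictal), %d columns",
        len(table),
        int(table["label"].sum()),
        table.shape[1],
    )
    return table, cohort_manifest(profiles)
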