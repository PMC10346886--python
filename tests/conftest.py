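import numpy as np
import pytest

from eegselect.features import PSD, extract_features
from eegselect.preprocess import accepted, preprocess_recording
from eegselect.synthetic import generate_cohort

FS = 128.0  # unit-test sampling rate: keeps fixtures fast, 0.5 Hz PSD grid


@pytest.fixture(scope="session")
def cohort():
    """Small cohort: 4 patients, 15 min each, left-lateralized so the
    (zone, hemisphere) strata stay large enough to stratify 4 patients."""
    return generate_cohort(4, 0.25, FS, seed=7, hemisphere_distribution={"left": 1.0})


@pytest.fixture(scope="session")
def recording(cohort):
    return cohort[0][1]


@pytest.fixture(scope="session")
def segments(recording):
    return preprocess_recording(recording)


@pytest.fixture(scope="session")
def feature_table(segments):
    return extract_features(accepted(segments), mode="full")


@pytest.fixture(scope="session")
def cohort_table(cohort):
    """Feature table + strata for the whole 4-patient cohort."""
    import pandas as pd

    tables = [
        extract_features(accepted(preprocess_recording(rec)), mode="full")
        for _, rec in cohort
    ]
    strata = {p.patient_id: (p.focus_zone, p.hemisphere) for p, _ in cohort}
    return pd.concat(tables, ignore_index=True), strata


def make_psd(power, f_lo=1.0, f_hi=50.0, df=0.5) -> PSD:
    """PSD on the standard analysis grid from an explicit power array."""
    freqs = np.arange(f_lo, f_hi + df / 2, df)
    power = np.asarray(power, float)
    assert power.shape[-1] == len(freqs)
    return PSD(freqs, power)


def flat_psd(value=1.0, **kw) -> PSD:
    freqs = np.arange(kw.get("f_lo", 1.0), kw.get("f_hi", 50.0) + 0.25, kw.get("df", 0.5))
    return PSD(freqs, np.full(len(freqs), float(value)))


def random_psds(n, seed=0):
    """Positive random spectra on the standard grid, roughly 1/f shaped."""
    rng = np.random.default_rng(seed)
    freqs = np.arange(1.0, 50.25, 0.5)
    out = []
    for _ in range(n):
        shape = freqs ** rng.uniform(-2.0, 0.0)
        noise = rng.lognormal(0.0, rng.uniform(0.2, 1.0), len(freqs))
        out.append(PSD(freqs, shape * noise * rng.uniform(0.5, 200.0)))
    return out
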