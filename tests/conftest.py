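import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

from gliospec.spectra_io import Spectrum, SpectraSet
from gliospec import synthetic_data as sd

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def lorentzian(axis, shift, amplitude, fwhm):
    gamma = fwhm / 2.0
    return amplitude * gamma**2 / ((axis - shift) ** 2 + gamma**2)


@pytest.fixture(scope="session")
def axis():
    return np.arange(400.0, 1701.0)


def make_set(spectra_values, labels, axis, patients=None):
    """Build a SpectraSet from a list of intensity vectors."""
    spectra, meta = [], []
    for i, (vals, label) in enumerate(zip(spectra_values, labels)):
        sid = f"sp{i:03d}"
        spectra.append(Spectrum(sid, axis, np.asarray(vals, dtype=float)))
        pid = patients[i] if patients is not None else f"p{i:03d}"
        meta.append(
            {"spectrum_id": sid, "sample_id": pid, "patient_id": pid,
             "label": label}
        )
    return SpectraSet(spectra=spectra, meta=pd.DataFrame(meta))


@pytest.fixture(scope="session")
def small_cohort():
    """Fast synthetic cohort: 8 tumor + 6 healthy patients, ~8 spectra each."""
    cfg = sd.SimConfig(
        n_tumor_samples=8,
        n_healthy_samples=6,
        spectra_per_sample=(7, 9),
        spike_prob=0.0,
        seed=7,
    )
    return sd.generate_cohort(cfg)


@pytest.fixture(scope="session")
def toy_set(axis):
    """Three labelled noiseless peak spectra on the default grid."""
    rng = np.random.default_rng(0)
    values = []
    for amp in (100.0, 120.0, 80.0):
        values.append(
            lorentzian(axis, 1003, amp, 10)
            + lorentzian(axis, 1440, 2 * amp, 12)
            + rng.normal(scale=1.0, size=len(axis))
        )
    return make_set(values, ["Tumor", "Tumor", "Healthy"], axis)
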