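import numpy as np
import pytest

from ecglead.signal_io import CANONICAL_LEADS, ECGRecord
from ecglead.synth import SyntheticPatientSpec, generate_dipole, project_leads


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_record(duration_s: float = 30.0, fs: float = 1000.0, seed: int = 0,
                nonlinearity: float = 0.0, noise_sd: float = 0.0,
                record_id: str = "rec0", patient_id: str = "pat0") -> ECGRecord:
    spec = SyntheticPatientSpec(patient_id=patient_id, seed=seed,
                                nonlinearity=nonlinearity, noise_sd=noise_sd,
                                fs=fs)
    gen = np.random.default_rng(seed)
    source = generate_dipole(spec, duration_s, gen)
    rec = project_leads(source, spec, gen, record_id=record_id)
    return rec


@pytest.fixture
def record():
    """A 30 s noiseless, linear 15-lead synthetic record at 1 kHz."""
    return make_record()


@pytest.fixture
def noisy_record():
    """A 30 s record with mild saturation and 10 µV noise."""
    return make_record(nonlinearity=0.5, noise_sd=0.01, seed=3,
                       record_id="rec_noisy")
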