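import numpy as np
import pytest

from qeegnorm.montage import ELECTRODES_1020, MonopolarRecording
from qeegnorm.pipeline import analyze_recording
from qeegnorm.synthetic import SubjectSpec, generate_subject


def make_recording(samples, fs=512.0, age=None):
    return MonopolarRecording(ELECTRODES_1020, samples, fs, subject_age=age)


def sine_recording(freq, fs=512.0, duration=10.0, amplitude=1.0, age=None):
    """All 19 electrodes carry distinct-phase copies of one sinusoid."""
    t = np.arange(int(duration * fs)) / fs
    phases = np.linspace(0, np.pi, 19)
    samples = amplitude * np.sin(2 * np.pi * freq * t[None, :] + phases[:, None])
    return make_recording(samples, fs, age)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def noise_recording():
    """20 s of independent white noise on every electrode."""
    g = np.random.default_rng(7)
    return make_recording(10.0 * g.standard_normal((19, 512 * 20)))


@pytest.fixture(scope="session")
def synth_subject():
    """One default synthetic subject (60 s) with its ground truth."""
    return generate_subject(SubjectSpec(age=35.0, seed=42), duration=60.0)


@pytest.fixture(scope="session")
def synth_features(synth_subject):
    rec, _ = synth_subject
    return analyze_recording(rec)
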