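import numpy as np
import pytest

import eegmicrostates as ms


@pytest.fixture(scope="session")
def montage():
    return ms.make_montage(30)


@pytest.fixture(scope="session")
def templates(montage):
    return ms.make_templates(5, montage, seed=1)


@pytest.fixture(scope="session")
def study_templates(montage):
    return ms.make_study_templates(montage, seed=7)


@pytest.fixture(scope="session")
def noiseless_recording(montage, templates):
    """10 s noiseless recording with its ground-truth label sequence."""
    cfg = ms.GeneratorConfig(duration_s=10.0, noise_sd=0.0, seed=4)
    rec, seq = ms.simulate_recording(cfg, templates, montage=montage)
    return rec, seq


@pytest.fixture(scope="session")
def noisy_recording(montage, templates):
    """60 s recording at the default noise level, band-filtered."""
    cfg = ms.GeneratorConfig(duration_s=60.0, seed=9)
    rec, seq = ms.simulate_recording(cfg, templates, montage=montage)
    filtered = ms.average_reference(ms.bandpass(rec, 2.0, 20.0))
    return filtered, seq


def make_segmentation(label_str, sfreq=500.0, class_names=("A", "B", "C", "D", "E"),
                      splices=()):
    """Segmentation from a compact string like 'AAABB'; '.' = unassigned."""
    mapping = {name: i for i, name in enumerate(class_names)}
    mapping["."] = ms.UNASSIGNED
    labels = np.array([mapping[ch] for ch in label_str], dtype=int)
    return ms.Segmentation(labels=labels, sfreq=sfreq,
                           class_names=list(class_names),
                           splice_boundaries=list(splices))
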