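import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_phantom_set():
    """A small preprocessed phantom dataset shared by pipeline tests."""
    import warnings

    from gao_kneegrade.evaluation import ExperimentConfig, preprocess_sample
    from gao_kneegrade.phantoms import generate_dataset

    samples, manifest = generate_dataset(12, 12, {1: 3, 2: 3, 3: 3, 4: 3}, seed=123)
    config = ExperimentConfig(seed=123)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pre = [preprocess_sample(s, config) for s in samples]
    return {
        "samples": samples,
        "manifest": manifest,
        "images": np.stack([p[0] for p in pre]),
        "mfms": np.stack([p[1] for p in pre]),
        "fvecs": np.stack([p[2] for p in pre]),
        "seg_acc": np.array([p[3] for p in pre]),
        "labels": np.array([0 if s.label == "normal" else 1 for s in samples]),
        "grades": np.array([s.grade for s in samples]),
    }
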