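import numpy as np
import pytest

import decoyfeat as df


@pytest.fixture(scope="session")
def clean_ensemble():
    """Noise-free 40-residue ensemble with planted 2-mode ground truth."""
    spec = df.SyntheticSpec(
        n_residues=40, n_decoys=300, n_modes=2, noise_sigma=0.0, seed=5
    )
    return df.sample_ensemble(spec)


@pytest.fixture(scope="session")
def noisy_dataset():
    """Centralized + split dataset from a noisy 60-residue ensemble."""
    spec = df.SyntheticSpec(
        n_residues=60, n_decoys=800, n_modes=2, noise_sigma=0.2, seed=11
    )
    ensemble, gt = df.sample_ensemble(spec)
    dataset = df.split_dataset(df.centralize(ensemble), seed=11)
    return dataset, ensemble, gt


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
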