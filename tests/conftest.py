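import numpy as np
import pytest

from ramanomics.synthetic_data import GeneratorConfig, generate_cohort
from ramanomics.preprocess import preprocess_batch


@pytest.fixture(scope="session")
def small_cohort():
    """20 samples x 5 replicates with a planted tyrosine elevation."""
    cfg = GeneratorConfig(n_samples=20, replicates_per_sample=5,
                          effect_sizes={"tyrosine": 1.0}, seed=42)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def processed_small(small_cohort):
    spectra, manifest, truth = small_cohort
    return preprocess_batch(spectra), manifest, truth


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Artifact-free spectra: pure band sums, known amplitudes."""
    cfg = GeneratorConfig(n_samples=6, replicates_per_sample=2, noise_sd=0.0,
                          baseline_magnitude=0.0, spike_rate=0.0, seed=7)
    return generate_cohort(cfg)


def separable_scores(n_samples=60, replicates=3, n_features=20, shift=5.0,
                     n_signal=3, seed=0):
    """Linearly separable sample-replicate score data for classifier checks.

    The class mean shift lies along the first ``n_signal`` features, as a
    genuine spectral group difference projects onto several leading PCs.
    """
    rng = np.random.default_rng(seed)
    labels, rows, y, groups = [], [], [], []
    for i in range(n_samples):
        lab = "pregnancy" if i % 2 == 0 else "non_pregnancy"
        mu = np.zeros(n_features)
        if lab == "non_pregnancy":
            mu[:n_signal] = shift
        base = rng.normal(mu, 1.0)
        for _ in range(replicates):
            rows.append(base + rng.normal(0.0, 0.3, n_features))
            y.append(lab)
            groups.append(f"S{i:03d}")
    return np.array(rows), np.array(y, dtype=object), np.array(groups)
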