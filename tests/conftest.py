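import numpy as np
import pytest

import radbpe as rb


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Deterministic phantom with no noise and no BPE heterogeneity: every
    compartment's time course is exactly its spec'd kinetics."""
    spec = rb.PhantomSpec(seed=11, noise_sd=0.0, bpe_variance=0.0)
    volume, masks, truth = rb.generate_dce_phantom(spec)
    return spec, volume, masks, truth


@pytest.fixture(scope="session")
def noisy_phantom():
    """Default-condition phantom (noise sd 5, non-TN heterogeneity preset)."""
    spec = rb.PhantomSpec(seed=23)
    volume, masks, truth = rb.generate_dce_phantom(spec)
    return spec, volume, masks, truth


@pytest.fixture(scope="session")
def study_table():
    """Synthetic analog of the study feature table: 88 lesions, 11 TN,
    class effect concentrated in the BPE texture block."""
    return rb.generate_feature_table(rb.FeatureTableSpec(seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
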