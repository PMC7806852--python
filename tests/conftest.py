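import numpy as np
import pytest

from xmosaic import (
    ClusterMixModel,
    SampleProfile,
    build_probe_map,
    simulate_sample,
)

# c_ref = 1.5 at an even sex mix: the raw hemizygous offset is log2(1/1.5)
RAW_MALE_OFFSET = np.log2(1.0 / 1.5)


@pytest.fixture(scope="session")
def probes():
    """Mid-density probe map shared across tests: 1500 X probes + 40 Y probes."""
    return build_probe_map(1500, n_y_probes=40, seed=42)


@pytest.fixture(scope="session")
def dense_probes():
    """Denser map for segmentation/XXY tests."""
    return build_probe_map(4000, n_y_probes=60, seed=43)


@pytest.fixture
def mix():
    return ClusterMixModel()


def make_sample(probes, karyotype="XY_NORMAL", seed=0, noise=0.2, baf_noise=0.03, **kwargs):
    prof = SampleProfile(f"{karyotype}_{seed}", karyotype, lrr_noise_sd=noise, **kwargs)
    return simulate_sample(prof, probes, seed=seed, baf_noise_sd=baf_noise)


@pytest.fixture
def noise_free_normal(probes):
    return make_sample(probes, seed=1, noise=0.0, baf_noise=0.0)
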