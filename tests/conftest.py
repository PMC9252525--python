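import numpy as np
import pytest

from bnmscca.synthetic import generate_groups, generate_multiview


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_groups():
    return generate_groups(20, 4)


@pytest.fixture
def small_data(small_groups):
    """Moderate-signal multi-view dataset with one active network."""
    return generate_multiview(
        120, 20, 20, small_groups, latent_corr=0.6, seed=1, K=4, n_active=1
    )


@pytest.fixture
def feature_csv(tmp_path):
    path = tmp_path / "features.csv"
    path.write_text(
        "subject_id,PUT.L,HIP.L\n"
        "s1,0.1,1.5\n"
        "s2,0.4,-0.2\n"
        "s3,0.9,0.3\n"
    )
    return path
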