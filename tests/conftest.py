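import numpy as np
import pytest

import mlsemfit as m


@pytest.fixture
def uni_data():
    """Univariate two-cluster example: clusters {0, 2} and {4, 6}."""
    return m.TwoLevelDataset(
        values=np.array([[0.0], [2.0], [4.0], [6.0]]),
        cluster_id=np.array([1, 1, 2, 2]),
        variable_names=["y"],
    )


@pytest.fixture
def uni_stats(uni_data):
    return m.compute_sufficient_stats(uni_data)


@pytest.fixture
def uni_sat_spec():
    return m.parse_model("variables: [y]\nwithin: saturated\nbetween: saturated")


@pytest.fixture(scope="session")
def timss_spec():
    return m.timss_like_spec()


def random_two_level_dataset(rng, J=6, p=2, sizes=None):
    """Small arbitrary clustered dataset for property tests."""
    if sizes is None:
        sizes = rng.integers(1, 6, size=J)
    sizes = np.asarray(sizes)
    N = int(sizes.sum())
    values = rng.normal(size=(N, p)) + np.repeat(rng.normal(size=(J, p)), sizes, axis=0)
    cluster = np.repeat(np.arange(J), sizes)
    return m.TwoLevelDataset(values, cluster, [f"v{i}" for i in range(p)])
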