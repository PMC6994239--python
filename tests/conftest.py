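import numpy as np
import pandas as pd
import pytest

from crawlnet.synthetic import GeneratorSpec, synth_connectome


@pytest.fixture(scope="session")
def connectome_default():
    """The packaged-default synthetic connectome (40 PMN pairs, 16 MN pairs)."""
    return synth_connectome(GeneratorSpec(seed=0))


@pytest.fixture(scope="session")
def toy_connectome():
    """A small, densely coupled connectome for model unit tests."""
    return synth_connectome(
        GeneratorSpec(seed=3, n_pmn_pairs=5, n_mn_pairs=3, mean_mn_targets=2.0,
                      pmn_pmn_density=0.3)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def cloud(points, weights=None, neuron_id="n", polarity="post"):
    """Build a synapse table from an (n, 3) coordinate array."""
    points = np.asarray(points, dtype=float)
    n = len(points)
    return pd.DataFrame(
        {
            "neuron_id": neuron_id,
            "x_um": points[:, 0],
            "y_um": points[:, 1],
            "z_um": points[:, 2],
            "polarity": polarity,
            "polyadic_weight": np.ones(n, dtype=int) if weights is None else weights,
        }
    )
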