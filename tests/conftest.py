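import numpy as np
import pandas as pd
import pytest

import immunesig as im


@pytest.fixture(scope="session")
def small_study():
    """Two datasets, three conserved modules, mild noise; shared truth."""
    mats, truth = im.simulate_datasets(
        n_datasets=2,
        n_samples=80,
        n_conserved=3,
        n_private=1,
        module_size=15,
        n_background=80,
        noise_sd=0.4,
        seed=11,
    )
    ann = im.simulate_annotation(truth, seed=11)
    return mats, truth, ann


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_matrix(rng, n_feat=10, n_samp=10, prefix="g"):
    df = pd.DataFrame(
        rng.normal(8, 1, size=(n_feat, n_samp)),
        index=[f"{prefix}{i}" for i in range(n_feat)],
        columns=[f"s{j}" for j in range(n_samp)],
    )
    return im.ExpressionMatrix(df, "toy")
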