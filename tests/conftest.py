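import numpy as np
import pytest

from spongenet.io_formats import CountMatrix, ExpressionMatrix
from spongenet.synthetic import SimConfig, generate


def small_config(seed: int = 0, **overrides) -> SimConfig:
    """A fast, fully featured study configuration for unit tests."""
    params = dict(
        n_coding=40, n_lnc=24, n_mirna=30, n_per_group=3,
        n_de_lnc=10, n_de_mrna=12, n_de_mirna=8,
        n_triads_forward=2, n_triads_reverse=2, seed=seed,
    )
    params.update(overrides)
    return SimConfig(**params)


@pytest.fixture(scope="session")
def dataset():
    """One shared synthetic study (seed 0, no decoy background)."""
    return generate(small_config(seed=0))


@pytest.fixture(scope="session")
def dataset_bg():
    """Synthetic study with 1% decoy interaction background."""
    return generate(small_config(seed=0), background_density=0.01)


def two_group_matrix(values, feature_ids=None, integral=False):
    """Build a 3-vs-3 matrix from a (features x 6) array."""
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    fids = feature_ids or [f"f{i}" for i in range(n)]
    sids = ["c1", "c2", "c3", "t1", "t2", "t3"]
    groups = {s: ("control" if s.startswith("c") else "C+T") for s in sids}
    cls = CountMatrix if integral else ExpressionMatrix
    return cls(fids, sids, values, groups)
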