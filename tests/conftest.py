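import numpy as np
import pytest

from bloodmark.datatypes import ExpressionDataset, SampleInfo


@pytest.fixture
def tiny_dataset() -> ExpressionDataset:
    return ExpressionDataset(
        np.array([[1.0, 2.0], [3.5, 4.25], [-0.5, 6.0]]),
        ["p1", "p2", "p3"],
        ["s1", "s2"],
        dataset_label="toy",
    )


def make_two_group(seed: int, G: int = 200, n1: int = 30, n0: int = 30, delta: float = 0.0):
    """Simple two-group dataset: baseline 8, optional shift on the first
    quarter of features, unit-free Gaussian noise with sd 0.3."""
    rng = np.random.default_rng(seed)
    n = n1 + n0
    grp = np.r_[np.ones(n1), np.zeros(n0)]
    age = rng.normal(75, 7, n)
    fem = rng.integers(0, 2, n).astype(float)
    eff = np.zeros(G)
    eff[: G // 4] = delta
    Y = 8 + eff[:, None] * grp[None, :] + rng.normal(0, 0.3, (G, n))
    ds = ExpressionDataset(Y, [f"g{i:04d}" for i in range(G)], [f"s{i:03d}" for i in range(n)])
    info = [
        SampleInfo(f"s{i:03d}", "AD" if grp[i] else "CTL", float(age[i]), "F" if fem[i] else "M")
        for i in range(n)
    ]
    return ds, info


@pytest.fixture
def two_group():
    return make_two_group(seed=0)
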