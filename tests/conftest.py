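import numpy as np
import pytest

import txanomaly as tx


@pytest.fixture(scope="session")
def small_spec():
    return tx.SyntheticSpec(
        p=300, n_normal=150, n_anomaly=50, d=5, seed=7, delta=10.0
    )


@pytest.fixture(scope="session")
def small_study(small_spec):
    return tx.simulate(small_spec, n_test_normal=120)


@pytest.fixture(scope="session")
def small_model(small_study):
    return tx.fit_detector(small_study["train"], log=True, k=5)


@pytest.fixture
def tiny_matrix():
    return tx.ExpressionMatrix(
        gene_ids=["G1", "G2", "G3"],
        sample_ids=["s1", "s2"],
        values=np.array([[1.0, 2.0], [3.5, 0.0], [4.0, 5.25]]),
        labels={"s1": "normal", "s2": "cancer"},
    )


def make_gaussian_matrix(p, n, rng, prefix="s"):
    """I.i.d. standard-normal 'expression' for calibration checks (the
    non-negativity check is relaxed: this is already on the analysis scale)."""
    return tx.ExpressionMatrix(
        gene_ids=[f"G{i}" for i in range(p)],
        sample_ids=[f"{prefix}{j}" for j in range(n)],
        values=rng.standard_normal((p, n)),
        non_negative=False,
    )
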