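import numpy as np
import pandas as pd
import pytest

from mirlasso.io import ClinicalTable, ExpressionMatrix, MIRNA, MRNA


def make_expr(values, sample_ids=None, feature_ids=None, classes=None):
    """Small helper to build an ExpressionMatrix from a nested list."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    sample_ids = sample_ids or [f"s{i}" for i in range(n)]
    feature_ids = feature_ids or [f"f{j}" for j in range(m)]
    classes = classes or [MRNA] * m
    return ExpressionMatrix(
        pd.DataFrame(values, index=sample_ids, columns=feature_ids),
        pd.Series(classes, index=feature_ids),
    )


def random_correlation(rng, m, n=100):
    """Empirical correlation matrix of an n x m random-design Gaussian sample."""
    A = rng.standard_normal((m, m))
    X = rng.standard_normal((n, m)) @ A
    Xc = X - X.mean(0)
    S = Xc.T @ Xc / n
    d = np.sqrt(np.diag(S))
    S = S / np.outer(d, d)
    np.fill_diagonal(S, 1.0)
    return S


@pytest.fixture
def tiny_expr():
    return make_expr([[5, 0], [2, 7], [1, 1]], feature_ids=["g1", "g2"])


@pytest.fixture
def clinical_mixed():
    df = pd.DataFrame(
        {
            "survival_days": [100.0, 400.0, 365.0, np.nan],
            "er_status": ["positive", "negative", np.nan, "positive"],
            "stage": ["I", "III", "II", "IV"],
        },
        index=pd.Index(["s1", "s2", "s3", "s4"]),
    )
    return ClinicalTable(df)
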