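import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from stressnet.containers import ExpressionMatrix, SampleTable
from stressnet import ggm


def make_covariance_set(p=20, K=2, n=100, seed=0, conditions=None):
    """Correlation matrices from random Gaussian data (null structure)."""
    rng = np.random.default_rng(seed)
    conditions = conditions or [f"c{k}" for k in range(K)]
    S = {c: np.corrcoef(rng.normal(size=(p, n))) for c in conditions}
    return ggm.CovarianceSet(
        S=S,
        n={c: n for c in conditions},
        gene_ids=[f"g{i}" for i in range(p)],
        conditions=conditions,
    )


def latent_expression(truth, n_per_condition, seed=0):
    """Standardized latent MVN draws from a GroundTruth (no count noise)."""
    rng = np.random.default_rng(seed)
    p = truth.p
    cols, data, cond = [], [], []
    for name, n_k in zip(truth.condition_names, n_per_condition):
        sigma = np.linalg.inv(truth.precision_set[name])
        z = rng.multivariate_normal(np.zeros(p), sigma, size=n_k).T
        data.append(z)
        cols += [f"{name}_s{i}" for i in range(n_k)]
        cond += [name] * n_k
    X = np.hstack(data)
    X = (X - X.mean(1, keepdims=True)) / X.std(1, ddof=0, keepdims=True)
    expr = ExpressionMatrix(
        pd.DataFrame(X, index=[f"g{i+1}" for i in range(p)], columns=cols),
        "standardized",
    )
    samples = SampleTable(
        pd.DataFrame({"sample": cols, "condition": cond, "batch": "b1"})
    )
    return expr, samples


@pytest.fixture
def covs_pair():
    return make_covariance_set(p=12, K=2, n=80, seed=1)
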