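import numpy as np
import pytest
from scipy.stats import multivariate_normal

from outclust.data import (
    ExpressionMatrix,
    ModelParams,
    OutcomeVector,
    Partition,
)


def make_instance(rng, N=6, J=8, K=3, centered=True, tau=0.9):
    """Random centered expression matrix, outcome, params, partition."""
    Yv = rng.normal(size=(N, J))
    if centered:
        Yv = Yv - Yv.mean(axis=0)
    Y = ExpressionMatrix(
        Yv,
        [f"s{i}" for i in range(N)],
        [f"g{j}" for j in range(J)],
        centered=centered,
    )
    Z = OutcomeVector(rng.normal(size=N))
    partition = Partition(rng.integers(0, K, J), K)
    omega = rng.uniform(0.5, 1.5, K)
    params = ModelParams(
        sigma=float(rng.uniform(0.6, 1.5)),
        tau=tau,
        gamma=float(rng.uniform(0.6, 1.5)),
        beta=rng.normal(0, 2, K),
        omega=omega / omega.sum(),
    )
    return Y, Z, params, partition


def dense_joint_logpdf(Y, Z, cov):
    """Dense multivariate-normal oracle for the joint (Y, Z) density."""
    X = np.column_stack([Y.values, Z.z])
    return float(
        multivariate_normal(mean=np.zeros(cov.shape[0]), cov=cov).logpdf(X).sum()
    )


def dense_expression_logpdf(Y, cov_y):
    return float(
        multivariate_normal(mean=np.zeros(cov_y.shape[0]), cov=cov_y)
        .logpdf(Y.values)
        .sum()
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
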