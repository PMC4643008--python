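"""Closed-form outcome prediction from a new expression profile.

Because (Y_i, Z_i) is jointly Gaussian, the conditional of the outcome
given the expression profile is Gaussian with

    E[Z | y]   = tau^2 * sum_k beta_k / (sigma^2 + n_k tau^2) * sum_{j in S_k} y_j
    Var[Z | y] = tau^2 sigma^2 * sum_k beta_k^2 / (sigma^2 + n_k tau^2) + gamma^2

(y centered with the *training* column means). The variance does not
depend on y. Empty clusters (n_k = 0) contribute tau^2 beta_k^2 to the
variance and nothing to the mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import DataValidationError, ModelParams, Partition
from .sampler import ChainResult
from .summaries import modal_partition


@dataclass(frozen=True)
class PredictiveDistribution:
    """Gaussian predictive law of one sample's outcome."""

    mean: float
    variance: float

    def __post_init__(self):
        if not (np.isfinite(self.mean) and np.isfinite(self.variance)):
            raise DataValidationError("non-finite predictive moments")
        if self.variance <= 0:
            raise DataValidationError("predictive variance must be positive")

    @property
    def sd(self) -> float:
        return float(np.sqrt(self.variance))

    def interval(self, level: float = 0.95) -> tuple[float, float]:
        from scipy.stats import norm

        half = norm.ppf(0.5 + level / 2.0) * self.sd
        return (self.mean - half, self.mean + half)


def conditional_moments(
    y: np.ndarray, params: ModelParams, partition: Partition
) -> PredictiveDistribution:
    """Plug-in predictive mean and variance for one centered profile."""
    y = np.asarray(y, dtype=float).ravel()
    if y.shape[0] != partition.n_features:
        raise DataValidationError(
            f"profile has {y.shape[0]} features, partition {partition.n_features}"
        )
    s2, t2, g2 = params.sigma ** 2, params.tau ** 2, params.gamma ** 2
    n = partition.sizes()
    denom = s2 + n * t2
    cluster_sums = np.bincount(
        partition.assignment, weights=y, minlength=partition.k_max
    )
    mean = t2 * float(np.sum(params.beta / denom * cluster_sums))
    variance = t2 * s2 * float(np.sum(params.beta ** 2 / denom)) + g2
    return PredictiveDistribution(mean=mean, variance=variance)


def _moments_batch(
    Yc: np.ndarray, beta: np.ndarray, s2: float, t2: float, g2: float, labels: np.ndarray, K: int
) -> tuple[np.ndarray, float]:
    n = np.bincount(labels, minlength=K)
    denom = s2 + n * t2
    phi = np.zeros((labels.shape[0], K))
    phi[np.arange(labels.shape[0]), labels] = 1.0
    means = t2 * (Yc @ phi) @ (beta / denom)
    var = t2 * s2 * float(np.sum(beta ** 2 / denom)) + g2
    return means, var


def posterior_predict(
    y_new: np.ndarray,
    chain: ChainResult,
    column_means: np.ndarray,
    mode: str = "average",
) -> list[PredictiveDistribution]:
    """Predict outcomes for M new samples from a fitted chain.

    mode="average" (default): evaluates the conditional moments at every
    post-burn-in draw and combines them by the law of total variance
    (mean of means; mean of variances plus variance of means).

    mode="plugin": evaluates the closed form once at the posterior-mean
    parameters and the modal partition, reproducing the plug-in formulas
    exactly.
    """
    if chain.beta is None:
        raise DataValidationError("chain was fit without an outcome; cannot predict")
    Y = np.atleast_2d(np.asarray(y_new, dtype=float))
    J = chain.assignments.shape[1]
    if Y.shape[1] != J:
        raise DataValidationError(
            f"new samples have {Y.shape[1]} features, training had {J}"
        )
    Yc = Y - np.asarray(column_means, dtype=float)[None, :]
    post = chain.post_burn()
    K = chain.k_max
    if mode == "plugin":
        part = modal_partition(post.assignments, K)
        means, var = _moments_batch(
            Yc,
            post.beta.mean(axis=0),
            float(post.sigma.mean()) ** 2,
            float(post.tau.mean()) ** 2,
            float(post.gamma.mean()) ** 2,
            part.assignment,
            K,
        )
        return [PredictiveDistribution(float(m), var) for m in means]
    if mode != "average":
        raise ValueError(f"unknown mode {mode!r}")
    T = post.assignments.shape[0]
    M = Yc.shape[0]
    all_means = np.empty((T, M))
    all_vars = np.empty(T)
    for it in range(T):
        m, v = _moments_batch(
            Yc,
            post.beta[it],
            float(post.sigma[it]) ** 2,
            float(post.tau[it]) ** 2,
            float(post.gamma[it]) ** 2,
            post.assignments[it],
            K,
        )
        all_means[it] = m
        all_vars[it] = v
    mean = all_means.mean(axis=0)
    variance = all_vars.mean() + all_means.var(axis=0)
    return [
        PredictiveDistribution(float(m), float(v)) for m, v in zip(mean, variance)
    ]
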