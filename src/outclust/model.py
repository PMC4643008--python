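"""Marginalized joint likelihood of expression and outcome.

Per sample i the observation vector X_i = (Y_i1..Y_iJ, Z_i) is multivariate
normal once the latent cluster effects are integrated out. Writing the
J x K membership indicator as Phi and A = [[Phi], [beta^T]], the joint
covariance is

    Sigma = D + tau^2 * A A^T,   D = diag(sigma^2, ..., sigma^2, gamma^2),

i.e. diagonal plus rank-K. The Woodbury identity reduces the inverse to a
K x K "capacity" matrix M = diag(1/tau^2 + n_k/sigma^2) + (beta/gamma)
(beta/gamma)^T — itself diagonal plus rank one, so Sherman–Morrison and
the matrix-determinant lemma give a fully closed form. Evaluation costs
O(N*K) given the cached cluster sums T[i,k] = sum_{j in S_k} Y_ij; the
dense (J+1)x(J+1) matrix is never formed.
"""

from __future__ import annotations

import numpy as np

from .data import (
    DataValidationError,
    ExpressionMatrix,
    ModelParams,
    OutcomeVector,
    Partition,
    SufficientStats,
)

_LOG2PI = float(np.log(2.0 * np.pi))


def _check_variances(sigma2: float, tau2: float, gamma2: float | None = None):
    if sigma2 <= 0 or tau2 <= 0 or (gamma2 is not None and gamma2 <= 0):
        raise DataValidationError(
            f"variance components must be positive: sigma2={sigma2}, "
            f"tau2={tau2}, gamma2={gamma2}"
        )


def build_joint_covariance(params: ModelParams, partition: Partition) -> np.ndarray:
    """Dense (J+1) x (J+1) covariance of (Y_i, Z_i) for one sample.

    Entry (u, v) for features u, v is sigma^2*1(u=v) + tau^2*1(same
    cluster); the last row/column couples each feature to the outcome via
    tau^2 * beta_{k(u)}, and the outcome variance is
    tau^2 * sum_k beta_k^2 + gamma^2. Used as the reference ("oracle")
    construction; inference relies on the closed form instead.
    """
    s2, t2, g2 = params.sigma ** 2, params.tau ** 2, params.gamma ** 2
    phi = partition.indicator()
    J = partition.n_features
    cov = np.empty((J + 1, J + 1))
    cov[:J, :J] = t2 * (phi @ phi.T)
    cov[:J, :J] += s2 * np.eye(J)
    beta_per_feature = params.beta[partition.assignment]
    cov[:J, J] = t2 * beta_per_feature
    cov[J, :J] = cov[:J, J]
    cov[J, J] = t2 * float(params.beta @ params.beta) + g2
    return cov


def _loglik_joint_stats(
    n: np.ndarray,
    T: np.ndarray,
    sq_total: float,
    z: np.ndarray,
    J: int,
    sigma2: float,
    tau2: float,
    gamma2: float,
    beta: np.ndarray,
) -> float:
    """Closed-form sum over samples of the joint (Y_i, Z_i) log-density."""
    N = T.shape[0]
    d = 1.0 / tau2 + n / sigma2  # K capacity diagonal
    K = d.shape[0]
    c = (beta * beta / (gamma2 * d)).sum()
    logdet = (
        J * np.log(sigma2)
        + np.log(gamma2)
        + K * np.log(tau2)
        + np.log(d).sum()
        + np.log1p(c)
    )
    # w_ik = T_ik/sigma2 + z_i*beta_k/gamma2 ; quadratic via Sherman-Morrison
    W = T / sigma2 + z[:, None] * (beta / gamma2)
    S2_over_d = ((W * W).sum(axis=0) / d).sum()
    h = W @ (beta / d)  # length N
    rank1 = (h @ h) / (gamma2 * (1.0 + c))
    quad = sq_total / sigma2 + (z @ z) / gamma2 - (S2_over_d - rank1)
    return float(-0.5 * (N * (J + 1) * _LOG2PI + N * logdet + quad))


def _loglik_expression_stats(
    n: np.ndarray,
    T: np.ndarray,
    sq_total: float,
    J: int,
    sigma2: float,
    tau2: float,
) -> float:
    """Closed-form log-density of Y alone (block compound symmetry)."""
    N = T.shape[0]
    d = 1.0 / tau2 + n / sigma2
    K = d.shape[0]
    logdet = J * np.log(sigma2) + K * np.log(tau2) + np.log(d).sum()
    quad = sq_total / sigma2 - ((T * T).sum(axis=0) / d).sum() / sigma2 ** 2
    return float(-0.5 * (N * J * _LOG2PI + N * logdet + quad))


def _require_centered(Y: ExpressionMatrix):
    if not Y.centered:
        raise DataValidationError(
            "expression matrix must be column-centered before likelihood "
            "evaluation (apply center_columns)"
        )


def log_joint_density(
    Y: ExpressionMatrix,
    Z: OutcomeVector,
    params: ModelParams,
    partition: Partition,
) -> float:
    """Marginal log-likelihood of (Y, Z) under the joint cluster model."""
    _require_centered(Y)
    if len(Z) != Y.n_samples:
        raise DataValidationError(
            f"outcome length {len(Z)} != {Y.n_samples} samples"
        )
    _check_variances(params.sigma ** 2, params.tau ** 2, params.gamma ** 2)
    stats = SufficientStats.from_data(Y, partition)
    return _loglik_joint_stats(
        stats.n,
        stats.T,
        stats.sq_total,
        Z.z,
        Y.n_features,
        params.sigma ** 2,
        params.tau ** 2,
        params.gamma ** 2,
        params.beta,
    )


def log_density_expression_only(
    Y: ExpressionMatrix, params: ModelParams, partition: Partition
) -> float:
    """Marginal log-likelihood of Y alone (outcome omitted).

    beta and gamma do not enter Y's marginal, so the result is invariant
    to them.
    """
    _require_centered(Y)
    _check_variances(params.sigma ** 2, params.tau ** 2)
    stats = SufficientStats.from_data(Y, partition)
    return _loglik_expression_stats(
        stats.n,
        stats.T,
        stats.sq_total,
        Y.n_features,
        params.sigma ** 2,
        params.tau ** 2,
    )


def move_delta(
    stats: SufficientStats,
    params: ModelParams,
    Y: ExpressionMatrix,
    j: int,
    k_from: int,
    k_to: int,
    z: np.ndarray | None = None,
) -> float:
    """Log-likelihood change from moving feature j between clusters.

    Computed as the difference of two closed-form evaluations on the
    cached sufficient statistics, so it matches a pair of full
    evaluations exactly. Pass ``z`` for the joint model; omit it for the
    expression-only model. ``stats`` is left unchanged.
    """
    K = stats.n.shape[0]
    if not (0 <= k_from < K and 0 <= k_to < K):
        raise IndexError(f"cluster labels must lie in [0, {K})")
    if not (0 <= j < Y.n_features):
        raise IndexError(f"feature index {j} out of range")
    if k_to == k_from:
        return 0.0
    s2, t2 = params.sigma ** 2, params.tau ** 2
    J = Y.n_features
    y_col = Y.values[:, j]
    moved = stats.copy()
    moved.move(y_col, k_from, k_to)
    if z is None:
        before = _loglik_expression_stats(stats.n, stats.T, stats.sq_total, J, s2, t2)
        after = _loglik_expression_stats(moved.n, moved.T, moved.sq_total, J, s2, t2)
    else:
        g2, beta = params.gamma ** 2, params.beta
        before = _loglik_joint_stats(
            stats.n, stats.T, stats.sq_total, z, J, s2, t2, g2, beta
        )
        after = _loglik_joint_stats(
            moved.n, moved.T, moved.sq_total, z, J, s2, t2, g2, beta
        )
    return after - before
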