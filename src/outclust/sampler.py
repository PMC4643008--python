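"""Four-step MCMC sampler for the joint clustering model.

Each sweep: (1) Metropolis–Hastings updates of the variance components
sigma^2, tau^2 (and gamma^2 when the outcome is modelled) with an
inverse-gamma proposal centred at the current value; (2) a multinomial
Gibbs reassignment of every feature, weighted by omega_k times the
marginal likelihood of placing the feature in cluster k, with
random-walk MH updates of the affected beta_k after every accepted
membership change and of all beta after the sweep; (3) a Dirichlet draw
of the weights omega from their conjugate conditional.

Priors: sigma, tau, gamma uniform on (0, A); each beta_k uniform on
[-B, B]; omega symmetric Dirichlet(alpha); memberships multinomial(omega).
The uniform-on-SD prior contributes a v^{-1/2} density on the variance
scale, included in the MH ratio.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .data import (
    ConfigError,
    ExpressionMatrix,
    ModelParams,
    OutcomeVector,
    Partition,
    SufficientStats,
    center_columns,
)
from .model import _loglik_expression_stats, _loglik_joint_stats

logger = logging.getLogger(__name__)

_VARIANCE_FLOOR = 1e-10  # proposals below this are rejected outright


@dataclass(frozen=True)
class PriorConfig:
    """Bounds of the flat priors: SDs on (0, A), betas on [-B, B],
    symmetric Dirichlet(alpha) on the weights."""

    A: float = 100.0
    B: float = 1000.0
    alpha: float = 1.0

    def __post_init__(self):
        if self.A <= 0 or self.B <= 0 or self.alpha <= 0:
            raise ConfigError("A, B and alpha must all be positive")


@dataclass(frozen=True)
class ProposalConfig:
    """s: inverse-gamma proposal shape for the variance components
    (scale s*current, so the proposal mean sits near the current value);
    beta_step: SD of the Gaussian random walk on each beta_k."""

    s: float = 50.0
    beta_step: float = 0.25

    def __post_init__(self):
        if self.s <= 0 or self.beta_step <= 0:
            raise ConfigError("s and beta_step must be positive")


@dataclass(frozen=True)
class ChainConfig:
    k_max: int = 5
    iterations: int = 1000
    burn_in: int = 500
    seed: int = 0
    include_outcome: bool = True
    priors: PriorConfig = field(default_factory=PriorConfig)
    proposals: ProposalConfig = field(default_factory=ProposalConfig)

    def __post_init__(self):
        if self.iterations < 1:
            raise ConfigError("iterations must be >= 1")
        if not 0 <= self.burn_in < self.iterations:
            raise ConfigError(
                f"burn_in ({self.burn_in}) must satisfy 0 <= burn_in < "
                f"iterations ({self.iterations})"
            )
        if self.k_max < 1:
            raise ConfigError("k_max must be >= 1")


@dataclass
class ChainResult:
    """Per-sweep record of one chain. ``beta``/``gamma`` are None for
    expression-only fits."""

    assignments: np.ndarray  # iterations x J, int
    sigma: np.ndarray
    tau: np.ndarray
    gamma: np.ndarray | None
    beta: np.ndarray | None  # iterations x K
    omega: np.ndarray  # iterations x K
    loglik: np.ndarray
    acceptance_rates: dict[str, float]
    config: ChainConfig
    column_means: np.ndarray | None = None

    @property
    def k_max(self) -> int:
        return self.omega.shape[1]

    def post_burn(self) -> "ChainResult":
        """View of the stored draws with the burn-in discarded."""
        b = self.config.burn_in
        return dataclasses.replace(
            self,
            assignments=self.assignments[b:],
            sigma=self.sigma[b:],
            tau=self.tau[b:],
            gamma=None if self.gamma is None else self.gamma[b:],
            beta=None if self.beta is None else self.beta[b:],
            omega=self.omega[b:],
            loglik=self.loglik[b:],
            config=dataclasses.replace(self.config, burn_in=0),
        )


def mh_accept(
    log_post_candidate: float,
    log_post_current: float,
    log_q_forward: float,
    log_q_backward: float,
    rng: np.random.Generator,
) -> bool:
    """Metropolis–Hastings acceptance decision.

    Accepts with probability
    min(1, exp[(lp_cand - lq_fwd) - (lp_curr - lq_bwd)]), where the q
    terms correct for proposal asymmetry.
    """
    if log_post_candidate == -np.inf:
        return False
    log_ratio = (log_post_candidate - log_q_forward) - (
        log_post_current - log_q_backward
    )
    if log_ratio >= 0:
        return True
    return float(np.log(rng.uniform())) < log_ratio


class SamplerState:
    """Mutable state of one chain: data views, sufficient statistics,
    current parameters and the cached log-likelihood."""

    def __init__(
        self,
        Y: ExpressionMatrix,
        Z: OutcomeVector | None,
        config: ChainConfig,
        rng: np.random.Generator,
        labels: np.ndarray | None = None,
    ):
        self.Y = Y
        self.z = None if Z is None else Z.z
        self.config = config
        self.rng = rng
        K = config.k_max
        if labels is None:
            labels = rng.integers(0, K, Y.n_features)
        self.labels = np.asarray(labels, dtype=np.int64).copy()
        self.stats = SufficientStats.from_data(Y, Partition(self.labels, K))
        # moment-based, over-dispersed starts
        self.sigma2 = 0.5 * float(np.var(Y.values))
        self.tau2 = self.sigma2
        if config.include_outcome:
            self.gamma2 = 0.5 * float(np.var(self.z))
            self.beta = np.zeros(K)
        else:
            self.gamma2 = None
            self.beta = None
        self.omega = np.full(K, 1.0 / K)
        self.loglik = self._loglik_current()
        self.accept_counts = {
            "sigma2": [0, 0],
            "tau2": [0, 0],
            "gamma2": [0, 0],
            "beta": [0, 0],
        }

    # -- likelihood plumbing -------------------------------------------------

    def _loglik(self, n, T, sigma2=None, tau2=None, gamma2=None, beta=None):
        sigma2 = self.sigma2 if sigma2 is None else sigma2
        tau2 = self.tau2 if tau2 is None else tau2
        J = self.Y.n_features
        if self.config.include_outcome:
            gamma2 = self.gamma2 if gamma2 is None else gamma2
            beta = self.beta if beta is None else beta
            return _loglik_joint_stats(
                n, T, self.stats.sq_total, self.z, J, sigma2, tau2, gamma2, beta
            )
        return _loglik_expression_stats(n, T, self.stats.sq_total, J, sigma2, tau2)

    def _loglik_current(self) -> float:
        return self._loglik(self.stats.n, self.stats.T)

    def audit(self, atol: float = 1e-6):
        """Assert cached stats and log-likelihood match a recomputation."""
        self.stats.verify(self.Y, Partition(self.labels, self.config.k_max))
        fresh = self._loglik_current()
        if abs(fresh - self.loglik) > atol * max(1.0, abs(fresh)):
            raise RuntimeError(
                f"cached log-likelihood {self.loglik} drifted from {fresh}"
            )

    def params(self) -> ModelParams:
        K = self.config.k_max
        return ModelParams(
            sigma=float(np.sqrt(self.sigma2)),
            tau=float(np.sqrt(self.tau2)),
            gamma=1.0 if self.gamma2 is None else float(np.sqrt(self.gamma2)),
            beta=np.zeros(K) if self.beta is None else self.beta,
            omega=self.omega,
        )


# -- step 1: variance components ---------------------------------------------


def _invgamma_draw(shape: float, scale: float, rng: np.random.Generator) -> float:
    # X ~ InvGamma(a, scale=c)  <=>  1/X ~ Gamma(a, scale=1/c)
    return float(scale / rng.gamma(shape))


def _invgamma_logpdf(x: float, shape: float, scale: float) -> float:
    if x <= 0:
        return -np.inf
    return float(
        shape * np.log(scale)
        - gammaln(shape)
        - (shape + 1.0) * np.log(x)
        - scale / x
    )


def _log_prior_variance(v: float, A: float) -> float:
    # uniform prior on the SD scale: p(v) ∝ v^{-1/2} on (0, A^2)
    if v <= _VARIANCE_FLOOR or v >= A * A:
        return -np.inf
    return -0.5 * np.log(v)


def sample_variance_component(
    state: SamplerState, which: str, rng: np.random.Generator | None = None
) -> bool:
    """One MH update of sigma^2, tau^2 or gamma^2. Returns acceptance."""
    rng = state.rng if rng is None else rng
    if which not in ("sigma2", "tau2", "gamma2"):
        raise ValueError(f"unknown variance component {which!r}")
    if which == "gamma2" and not state.config.include_outcome:
        raise ValueError("gamma2 has no role in an expression-only fit")
    cur = getattr(state, which)
    s = state.config.proposals.s
    A = state.config.priors.A
    cand = _invgamma_draw(s, s * cur, rng)
    state.accept_counts[which][1] += 1
    lp_cand = _log_prior_variance(cand, A)
    if lp_cand == -np.inf:
        return False
    kw = {which: cand}
    ll_cand = state._loglik(state.stats.n, state.stats.T, **kw)
    lq_fwd = _invgamma_logpdf(cand, s, s * cur)
    lq_bwd = _invgamma_logpdf(cur, s, s * cand)
    accepted = mh_accept(
        ll_cand + lp_cand,
        state.loglik + _log_prior_variance(cur, A),
        lq_fwd,
        lq_bwd,
        rng,
    )
    if accepted:
        setattr(state, which, cand)
        state.loglik = ll_cand
        state.accept_counts[which][0] += 1
    return accepted


# -- step 2: membership and regression coefficients ---------------------------


def reassignment_logprobs(state: SamplerState, j: int) -> tuple[np.ndarray, np.ndarray]:
    """Log-probabilities of each label for feature j, and the
    corresponding candidate log-likelihoods.

    Probabilities are proportional to omega_k times the marginal
    likelihood with feature j in cluster k; all K are strictly positive,
    so empty clusters can fill and filled ones can empty.
    """
    K = state.config.k_max
    y_col = state.Y.values[:, j]
    cur = state.labels[j]
    n, T = state.stats.n, state.stats.T
    # remove the feature, then try each label
    n_base = n.copy()
    n_base[cur] -= 1
    T_base = T.copy()
    T_base[:, cur] -= y_col
    logliks = np.empty(K)
    for k in range(K):
        n_base[k] += 1
        T_base[:, k] += y_col
        logliks[k] = state._loglik(n_base, T_base)
        n_base[k] -= 1
        T_base[:, k] -= y_col
    logw = np.log(state.omega) + logliks
    m = logw.max()
    p = np.exp(logw - m)
    return logw - (m + np.log(p.sum())), logliks


def reassign_gene(
    state: SamplerState, j: int, rng: np.random.Generator | None = None
) -> bool:
    """Multinomial Gibbs update of feature j's label. Returns whether the
    label changed."""
    rng = state.rng if rng is None else rng
    logp, logliks = reassignment_logprobs(state, j)
    cum = np.cumsum(np.exp(logp))
    new = int(np.searchsorted(cum, rng.uniform() * cum[-1]))
    new = min(new, logp.shape[0] - 1)
    old = int(state.labels[j])
    state.loglik = float(logliks[new])
    if new == old:
        return False
    state.stats.move(state.Y.values[:, j], old, new)
    state.labels[j] = new
    return True


def sample_betas(
    state: SamplerState,
    rng: np.random.Generator | None = None,
    which: "set[int] | None" = None,
) -> int:
    """Random-walk MH updates of beta_k for the named clusters (all K if
    None). Returns the number of accepted moves."""
    if not state.config.include_outcome:
        raise ValueError("beta has no role in an expression-only fit")
    rng = state.rng if rng is None else rng
    B = state.config.priors.B
    step = state.config.proposals.beta_step
    ks = range(state.config.k_max) if which is None else sorted(which)
    n_accept = 0
    for k in ks:
        state.accept_counts["beta"][1] += 1
        cand_beta = state.beta.copy()
        cand_beta[k] += rng.normal(0.0, step)
        if abs(cand_beta[k]) > B:
            continue  # outside the flat prior's support
        ll_cand = state._loglik(state.stats.n, state.stats.T, beta=cand_beta)
        if mh_accept(ll_cand, state.loglik, 0.0, 0.0, rng):
            state.beta = cand_beta
            state.loglik = ll_cand
            state.accept_counts["beta"][0] += 1
            n_accept += 1
    return n_accept


# -- step 3: weights ----------------------------------------------------------


def sample_weights(
    state: SamplerState, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Conjugate Dirichlet(alpha + n_1, ..., alpha + n_K) draw of omega."""
    rng = state.rng if rng is None else rng
    alpha = state.config.priors.alpha
    w = rng.dirichlet(alpha + state.stats.n)
    # guard against numerical zeros (omega must stay strictly positive)
    w = np.clip(w, 1e-300, None)
    state.omega = w / w.sum()
    return state.omega


# -- the full chain -----------------------------------------------------------


def run_chain(
    Y: ExpressionMatrix,
    Z: OutcomeVector | None,
    config: ChainConfig,
    *,
    initial_labels: np.ndarray | None = None,
) -> ChainResult:
    """Run one MCMC chain and record every sweep.

    The partition is initialized uniformly at random (seeded) and the
    variance components at half the empirical variances. Deterministic
    given ``config.seed``.
    """
    if config.include_outcome:
        if Z is None:
            raise ConfigError("include_outcome=True requires an outcome vector")
        if len(Z) != Y.n_samples:
            raise ConfigError(
                f"outcome length {len(Z)} != {Y.n_samples} samples"
            )
    column_means = None
    if not Y.centered:
        logger.info("centering expression matrix columns before sampling")
        column_means = Y.column_means()
        Y = center_columns(Y)
    rng = np.random.default_rng(config.seed)
    state = SamplerState(Y, Z if config.include_outcome else None, config, rng,
                         labels=initial_labels)
    J, K, n_iter = Y.n_features, config.k_max, config.iterations
    out_assign = np.empty((n_iter, J), dtype=np.int64)
    out_sigma = np.empty(n_iter)
    out_tau = np.empty(n_iter)
    out_gamma = np.empty(n_iter) if config.include_outcome else None
    out_beta = np.empty((n_iter, K)) if config.include_outcome else None
    out_omega = np.empty((n_iter, K))
    out_loglik = np.empty(n_iter)

    for it in range(n_iter):
        sample_variance_component(state, "sigma2")
        sample_variance_component(state, "tau2")
        if config.include_outcome:
            sample_variance_component(state, "gamma2")
        for j in range(J):
            old = int(state.labels[j])
            changed = reassign_gene(state, j)
            if changed and config.include_outcome:
                sample_betas(state, which={old, int(state.labels[j])})
        if config.include_outcome:
            sample_betas(state)  # all K after the full sweep
        sample_weights(state)

        out_assign[it] = state.labels
        out_sigma[it] = np.sqrt(state.sigma2)
        out_tau[it] = np.sqrt(state.tau2)
        if config.include_outcome:
            out_gamma[it] = np.sqrt(state.gamma2)
            out_beta[it] = state.beta
        out_omega[it] = state.omega
        out_loglik[it] = state.loglik

        if (it + 1) % 100 == 0:
            state.audit()
            rates = {
                k: (v[0] / v[1] if v[1] else float("nan"))
                for k, v in state.accept_counts.items()
            }
            logger.debug(
                "sweep %d: loglik=%.3f acceptance=%s", it + 1, state.loglik, rates
            )

    rates = {
        k: (v[0] / v[1] if v[1] else float("nan"))
        for k, v in state.accept_counts.items()
    }
    return ChainResult(
        assignments=out_assign,
        sigma=out_sigma,
        tau=out_tau,
        gamma=out_gamma,
        beta=out_beta,
        omega=out_omega,
        loglik=out_loglik,
        acceptance_rates=rates,
        config=config,
        column_means=column_means,
    )


def run_multi_chain(
    Y: ExpressionMatrix,
    Z: OutcomeVector | None,
    config: ChainConfig,
    n_chains: int = 2,
) -> list[ChainResult]:
    """Run independent chains with seeds derived from the master seed.

    Each chain starts from its own random assignment of features to
    clusters; cross-chain concordance agreement (see ``summaries``)
    diagnoses whether they reached the same clustering.
    """
    if n_chains < 1:
        raise ConfigError("n_chains must be >= 1")
    if n_chains == 1:
        return [run_chain(Y, Z, config)]
    children = np.random.SeedSequence(config.seed).spawn(n_chains)
    results = []
    for child in children:
        seed = int(child.generate_state(1)[0] & 0x7FFFFFFF)
        results.append(run_chain(Y, Z, dataclasses.replace(config, seed=seed)))
    return results
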