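"""Synthetic-data generator and the simulation-study harness.

The generator draws data from the model itself: per-sample cluster
effects c[i, k] ~ N(0, tau^2); expression Y[i, j] = c[i, k(j)] + N(0,
sigma^2); outcome Z[i] = sum_k beta_k c[i, k] + N(0, gamma^2). The
default configuration is the reference study design: 80 samples, 50
features in 3 clusters (17/17/16), sigma = gamma = 1, beta = (-5, 0, 5),
variance ratio tau^2/sigma^2 = 4. A 27-feature (9/9/9) preset supports
the pair-recovery comparison at the low variance ratio 0.15.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import (
    ConfigError,
    ExpressionMatrix,
    ModelParams,
    OutcomeVector,
    Partition,
    SimulationTruth,
    center_columns,
)
from .sampler import ChainConfig, ChainResult, run_chain
from .summaries import correct_pairing_proportion, modal_partition, stable_beta_summary


@dataclass(frozen=True)
class SimConfig:
    n_samples: int = 80
    n_features: int = 50
    true_k: int = 3
    cluster_sizes: tuple[int, ...] = (17, 17, 16)
    sigma: float = 1.0
    tau: float = 2.0
    gamma: float = 1.0
    beta: tuple[float, ...] = (-5.0, 0.0, 5.0)
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 2 or self.n_features < 1 or self.true_k < 1:
            raise ConfigError("dimensions must be positive (and n_samples >= 2)")
        if len(self.cluster_sizes) != self.true_k:
            raise ConfigError(
                f"{len(self.cluster_sizes)} cluster sizes for true_k={self.true_k}"
            )
        if any(s <= 0 for s in self.cluster_sizes):
            raise ConfigError("cluster sizes must be positive")
        if sum(self.cluster_sizes) != self.n_features:
            raise ConfigError(
                f"cluster sizes sum to {sum(self.cluster_sizes)}, "
                f"expected {self.n_features}"
            )
        if len(self.beta) != self.true_k:
            raise ConfigError("beta must have one entry per true cluster")
        if min(self.sigma, self.tau, self.gamma) <= 0:
            raise ConfigError("sigma, tau, gamma must be positive")

    @property
    def variance_ratio(self) -> float:
        return (self.tau / self.sigma) ** 2


def small_three_cluster_config(
    variance_ratio: float = 0.15, seed: int = 0
) -> SimConfig:
    """Three clusters of 9 features at a chosen variance ratio (the
    pair-recovery comparison setting)."""
    return SimConfig(
        n_features=27,
        cluster_sizes=(9, 9, 9),
        tau=float(np.sqrt(variance_ratio)),
        seed=seed,
    )


def simulate_dataset(
    config: SimConfig,
) -> tuple[ExpressionMatrix, OutcomeVector, SimulationTruth]:
    """Draw one dataset from the generative model (deterministic per seed).

    Returns the *uncentered* expression matrix plus the latent truth;
    inference code never sees the truth object.
    """
    rng = np.random.default_rng(config.seed)
    N, J, K = config.n_samples, config.n_features, config.true_k
    labels = np.repeat(np.arange(K), config.cluster_sizes)
    c = rng.normal(0.0, config.tau, size=(N, K))
    Y = c[:, labels] + rng.normal(0.0, config.sigma, size=(N, J))
    beta = np.asarray(config.beta, dtype=float)
    z = c @ beta + rng.normal(0.0, config.gamma, size=N)
    sample_ids = [f"s{i:04d}" for i in range(N)]
    feature_ids = [f"g{j:04d}" for j in range(J)]
    truth = SimulationTruth(
        c=c,
        true_partition=Partition(labels, K),
        true_params=ModelParams(
            sigma=config.sigma,
            tau=config.tau,
            gamma=config.gamma,
            beta=beta,
            omega=np.asarray(config.cluster_sizes, dtype=float) / J,
        ),
    )
    return (
        ExpressionMatrix(Y, sample_ids, feature_ids, centered=False),
        OutcomeVector(z, sample_ids),
        truth,
    )


def _match_reference_to_truth(
    reference: Partition, truth: Partition
) -> dict[int, int]:
    """Map each true cluster to the reference cluster with maximal
    Jaccard overlap (ties by smaller reference index)."""
    ref_sets = reference.cluster_sets()
    out = {}
    for t_idx, t_set in enumerate(truth.cluster_sets()):
        if not t_set:
            continue
        best, best_j = None, -1.0
        for r_idx, r_set in enumerate(ref_sets):
            if not r_set:
                continue
            jac = len(t_set & r_set) / len(t_set | r_set)
            if jac > best_j:
                best, best_j = r_idx, jac
        out[t_idx] = best
    return out


def fit_replicate(
    sim: SimConfig, chain_cfg: ChainConfig
) -> tuple[ChainResult, SimulationTruth]:
    """Simulate one dataset and fit one chain to it."""
    Y, Z, truth = simulate_dataset(sim)
    result = run_chain(
        center_columns(Y), Z if chain_cfg.include_outcome else None, chain_cfg
    )
    return result, truth


def _replicate_estimates(
    result: ChainResult, truth: SimulationTruth
) -> dict[str, float]:
    post = result.post_burn()
    rec: dict[str, float] = {
        "sigma": float(post.sigma.mean()),
        "sigma_post_sd": float(post.sigma.std(ddof=1)),
        "tau": float(post.tau.mean()),
        "tau_post_sd": float(post.tau.std(ddof=1)),
        "tau_sq": float((post.tau ** 2).mean()),
        "tau_sq_post_sd": float((post.tau ** 2).std(ddof=1)),
        "pairing": correct_pairing_proportion(
            post.assignments, truth.true_partition
        ),
    }
    if result.beta is not None:
        reference = modal_partition(post.assignments, result.k_max)
        table = stable_beta_summary(result, reference)
        ref_by_cluster = {
            frozenset(row.features): row for row in table.itertuples()
        }
        ref_part_sets = reference.cluster_sets()
        match = _match_reference_to_truth(reference, truth.true_partition)
        for t_idx in range(truth.true_partition.k_max):
            r_idx = match.get(t_idx)
            key = ref_part_sets[r_idx] if r_idx is not None else None
            row = ref_by_cluster.get(key) if key else None
            rec[f"beta_{t_idx + 1}"] = (
                float(row.beta_mean) if row is not None else float("nan")
            )
            rec[f"beta_{t_idx + 1}_post_sd"] = (
                float(row.beta_se) if row is not None else float("nan")
            )
    return rec


def run_simulation_study(
    reps: int,
    sim: SimConfig,
    chain: ChainConfig,
    include_outcome: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replicate the simulate-then-fit experiment and tabulate recovery.

    Returns ``(table, per_rep)``: ``per_rep`` holds one row of posterior
    summaries per replicate; ``table`` aggregates each parameter's mean
    estimate, the SD of the estimates across replicates ("se") and the
    mean of the per-replicate posterior SDs ("mean_of_se"). Replicate
    data seeds derive only from ``sim.seed`` so with- and without-outcome
    studies at the same sim seed see identical datasets.
    """
    if reps < 1:
        raise ConfigError("reps must be >= 1")
    if include_outcome is None:
        include_outcome = chain.include_outcome
    chain = dataclasses.replace(chain, include_outcome=include_outcome)
    data_ss = np.random.SeedSequence(sim.seed)
    chain_ss = np.random.SeedSequence((chain.seed, 1 if include_outcome else 0))
    data_children = data_ss.spawn(reps)
    chain_children = chain_ss.spawn(reps)
    records = []
    for r in range(reps):
        sim_r = dataclasses.replace(
            sim, seed=int(data_children[r].generate_state(1)[0] & 0x7FFFFFFF)
        )
        chain_r = dataclasses.replace(
            chain, seed=int(chain_children[r].generate_state(1)[0] & 0x7FFFFFFF)
        )
        result, truth = fit_replicate(sim_r, chain_r)
        rec = _replicate_estimates(result, truth)
        rec["rep"] = r
        records.append(rec)
    per_rep = pd.DataFrame(records)

    true_vals = {
        "sigma": sim.sigma,
        "tau": sim.tau,
        "tau_sq": sim.tau ** 2,
        "pairing": 1.0,
    }
    if include_outcome:
        for t_idx, b in enumerate(sim.beta):
            true_vals[f"beta_{t_idx + 1}"] = float(b)
    rows = []
    for name, true in true_vals.items():
        est = per_rep[name].dropna()
        sd_col = f"{name}_post_sd"
        post_sd = per_rep[sd_col].dropna() if sd_col in per_rep else pd.Series(dtype=float)
        rows.append(
            {
                "parameter": name,
                "true": true,
                "mean": float(est.mean()) if len(est) else float("nan"),
                "se": float(est.std(ddof=1)) if len(est) > 1 else float("nan"),
                "mean_of_se": float(post_sd.mean()) if len(post_sd) else float("nan"),
                "n_reps_used": int(len(est)),
            }
        )
    return pd.DataFrame(rows), per_rep


def reference_recovery_study(
    reps: int = 20, seed: int = 0, iterations: int = 1000, burn_in: int = 500
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Parameter-recovery study at the reference design.

    N=80, J=50 in 3 clusters (17/17/16), sigma=gamma=1, beta=(-5,0,5),
    variance ratio 4 (tau=2), K=5, joint model. Returns the aggregated
    recovery table and the per-replicate estimates.
    """
    sim = SimConfig(seed=seed)
    chain = ChainConfig(
        k_max=5, iterations=iterations, burn_in=burn_in, seed=seed + 1
    )
    return run_simulation_study(reps, sim, chain, include_outcome=True)


def pairing_comparison_study(
    reps: int = 20,
    seed: int = 0,
    variance_ratio: float = 0.15,
    iterations: int = 1000,
    burn_in: int = 500,
) -> dict[str, float]:
    """Correct-pairing comparison with vs without the outcome.

    Three clusters of 9 features at the given variance ratio; both model
    variants are fit to the *same* replicate datasets. Returns the mean
    pairing proportion for each variant plus per-replicate values.
    """
    sim = small_three_cluster_config(variance_ratio, seed=seed)
    chain = ChainConfig(
        k_max=5, iterations=iterations, burn_in=burn_in, seed=seed + 1
    )
    _, with_o = run_simulation_study(reps, sim, chain, include_outcome=True)
    _, without_o = run_simulation_study(reps, sim, chain, include_outcome=False)
    return {
        "with_outcome": float(with_o["pairing"].mean()),
        "without_outcome": float(without_o["pairing"].mean()),
        "with_outcome_per_rep": with_o["pairing"].to_numpy(),
        "without_outcome_per_rep": without_o["pairing"].to_numpy(),
    }
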