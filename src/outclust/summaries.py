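"""Label-switching-robust posterior summaries.

Cluster labels carry no meaning across MCMC iterations (any relabeling
leaves the likelihood unchanged), so summaries are built on the
*partition* itself: the J x J concordance matrix of pairwise
co-clustering proportions, seriation of features for heat maps,
cross-chain agreement diagnostics, pair-level scoring against a known
truth, and beta estimates restricted to iterations whose sampled
clusters exactly reproduce a reference gene set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage, optimal_leaf_ordering
from scipy.spatial.distance import squareform

from .data import DataValidationError, Partition
from .sampler import ChainResult


@dataclass(frozen=True)
class ConcordanceMatrix:
    """J x J matrix of posterior co-clustering proportions."""

    values: np.ndarray
    feature_ids: list[str]
    iterations_used: int

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise DataValidationError(f"concordance matrix must be square, got {v.shape}")
        if not np.allclose(v, v.T, atol=1e-12):
            raise DataValidationError("concordance matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-12):
            raise DataValidationError("concordance diagonal must be 1")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise DataValidationError("concordance entries must lie in [0, 1]")
        object.__setattr__(self, "values", np.clip(v, 0.0, 1.0))

    @property
    def n_features(self) -> int:
        return self.values.shape[0]


def concordance_matrix(
    assignments: np.ndarray, feature_ids: list[str] | None = None
) -> ConcordanceMatrix:
    """Fraction of iterations in which each feature pair shares a label.

    ``assignments`` is T x J (one stored partition per row). The result
    is invariant to any per-iteration relabeling of clusters.
    """
    a = np.asarray(assignments)
    if a.ndim != 2 or a.shape[0] < 1:
        raise DataValidationError("need a T x J array with at least one iteration")
    T, J = a.shape
    same = a[:, :, None] == a[:, None, :]
    C = same.mean(axis=0)
    if feature_ids is None:
        feature_ids = [str(j) for j in range(J)]
    return ConcordanceMatrix(C, list(feature_ids), T)


def order_features(C: ConcordanceMatrix) -> np.ndarray:
    """Deterministic permutation placing high-concordance features adjacently.

    Average-linkage hierarchical clustering on dissimilarity 1 - C with
    optimal leaf ordering; exact {0,1} block structure comes out as
    contiguous blocks.
    """
    J = C.n_features
    if J <= 2:
        return np.arange(J)
    d = squareform(1.0 - C.values, checks=False)
    Zl = linkage(d, method="average")
    return np.asarray(leaves_list(optimal_leaf_ordering(Zl, d)))


def quantize16(values: np.ndarray) -> np.ndarray:
    """Bin concordance values into the 16 discrete gray shades used for
    the heat map (bin edges at i/16; 1.0 falls in the top bin)."""
    return np.minimum((np.asarray(values) * 16).astype(int), 15)


def heatmap_export(
    C: ConcordanceMatrix,
    order: np.ndarray,
    matrix_path,
    image_path=None,
):
    """Write the reordered concordance matrix as CSV and optionally render
    a 16-shade grayscale heat map (white = 0, black = 1)."""
    order = np.asarray(order)
    ids = [C.feature_ids[i] for i in order]
    reordered = C.values[np.ix_(order, order)]
    pd.DataFrame(reordered, index=ids, columns=ids).to_csv(matrix_path)
    if image_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        from matplotlib.colors import BoundaryNorm, ListedColormap

        cmap = ListedColormap([str(1.0 - i / 15.0) for i in range(16)])
        norm = BoundaryNorm(np.linspace(0.0, 1.0, 17), 16)
        fig, ax = plt.subplots(figsize=(6, 6))
        ax.imshow(reordered, cmap=cmap, norm=norm, interpolation="nearest")
        ax.set_xlabel("features")
        ax.set_ylabel("features")
        ax.set_title("posterior co-clustering concordance")
        fig.savefig(image_path, dpi=150)
        plt.close(fig)


@dataclass(frozen=True)
class ChainAgreement:
    """Paired upper-triangle concordance values from two chains and their
    Pearson correlation (the convergence diagnostic scatter)."""

    a: np.ndarray
    b: np.ndarray
    correlation: float


def chain_agreement(Ca: ConcordanceMatrix, Cb: ConcordanceMatrix) -> ChainAgreement:
    """Compare two chains' concordance matrices pair by pair."""
    if Ca.feature_ids != Cb.feature_ids:
        raise DataValidationError("chains summarize different feature sets")
    iu = np.triu_indices(Ca.n_features, k=1)
    a, b = Ca.values[iu], Cb.values[iu]
    if np.allclose(a, b):
        r = 1.0
    elif a.std() == 0 or b.std() == 0:
        r = float("nan")
    else:
        r = float(np.corrcoef(a, b)[0, 1])
    return ChainAgreement(a=a, b=b, correlation=r)


def correct_pairing_proportion(
    assignments: np.ndarray, truth: Partition, mode: str = "all_pairs"
) -> float:
    """Iteration-averaged agreement between sampled and true pairings.

    mode="all_pairs" (default): per iteration, the fraction of all
    feature pairs whose same/different-cluster status matches the truth
    (the Rand index against the truth), averaged over iterations. Equals
    1 iff every stored partition matches the truth up to relabeling.

    mode="true_pairs": restricts to pairs that are truly co-clustered
    (average pairwise sensitivity).
    """
    a = np.asarray(assignments)
    if a.ndim == 1:
        a = a[None, :]
    J = truth.n_features
    if a.shape[1] != J:
        raise DataValidationError(f"assignments have {a.shape[1]} features, truth {J}")
    iu = np.triu_indices(J, k=1)
    t = truth.assignment
    truth_same = (t[:, None] == t[None, :])[iu]
    same = (a[:, :, None] == a[:, None, :])[:, iu[0], iu[1]]
    if mode == "all_pairs":
        return float((same == truth_same).mean())
    if mode == "true_pairs":
        if not truth_same.any():
            raise DataValidationError("truth has no co-clustered pairs")
        return float(same[:, truth_same].mean())
    raise ValueError(f"unknown mode {mode!r}")


def canonicalize_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters by order of first appearance (0, 1, 2, ...)."""
    labels = np.asarray(labels)
    out = np.empty_like(labels)
    mapping: dict[int, int] = {}
    for i, lab in enumerate(labels):
        out[i] = mapping.setdefault(int(lab), len(mapping))
    return out


def modal_partition(assignments: np.ndarray, k_max: int) -> Partition:
    """Most frequent sampled partition after canonical relabeling; ties
    broken by first occurrence."""
    a = np.asarray(assignments)
    counts: dict[bytes, int] = {}
    first: dict[bytes, np.ndarray] = {}
    order: list[bytes] = []
    for row in a:
        canon = canonicalize_labels(row)
        key = canon.tobytes()
        if key not in counts:
            counts[key] = 0
            first[key] = canon
            order.append(key)
        counts[key] += 1
    best = max(order, key=lambda k: counts[k])
    return Partition(first[best], k_max)


def stable_beta_summary(
    chain: ChainResult, reference: Partition | None = None
) -> pd.DataFrame:
    """Per-cluster beta estimates from label-stable iterations only.

    For each non-empty cluster of the reference partition (default: the
    modal post-burn-in partition), only iterations in which *exactly*
    that feature set shares one label are used; the matching label's beta
    draw is tracked through any label switching by set identity. Returns
    a table with columns cluster, size, beta_mean, beta_se (SD of the
    usable draws) and n_iterations; clusters with no usable iteration get
    NaN estimates rather than an error.
    """
    if chain.beta is None:
        raise DataValidationError("chain was fit without an outcome; no beta draws")
    post = chain.post_burn()
    if reference is None:
        reference = modal_partition(post.assignments, chain.k_max)
    ref_sets = [s for s in reference.cluster_sets() if s]
    draws: dict[frozenset, list[float]] = {s: [] for s in ref_sets}
    for it in range(post.assignments.shape[0]):
        row = post.assignments[it]
        by_label: dict[int, list[int]] = {}
        for j, lab in enumerate(row):
            by_label.setdefault(int(lab), []).append(j)
        sets = {frozenset(v): k for k, v in by_label.items()}
        for s in ref_sets:
            lab = sets.get(s)
            if lab is not None:
                draws[s].append(float(post.beta[it, lab]))
    rows = []
    for idx, s in enumerate(ref_sets):
        d = np.asarray(draws[s])
        rows.append(
            {
                "cluster": idx,
                "size": len(s),
                "features": sorted(s),
                "beta_mean": float(d.mean()) if d.size else float("nan"),
                "beta_se": float(d.std(ddof=1)) if d.size > 1 else float("nan"),
                "n_iterations": int(d.size),
            }
        )
    return pd.DataFrame(rows)
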