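"""Core data containers for outcome-driven clustering.

The method clusters *features* (genes) measured across *samples*
(patients): an N x J matrix of log-scale expression values plus an
optional length-N continuous outcome. Features in the same cluster share
a per-sample Gaussian random effect of variance ``tau**2``; measurement
error has variance ``sigma**2``; the outcome is a linear combination of
the cluster effects plus noise of variance ``gamma**2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class DataValidationError(ValueError):
    """Raised when input data violate a structural requirement."""


class ConfigError(ValueError):
    """Raised when a configuration object is internally inconsistent."""


def _as_float_array(x, name: str) -> np.ndarray:
    try:
        arr = np.asarray(x, dtype=float)
    except (TypeError, ValueError) as exc:
        raise DataValidationError(f"{name} is not numeric: {exc}") from exc
    return arr


@dataclass(frozen=True)
class ExpressionMatrix:
    """N samples x J features of (log-scale) expression values.

    Rows are samples, columns are features; ``centered`` records whether
    the J column means have been subtracted (the model assumes they have
    before any likelihood evaluation).
    """

    values: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]
    centered: bool = False

    def __post_init__(self):
        vals = _as_float_array(self.values, "expression matrix")
        if vals.ndim != 2:
            raise DataValidationError(
                f"expression matrix must be 2-D, got shape {vals.shape}"
            )
        n, j = vals.shape
        if n < 2 or j < 1:
            raise DataValidationError(
                f"need at least 2 samples and 1 feature, got {n} x {j}"
            )
        bad = np.argwhere(~np.isfinite(vals))
        if bad.size:
            i0, j0 = bad[0]
            sid = self.sample_ids[i0] if self.sample_ids else str(i0)
            fid = self.feature_ids[j0] if self.feature_ids else str(j0)
            raise DataValidationError(
                f"non-finite expression value at sample {sid!r}, feature {fid!r}"
            )
        if len(self.sample_ids) != n:
            raise DataValidationError(
                f"{len(self.sample_ids)} sample ids for {n} rows"
            )
        if len(self.feature_ids) != j:
            raise DataValidationError(
                f"{len(self.feature_ids)} feature ids for {j} columns"
            )
        if self.centered:
            means = vals.mean(axis=0)
            if np.abs(means).max() > 1e-10:
                raise DataValidationError(
                    "matrix flagged centered but column means reach "
                    f"{np.abs(means).max():.3g}"
                )
        object.__setattr__(self, "values", vals)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def column_means(self) -> np.ndarray:
        return self.values.mean(axis=0)


def center_columns(Y: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each feature's mean across samples.

    Returns a new matrix with every column mean zero and the ``centered``
    flag set; row and column order are preserved.
    """
    centered = Y.values - Y.values.mean(axis=0, keepdims=True)
    return ExpressionMatrix(
        values=centered,
        sample_ids=list(Y.sample_ids),
        feature_ids=list(Y.feature_ids),
        centered=True,
    )


@dataclass(frozen=True)
class OutcomeVector:
    """Continuous per-sample outcome (e.g. a maximum organ-failure score)."""

    z: np.ndarray
    sample_ids: list[str] | None = None

    def __post_init__(self):
        z = _as_float_array(self.z, "outcome vector").ravel()
        bad = np.argwhere(~np.isfinite(z))
        if bad.size:
            i0 = int(bad[0][0])
            sid = self.sample_ids[i0] if self.sample_ids else str(i0)
            raise DataValidationError(f"non-finite outcome for sample {sid!r}")
        object.__setattr__(self, "z", z)

    def __len__(self) -> int:
        return self.z.shape[0]


@dataclass(frozen=True)
class Partition:
    """Assignment of each of J features to one of ``k_max`` cluster labels.

    Labels are 0-based integers in ``0..k_max-1``. ``k_max`` is the fixed
    maximum number of clusters; any label may be empty at a given moment —
    the number of *filled* clusters is whatever the assignment implies.
    """

    assignment: np.ndarray
    k_max: int

    def __post_init__(self):
        a = np.asarray(self.assignment, dtype=np.int64).ravel()
        if self.k_max < 1:
            raise DataValidationError(f"k_max must be >= 1, got {self.k_max}")
        if a.size < 1:
            raise DataValidationError("empty assignment")
        if a.min() < 0 or a.max() >= self.k_max:
            raise DataValidationError(
                f"labels must lie in [0, {self.k_max}), "
                f"got range [{a.min()}, {a.max()}]"
            )
        object.__setattr__(self, "assignment", a)

    @property
    def n_features(self) -> int:
        return self.assignment.shape[0]

    def sizes(self) -> np.ndarray:
        """Cluster sizes n_k, length k_max (empty clusters count 0)."""
        return np.bincount(self.assignment, minlength=self.k_max)

    def indicator(self) -> np.ndarray:
        """J x k_max one-hot membership matrix."""
        phi = np.zeros((self.n_features, self.k_max))
        phi[np.arange(self.n_features), self.assignment] = 1.0
        return phi

    def cluster_sets(self) -> list[frozenset[int]]:
        """Feature-index set for each label (empty sets for empty labels)."""
        return [
            frozenset(np.flatnonzero(self.assignment == k).tolist())
            for k in range(self.k_max)
        ]


@dataclass(frozen=True)
class ModelParams:
    """Variance components, regression coefficients and cluster weights.

    sigma : measurement-error SD.
    tau   : cluster-effect SD (within-cluster covariance is tau**2).
    gamma : outcome-error SD.
    beta  : per-cluster outcome regression coefficients, length k_max.
    omega : cluster weights on the simplex, length k_max.
    """

    sigma: float
    tau: float
    gamma: float
    beta: np.ndarray
    omega: np.ndarray

    def __post_init__(self):
        for name in ("sigma", "tau", "gamma"):
            v = float(getattr(self, name))
            if not np.isfinite(v) or v <= 0:
                raise DataValidationError(f"{name} must be finite and > 0, got {v}")
            object.__setattr__(self, name, v)
        beta = _as_float_array(self.beta, "beta").ravel()
        omega = _as_float_array(self.omega, "omega").ravel()
        if beta.shape != omega.shape:
            raise DataValidationError(
                f"beta (len {beta.size}) and omega (len {omega.size}) disagree"
            )
        if np.any(omega <= 0) or abs(omega.sum() - 1.0) > 1e-10:
            raise DataValidationError("omega must be strictly positive and sum to 1")
        object.__setattr__(self, "beta", beta)
        object.__setattr__(self, "omega", omega)

    @property
    def k_max(self) -> int:
        return self.beta.shape[0]

    @property
    def variance_ratio(self) -> float:
        """tau**2 / sigma**2 — governs how separable the clusters are."""
        return (self.tau / self.sigma) ** 2


@dataclass
class SufficientStats:
    """Cached aggregates enabling O(N*K) likelihood evaluation.

    n        : cluster sizes, length K.
    T        : N x K matrix, T[i, k] = sum of Y[i, j] over features j in k.
    sq_total : sum of Y[i, j]**2 over all cells.
    """

    n: np.ndarray
    T: np.ndarray
    sq_total: float

    @classmethod
    def from_data(cls, Y: ExpressionMatrix, partition: Partition) -> "SufficientStats":
        phi = partition.indicator()
        return cls(
            n=partition.sizes().astype(float),
            T=Y.values @ phi,
            sq_total=float(np.sum(Y.values**2)),
        )

    def move(self, y_col: np.ndarray, k_from: int, k_to: int) -> None:
        """Move one feature (with sample profile ``y_col``) between labels."""
        if k_from == k_to:
            return
        self.n[k_from] -= 1
        self.n[k_to] += 1
        self.T[:, k_from] -= y_col
        self.T[:, k_to] += y_col

    def copy(self) -> "SufficientStats":
        return SufficientStats(self.n.copy(), self.T.copy(), self.sq_total)

    def verify(self, Y: ExpressionMatrix, partition: Partition, atol: float = 1e-9):
        """Check cached values against a from-scratch recomputation."""
        fresh = SufficientStats.from_data(Y, partition)
        if (
            not np.allclose(self.n, fresh.n, atol=atol)
            or not np.allclose(self.T, fresh.T, atol=atol)
            or abs(self.sq_total - fresh.sq_total) > atol * max(1.0, abs(fresh.sq_total))
        ):
            raise RuntimeError("sufficient statistics drifted from the data")


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth kept by the simulator; never consulted by inference."""

    c: np.ndarray  # N x K_true latent cluster effects
    true_partition: Partition
    true_params: ModelParams

    def __post_init__(self):
        c = _as_float_array(self.c, "latent effects")
        if not np.all(np.isfinite(c)):
            raise DataValidationError("non-finite latent cluster effect")
        object.__setattr__(self, "c", c)
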