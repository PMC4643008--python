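"""Delimited-text I/O for expression matrices, outcomes and chain output.

Expression files are CSV or TSV (autodetected by extension): header row
of feature ids, first column sample ids. Outcome files are two-column
(sample_id, value) or a single unlabeled column in matrix row order.
A fitted chain is persisted as a directory of CSV tables plus a JSON
manifest sufficient to re-run the fit bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .data import DataValidationError, ExpressionMatrix, OutcomeVector
from .sampler import ChainConfig, ChainResult, PriorConfig, ProposalConfig

__all__ = [
    "read_expression",
    "write_expression",
    "read_outcome",
    "write_outcome",
    "write_chain_dir",
    "read_chain_dir",
]


def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_expression(path, transpose: bool = False) -> ExpressionMatrix:
    """Read a samples x features matrix; ``transpose`` flips orientation
    for files stored features x samples."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    except pd.errors.ParserError as exc:
        raise DataValidationError(f"malformed delimited file {path}: {exc}") from exc
    if transpose:
        df = df.T
    values = df.to_numpy()
    if values.dtype == object or not np.issubdtype(values.dtype, np.number):
        for j, col in enumerate(df.columns):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                row = bad.idxmax()
                raise DataValidationError(
                    f"non-numeric value {df[col][row]!r} at sample {row!r}, "
                    f"feature {col!r} in {path}"
                )
        values = df.apply(pd.to_numeric).to_numpy()
    nan = np.argwhere(~np.isfinite(values.astype(float)))
    if nan.size:
        i0, j0 = nan[0]
        raise DataValidationError(
            f"missing or non-finite value at sample {df.index[i0]!r}, "
            f"feature {df.columns[j0]!r} in {path} (missing data unsupported)"
        )
    return ExpressionMatrix(
        values=values.astype(float),
        sample_ids=[str(s) for s in df.index],
        feature_ids=[str(f) for f in df.columns],
        centered=bool(np.abs(values.astype(float).mean(axis=0)).max() <= 1e-10),
    )


def write_expression(Y: ExpressionMatrix, path) -> None:
    path = Path(path)
    pd.DataFrame(Y.values, index=Y.sample_ids, columns=Y.feature_ids).to_csv(
        path, sep=_sep_for(path), index_label="sample_id"
    )


def read_outcome(path, sample_ids: list[str] | None = None) -> OutcomeVector:
    """Read the outcome; two-column files are aligned to ``sample_ids``
    (order-insensitive), single-column files are taken in row order."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), header=None)
    if df.shape[1] == 1:
        col = pd.to_numeric(df[0], errors="coerce")
        if col.isna().all() and df.shape[0] > 0:
            # header line present on a labelled single column
            raise DataValidationError(f"no numeric outcome values in {path}")
        if col.isna().iloc[0] and col.iloc[1:].notna().all():
            col = col.iloc[1:]
        if col.isna().any():
            raise DataValidationError(f"non-numeric outcome value in {path}")
        return OutcomeVector(col.to_numpy(float), sample_ids)
    # two columns: sample_id, value (optional header)
    first_val = pd.to_numeric(df.iloc[0, 1], errors="coerce")
    if pd.isna(first_val):
        df = df.iloc[1:]
    ids = [str(s) for s in df[0]]
    vals = pd.to_numeric(df[1], errors="coerce")
    if vals.isna().any():
        bad = ids[int(np.argmax(vals.isna().to_numpy()))]
        raise DataValidationError(f"non-numeric outcome for sample {bad!r} in {path}")
    z = vals.to_numpy(float)
    if sample_ids is not None:
        lookup = dict(zip(ids, z))
        missing = [s for s in sample_ids if s not in lookup]
        extra = [s for s in ids if s not in set(sample_ids)]
        if missing or extra:
            raise DataValidationError(
                f"sample-id mismatch between expression and outcome: "
                f"missing={missing[:5]}, unexpected={extra[:5]}"
            )
        z = np.array([lookup[s] for s in sample_ids])
        ids = list(sample_ids)
    return OutcomeVector(z, ids)


def write_outcome(Z: OutcomeVector, path) -> None:
    path = Path(path)
    ids = Z.sample_ids or [str(i) for i in range(len(Z))]
    pd.DataFrame({"sample_id": ids, "value": Z.z}).to_csv(
        path, sep=_sep_for(path), index=False, header=False
    )


def _digest(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_chain_dir(
    out_dir,
    results: list[ChainResult],
    feature_ids: list[str],
    column_means: np.ndarray | None = None,
    input_paths: dict[str, str] | None = None,
) -> Path:
    """Persist one or more chains plus a reproducibility manifest."""
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for idx, res in enumerate(results):
        cdir = out / f"chain{idx}"
        cdir.mkdir(exist_ok=True)
        pd.DataFrame(res.assignments, columns=feature_ids).to_csv(
            cdir / "assignments.csv", index=False
        )
        params = {"sigma": res.sigma, "tau": res.tau, "loglik": res.loglik}
        if res.gamma is not None:
            params["gamma"] = res.gamma
        pd.DataFrame(params).to_csv(
            cdir / "params.csv", index=False, float_format="%.17g"
        )
        if res.beta is not None:
            pd.DataFrame(
                res.beta, columns=[f"beta_{k}" for k in range(res.k_max)]
            ).to_csv(cdir / "beta.csv", index=False, float_format="%.17g")
        pd.DataFrame(
            res.omega, columns=[f"omega_{k}" for k in range(res.k_max)]
        ).to_csv(cdir / "omega.csv", index=False, float_format="%.17g")
        (cdir / "acceptance.json").write_text(
            json.dumps(res.acceptance_rates, indent=1)
        )
    if column_means is not None:
        pd.DataFrame({"feature_id": feature_ids, "mean": column_means}).to_csv(
            out / "column_means.csv", index=False, float_format="%.17g"
        )
    cfg = results[0].config
    manifest = {
        "version": __version__,
        "created_utc": datetime.now(timezone.utc).isoformat(),
        "n_chains": len(results),
        "config": dataclasses.asdict(cfg),
        "chain_seeds": [r.config.seed for r in results],
        "feature_ids": feature_ids,
        "inputs": {
            name: {"path": str(p), "sha256": _digest(p)}
            for name, p in (input_paths or {}).items()
            if Path(p).exists()
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def read_chain_dir(out_dir) -> tuple[list[ChainResult], list[str], np.ndarray | None]:
    """Load chains written by :func:`write_chain_dir`.

    Returns (results, feature_ids, column_means).
    """
    out = Path(out_dir)
    mpath = out / "manifest.json"
    if not mpath.exists():
        raise DataValidationError(f"no manifest.json in {out}")
    manifest = json.loads(mpath.read_text())
    cfg_d = dict(manifest["config"])
    cfg_d["priors"] = PriorConfig(**cfg_d["priors"])
    cfg_d["proposals"] = ProposalConfig(**cfg_d["proposals"])
    feature_ids = manifest["feature_ids"]
    results = []
    for idx in range(manifest["n_chains"]):
        cdir = out / f"chain{idx}"
        if not cdir.exists():
            raise DataValidationError(f"missing chain directory {cdir}")
        assignments = pd.read_csv(cdir / "assignments.csv").to_numpy(np.int64)
        params = pd.read_csv(cdir / "params.csv")
        beta_path = cdir / "beta.csv"
        beta = pd.read_csv(beta_path).to_numpy(float) if beta_path.exists() else None
        omega = pd.read_csv(cdir / "omega.csv").to_numpy(float)
        rates = json.loads((cdir / "acceptance.json").read_text())
        cfg = ChainConfig(
            **{**cfg_d, "seed": manifest["chain_seeds"][idx],
               "include_outcome": beta is not None}
        )
        results.append(
            ChainResult(
                assignments=assignments,
                sigma=params["sigma"].to_numpy(),
                tau=params["tau"].to_numpy(),
                gamma=params["gamma"].to_numpy() if "gamma" in params else None,
                beta=beta,
                omega=omega,
                loglik=params["loglik"].to_numpy(),
                acceptance_rates=rates,
                config=cfg,
            )
        )
    means_path = out / "column_means.csv"
    column_means = (
        pd.read_csv(means_path)["mean"].to_numpy(float) if means_path.exists() else None
    )
    return results, feature_ids, column_means
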