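"""Reading and writing the package's file formats.

Canonical tabular dialect: TSV, UTF-8, LF line endings, no quoting,
floats at 10 significant digits.  The expression matrix file has the
sample id in the first column and one header row of feature ids; the
companion metadata file has columns ``sample_id``, ``class``, ``time``.
Run reports are JSON; configuration files are YAML key-value documents.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import JoinError, TopConNMFError, ValidationError
from .expression import ExpressionMatrix
from .factorization import (
    FactorConfig,
    FactorPair,
    FactorResult,
    l21_norm,
    reconstruction_error,
)
from . import topology

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.10g"


def _sep_for(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def write_expression(
    X: ExpressionMatrix, matrix_path: str | Path, metadata_path: str | Path
) -> None:
    """Write a matrix TSV/CSV and its sample-metadata companion."""
    df = pd.DataFrame(X.values, index=X.sample_ids, columns=X.feature_ids)
    df.index.name = "sample_id"
    df.to_csv(matrix_path, sep=_sep_for(matrix_path), float_format=FLOAT_FMT)
    meta = pd.DataFrame(
        {"sample_id": X.sample_ids, "class": X.sample_class, "time": X.sample_time}
    )
    meta.to_csv(
        metadata_path, sep=_sep_for(metadata_path), index=False, float_format=FLOAT_FMT
    )


def read_expression(
    matrix_path: str | Path, metadata_path: str | Path
) -> ExpressionMatrix:
    """Read and validate an expression matrix plus metadata.

    Rejects negative values (naming the offending cell), unmatched
    sample ids (listing them) and ragged rows (via the parser error).
    """
    try:
        df = pd.read_csv(matrix_path, sep=_sep_for(matrix_path), index_col=0)
    except pd.errors.ParserError as exc:
        raise ValidationError(f"cannot parse matrix file {matrix_path}: {exc}") from exc
    try:
        meta = pd.read_csv(metadata_path, sep=_sep_for(metadata_path))
    except pd.errors.ParserError as exc:
        raise ValidationError(f"cannot parse metadata file {metadata_path}: {exc}") from exc
    for col in ("sample_id", "class", "time"):
        if col not in meta.columns:
            raise ValidationError(f"metadata lacks required column {col!r}")
    meta = meta.set_index(meta["sample_id"].astype(str))
    sample_ids = [str(i) for i in df.index]
    missing = [s for s in sample_ids if s not in meta.index]
    extra = [s for s in meta.index if s not in set(sample_ids)]
    if missing or extra:
        raise JoinError(
            f"sample ids not matched between files; missing from metadata: "
            f"{missing}, absent from matrix: {extra}"
        )
    meta = meta.loc[sample_ids]
    values = df.to_numpy(dtype=float)
    if np.any(values < 0):
        i, j = np.argwhere(values < 0)[0]
        raise ValidationError(
            f"negative value at sample {sample_ids[i]!r}, feature {df.columns[j]!r}"
        )
    return ExpressionMatrix(
        values=values,
        feature_ids=[str(c) for c in df.columns],
        sample_class=list(meta["class"].astype(str)),
        sample_time=meta["time"].to_numpy(dtype=float),
        sample_ids=sample_ids,
    )


def _write_matrix(M: np.ndarray, path: str | Path, prefix: str) -> None:
    df = pd.DataFrame(
        M,
        index=[f"{prefix}{i}" for i in range(M.shape[0])],
        columns=[f"c{j}" for j in range(M.shape[1])],
    )
    df.index.name = "row"
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def write_factors(F: FactorPair, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_matrix(F.W, outdir / "W.tsv", "r")
    _write_matrix(F.H, outdir / "H.tsv", "r")


def read_factors(outdir: str | Path) -> FactorPair:
    outdir = Path(outdir)
    W = pd.read_csv(outdir / "W.tsv", sep="\t", index_col=0).to_numpy(dtype=float)
    H = pd.read_csv(outdir / "H.tsv", sep="\t", index_col=0).to_numpy(dtype=float)
    return FactorPair(W=W, H=H)


def write_cost_trace(result: FactorResult, path: str | Path) -> None:
    pd.DataFrame(
        {
            "iteration": np.arange(1, result.n_iter + 1),
            "total_cost": result.cost_trace,
            "reconstruction_error": result.re_trace,
        }
    ).to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def write_run_report(result: FactorResult, X, path: str | Path) -> dict:
    """JSON run report: config, seed, iterations, final cost decomposition."""
    cfg = result.config
    re = reconstruction_error(X, result.factors)
    alpha_term = cfg.alpha * l21_norm(result.factors.W)
    if cfg.beta > 0:
        T, _ = topology.topology_penalty(
            result.factors.H, cfg.k, cfg.floor_eps, cfg.tom_product_mode
        )
        beta_term = cfg.beta * T
    else:
        beta_term = 0.0
    report = {
        "config": dataclasses.asdict(cfg),
        "seed": cfg.seed,
        "n_iter": result.n_iter,
        "converged": result.converged,
        "final_cost": {
            "reconstruction_error": re,
            "alpha_term": alpha_term,
            "beta_term": beta_term,
            "total": re + alpha_term + beta_term,
        },
    }
    Path(path).write_text(json.dumps(report, indent=2) + "\n")
    return report


def write_metric_report(summaries, path: str | Path) -> None:
    """TSV report: metric, mean, sd, n_runs (one row per summary)."""
    rows = [
        {"metric": s.name, "mean": s.mean, "sd": s.sd, "n_runs": s.n_runs}
        for s in summaries
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def write_assignments(feature_ids, assignments, path: str | Path) -> None:
    pd.DataFrame({"feature_id": feature_ids, "group": np.asarray(assignments)}).to_csv(
        path, sep="\t", index=False
    )


def read_assignments(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Full pipeline configuration (factorization + ranking + evaluation)."""

    k: int = 5
    alpha: float = 0.0150
    beta: float = 0.0095
    max_iter: int = 300
    tol: float = 1e-6
    seed: int = 0
    floor_eps: float = 1e-10
    basis_penalty_mode: str = "reweighted"
    tom_product_mode: str = "matrix"
    gradient_mode: str = "chain_rule"
    matrix_path: str = ""
    metadata_path: str = ""
    outdir: str = "."
    top_fraction: float = 0.03
    n_repeat_runs: int = 30
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.n_repeat_runs < 1:
            raise ValidationError("n_repeat_runs must be >= 1")

    def factor_config(self) -> FactorConfig:
        return FactorConfig(
            k=self.k,
            alpha=self.alpha,
            beta=self.beta,
            max_iter=self.max_iter,
            tol=self.tol,
            seed=self.seed,
            floor_eps=self.floor_eps,
            basis_penalty_mode=self.basis_penalty_mode,
            tom_product_mode=self.tom_product_mode,
            gradient_mode=self.gradient_mode,
        )


def load_run_config(path: str | Path | None, **overrides) -> RunConfig:
    """Build a :class:`RunConfig` from an optional YAML file plus overrides.

    Explicit keyword overrides (CLI flags) win over file values; ``None``
    overrides are ignored.
    """
    data: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValidationError(f"config file {path} must be a mapping")
        data.update(loaded)
    for key, value in overrides.items():
        if value is not None:
            data[key] = value
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise TopConNMFError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)
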