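"""Readers, writers and study configuration.

Endpoint tables are CSV/TSV with a header row of endpoint labels: a paired
design has one row per subject of pre-post differences; a two-group design
carries an extra ``group`` column with exactly two levels.  Predictions are a
two-column file mapping endpoint label to direction (+1/-1/up/down).  Reports
are JSON (full precision) mirroring the human-readable table printed by the
CLI.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import DirectionPredictions, TestResult, parse_direction
from .obrien import OlsResult

__all__ = [
    "StudyConfig",
    "read_endpoint_table",
    "read_predictions",
    "read_correlation_matrix",
    "write_correlation_matrix",
    "write_distribution",
    "write_report",
    "load_config",
]


@dataclass(frozen=True)
class StudyConfig:
    """Analysis settings mirrored by the CLI flags (flags win over file)."""

    design: str = "paired"
    phi0: float = 0.5
    alpha: float = 0.05
    method: str = "auto"
    correlation_estimator: str = "pearson"
    require_T_ge_1: bool = True
    seed: int | None = None

    def __post_init__(self):
        if self.design not in ("paired", "two-group"):
            raise ValueError(f"unknown design {self.design!r}")
        if self.method not in ("auto", "exact", "normal"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.correlation_estimator not in ("pearson", "spearman", "kendall"):
            raise ValueError(
                f"unknown correlation estimator {self.correlation_estimator!r}"
            )
        if not 0.0 < self.phi0 < 1.0:
            raise ValueError("phi0 must be in (0, 1)")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path} is empty")
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=sep)


def read_endpoint_table(path, design: str = "paired") -> pd.DataFrame:
    """Read and validate a subjects x endpoints data table."""
    df = _read_table(path)
    if df.shape[0] == 0:
        raise ValueError(f"{path} has a header but no data rows")
    endpoint_cols = [c for c in df.columns if c != "group"]
    if design == "two-group":
        if "group" not in df.columns:
            raise ValueError("two-group design requires a 'group' column")
        levels = df["group"].unique()
        if len(levels) != 2:
            raise ValueError(
                f"'group' must have exactly 2 levels, got {len(levels)}: "
                f"{sorted(map(str, levels))}"
            )
    for col in endpoint_cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            row = int(np.argmax(bad.to_numpy()))
            raise ValueError(
                f"non-numeric value {df[col].iloc[row]!r} at row {row}, "
                f"column {col!r}"
            )
        if vals.isna().any():
            row = int(np.argmax(vals.isna().to_numpy()))
            raise ValueError(f"missing value at row {row}, column {col!r}")
        df[col] = vals
    return df


def read_predictions(path, endpoint_labels=None) -> DirectionPredictions:
    """Read a two-column (endpoint label, direction) predictions file.

    When ``endpoint_labels`` is given the predictions are reordered to match
    and must cover every endpoint exactly once.
    """
    df = _read_table(path)
    if df.shape[1] != 2:
        raise ValueError(
            f"predictions file must have 2 columns (label, direction), "
            f"got {df.shape[1]}"
        )
    labels = df.iloc[:, 0].astype(str).tolist()
    signs = [parse_direction(x) for x in df.iloc[:, 1]]
    series = pd.Series(signs, index=labels)
    if series.index.duplicated().any():
        dup = series.index[series.index.duplicated()][0]
        raise ValueError(f"duplicate prediction for endpoint {dup!r}")
    if endpoint_labels is not None:
        endpoint_labels = [str(x) for x in endpoint_labels]
        missing = set(endpoint_labels) - set(series.index)
        if missing:
            raise ValueError(f"no prediction for endpoint(s) {sorted(missing)}")
        series = series.reindex(endpoint_labels)
        labels = endpoint_labels
    return DirectionPredictions(series.to_numpy(), endpoint_labels=labels)


def read_correlation_matrix(path) -> pd.DataFrame:
    """Read a labelled square correlation matrix from TSV/CSV."""
    df = _read_table(path)
    if df.shape[0] != df.shape[1]:
        raise ValueError(
            f"correlation matrix must be square, got {df.shape[0]} rows x "
            f"{df.shape[1]} columns"
        )
    df.index = df.columns
    return df


def write_correlation_matrix(C, path, endpoint_labels=None) -> None:
    C = np.asarray(C, dtype=float)
    labels = (
        [str(x) for x in endpoint_labels]
        if endpoint_labels is not None
        else [f"e{i + 1}" for i in range(C.shape[0])]
    )
    pd.DataFrame(C, columns=labels).to_csv(path, sep="\t", index=False)


def write_distribution(dist, path) -> None:
    """Dump an exact null distribution as two-column (value, probability) TSV."""
    dist.to_frame().to_csv(path, sep="\t", index=False)


def report_dict(
    result: TestResult,
    ols: OlsResult | None = None,
    seed: int | None = None,
) -> dict:
    """JSON-serialisable report of a test run (full precision)."""
    out = {
        "statistic": result.statistic,
        "p_value": result.p_value,
        "method": result.method,
        "phi0": result.phi0,
        "alpha": result.alpha,
        "reject": result.reject,
        "require_T_ge_1": result.require_T_ge_1,
        "m": result.m,
        "W": result.W,
        "n_correct": result.n_correct,
        "weights": [float(x) for x in result.weights],
        "endpoint_labels": (
            list(result.endpoint_labels) if result.endpoint_labels else None
        ),
        "version": __version__,
        "seed": seed,
    }
    if ols is not None:
        out["ols"] = {
            "statistic": ols.statistic,
            "p_value": ols.p_value,
            "df": ols.df,
            "per_endpoint_t": [float(x) for x in ols.per_endpoint_t],
        }
    return out


def write_report(
    result: TestResult,
    path,
    *,
    ols: OlsResult | None = None,
    seed: int | None = None,
) -> dict:
    """Write the JSON report; returns the dict that was written."""
    out = report_dict(result, ols=ols, seed=seed)
    with open(path, "w") as fh:
        json.dump(out, fh, indent=2)
        fh.write("\n")
    return out


def load_config(path) -> dict:
    """Load a YAML mapping of settings (used by `predtest simulate`)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg
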