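"""Readers and writers for the delimited-text formats used throughout.

Matrices are plain TSV/CSV with feature names in the first row and sample
ids in the first column.  Labels are two-column files (sample id, label).
Reports are JSON.  Every writer embeds enough metadata to reproduce a run.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._errors import FormatError, ParameterError


@dataclasses.dataclass
class DataMatrix:
    """A dense samples x features matrix with named rows and columns."""

    values: np.ndarray
    feature_names: list[str]
    sample_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.feature_names = [str(f) for f in self.feature_names]
        self.sample_ids = [str(s) for s in self.sample_ids]
        n, d = self.values.shape
        if len(self.sample_ids) != n or len(self.feature_names) != d:
            raise ParameterError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.sample_ids)} sample ids / {len(self.feature_names)} feature names"
            )
        if len(set(self.feature_names)) != d:
            raise ParameterError("feature names must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("matrix contains non-finite values")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_values(cls, values, feature_names=None, sample_ids=None) -> "DataMatrix":
        values = np.asarray(values, dtype=float)
        if feature_names is None:
            feature_names = [f"f{j}" for j in range(values.shape[1])]
        if sample_ids is None:
            sample_ids = [f"s{i}" for i in range(values.shape[0])]
        return cls(values, list(feature_names), list(sample_ids))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_names)

    def subset_features(self, keep: Sequence[int]) -> "DataMatrix":
        keep = list(keep)
        return DataMatrix(
            self.values[:, keep],
            [self.feature_names[j] for j in keep],
            list(self.sample_ids),
        )


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_matrix(path) -> DataMatrix:
    """Read a delimited matrix: header row of feature names, first column ids."""
    path = Path(path)
    sep = _sep_for(path)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"{path}: could not parse delimited matrix: {exc}") from exc
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no feature columns found (wrong delimiter?)")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.nonzero(bad.values)[0][0]) + 2  # +1 header, +1 1-based
            raise FormatError(
                f"{path}: non-numeric cell in column {col!r} at line {row}"
            )
        df[col] = coerced
    if df.isna().any().any():
        i, j = np.argwhere(df.isna().values)[0]
        raise FormatError(f"{path}: missing value at line {i + 2}, column {df.columns[j]!r}")
    return DataMatrix(df.values.astype(float), list(df.columns), [str(i) for i in df.index])


def write_matrix(path, matrix: DataMatrix) -> None:
    path = Path(path)
    matrix.to_dataframe().to_csv(path, sep=_sep_for(path), index_label="sample_id")


def read_labels(path, sample_ids: Sequence[str] | None = None) -> np.ndarray:
    """Read a two-column (sample id, label) file; align to ``sample_ids``."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if df.shape[1] < 1:
        raise FormatError(f"{path}: expected two columns (sample id, label)")
    series = df.iloc[:, 0].astype(str)
    if sample_ids is None:
        return series.values
    missing = [s for s in sample_ids if s not in series.index]
    if missing:
        raise FormatError(f"{path}: labels missing for sample ids {missing[:10]}")
    return series.loc[list(sample_ids)].values


def write_labels(path, sample_ids: Sequence[str], labels: Sequence) -> None:
    pd.DataFrame({"label": list(labels)}, index=list(sample_ids)).to_csv(
        Path(path), sep=_sep_for(Path(path)), index_label="sample_id"
    )


def write_report(path, report: dict) -> None:
    """Write a JSON report, converting numpy scalars/arrays to plain types."""

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(report, indent=2, default=default) + "\n")


def read_report(path) -> dict:
    return json.loads(Path(path).read_text())
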