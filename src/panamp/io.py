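"""Readers, writers and run configuration.

All tabular inputs are plain TSV: matrices carry a header row of
sample/line identifiers and gene identifiers in the first column, with
``NA`` as the missing-value marker.  Gene positions travel as BED
(0-based, half-open).  Results are written as TSV or JSON.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "RunConfig",
    "read_bed",
    "read_matrix",
    "read_survival_table",
    "write_bed",
    "write_matrix",
]

NA_MARKER = "NA"

MATRIX_KINDS = ("cn", "expr", "effects", "prob")


@dataclass
class RunConfig:
    """Thresholds and reproducibility settings for a pipeline run.

    Every cutoff the pipeline applies lives here, never hard-coded at a call
    site: the amplification threshold on log2(CN/2), the dependency
    probability cutoff, the common-essential rank rule, the FDR level, and
    the minimum group fraction of the survival cutpoint scan.
    """

    seed: int = 0
    amp_threshold: float = 0.3
    dep_threshold: float = 0.5
    top_frac: float = 0.10
    line_frac: float = 0.90
    fdr: float = 0.05
    min_group_frac: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 < self.top_frac <= 1.0 or not 0.0 < self.line_frac <= 1.0:
            raise ValueError("top_frac and line_frac must lie in (0, 1]")
        if not 0.0 < self.fdr < 1.0:
            raise ValueError("fdr must lie in (0, 1)")
        if not 0.0 <= self.min_group_frac < 0.5:
            raise ValueError("min_group_frac must lie in [0, 0.5)")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def read_matrix(path: str | Path, kind: str | None = None) -> pd.DataFrame:
    """Read a gene x sample/line TSV matrix.

    First column holds gene identifiers, header holds sample identifiers,
    ``NA`` marks missing values.  Duplicate identifiers, ragged rows and
    non-numeric cells are rejected with the offending identifier named.
    ``kind='prob'`` additionally checks the [0, 1] range.
    """
    if kind is not None and kind not in MATRIX_KINDS:
        raise ValueError(f"kind must be one of {MATRIX_KINDS}")
    df = pd.read_csv(
        path, sep="\t", index_col=0, na_values=[NA_MARKER], keep_default_na=False
    )
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        line_no = int(np.nonzero(df.index.duplicated())[0][0]) + 2  # header is line 1
        raise ValueError(f"duplicate gene id {dup!r} at line {line_no} of {path}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"duplicate sample id {dup!r} in header of {path}")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
    if kind == "prob":
        vals = df.to_numpy()
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            raise ValueError(f"probability matrix {path} has values outside [0, 1]")
    return df


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", na_rep=NA_MARKER)


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read gene positions from BED (chrom, start, end, gene[, cytoband])."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 4:
        raise ValueError("BED file needs at least 4 columns (chrom start end name)")
    cols = ["chrom", "start", "end", "gene"]
    if df.shape[1] >= 5:
        cols.append("cytoband")
    df = df.iloc[:, : len(cols)]
    df.columns = cols
    if (df["start"] >= df["end"]).any():
        raise ValueError("BED intervals must satisfy start < end")
    return df[["gene", "chrom", "start", "end"] + (["cytoband"] if "cytoband" in cols else [])]


def write_bed(positions: pd.DataFrame, path: str | Path) -> None:
    cols = ["chrom", "start", "end", "gene"]
    if "cytoband" in positions.columns:
        cols.append("cytoband")
    positions[cols].to_csv(path, sep="\t", header=False, index=False)


def read_survival_table(path: str | Path) -> pd.DataFrame:
    """Read a patient table with columns (id, time, event, marker)."""
    df = pd.read_csv(path, sep="\t", na_values=[NA_MARKER], keep_default_na=False)
    required = {"time", "event", "marker"}
    if not required.issubset(df.columns):
        raise ValueError(f"survival table must have columns {sorted(required)}")
    return df
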