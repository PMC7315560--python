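"""Delimited-text I/O for beta matrices, probe sets and parameter tables.

Beta matrices are plain tab- or comma-separated files with probes as
rows: the first column holds probe ids and the header row holds sample
ids.  Sample metadata travels in a separate table with ``sample_id`` and
``age`` columns (plus optional ``group``/``tissue`` labels).  Missing
beta values are written/read as ``NA`` (case-insensitive) or empty cells;
decimal points only.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "BetaMatrix",
    "read_beta_matrix",
    "write_beta_matrix",
    "load_probe_set",
    "read_parameter_table",
    "write_parameter_table",
]

logger = logging.getLogger(__name__)

_NA_VALUES = ["NA", "na", "Na", "nA", "NaN", "nan", ""]
_CLAMP_TOL = 1e-6


@dataclass(frozen=True)
class BetaMatrix:
    """A validated beta-value matrix with per-sample metadata.

    ``values`` is probes x samples in [0, 1] (NaN for missing);
    ``metadata`` is indexed by sample id and carries at least an ``age``
    column (years).
    """

    values: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate probe ids")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        if not self.values.columns.equals(self.metadata.index):
            raise ValueError("metadata must be indexed by the matrix's samples")
        vals = self.values.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.any((vals < 0) | (vals > 1)):
                raise ValueError("beta values must lie in [0, 1]")
        ages = self.metadata["age"]
        if ages.notna().any() and (ages.dropna() <= 0).any():
            raise ValueError("ages must be positive where present")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def ages(self) -> pd.Series:
        return self.metadata["age"]


def _sniff_sep(path: Path, override: str | None) -> str:
    if override:
        return override
    with open(path, newline="") as fh:
        sample = fh.readline()
    try:
        return csv.Sniffer().sniff(sample, delimiters="\t,").delimiter
    except csv.Error:
        return "\t"


def read_beta_matrix(
    path: str | Path,
    metadata_path: str | Path,
    delimiter: str | None = None,
) -> BetaMatrix:
    """Read and validate a beta matrix plus its sample metadata.

    The delimiter (tab or comma) is auto-detected unless given.  Values
    outside [0, 1] by at most 1e-6 are clamped; larger violations raise.
    Samples present in the matrix but absent from the metadata are
    dropped with a warning; no overlap at all is an error.
    """
    path, metadata_path = Path(path), Path(metadata_path)
    sep = _sniff_sep(path, delimiter)
    df = pd.read_csv(
        path, sep=sep, index_col=0, na_values=_NA_VALUES, keep_default_na=False
    )
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique()
        raise ValueError(f"duplicate probe ids: {list(dupes[:5])}")
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cells in {path}: {exc}") from exc

    vals = values.to_numpy()
    with np.errstate(invalid="ignore"):
        below, above = vals < 0.0, vals > 1.0
        too_far = (vals < -_CLAMP_TOL) | (vals > 1.0 + _CLAMP_TOL)
    if np.any(too_far):
        raise ValueError(
            f"{int(np.sum(too_far))} beta values outside [0, 1] by more "
            f"than {_CLAMP_TOL}"
        )
    n_clamped = int(np.sum(below | above))
    if n_clamped:
        logger.warning("clamped %d beta values to [0, 1]", n_clamped)
        values = values.clip(0.0, 1.0)

    meta_sep = _sniff_sep(metadata_path, delimiter)
    meta = pd.read_csv(
        metadata_path, sep=meta_sep, na_values=_NA_VALUES, keep_default_na=False
    )
    if "sample_id" not in meta.columns or "age" not in meta.columns:
        raise ValueError("metadata must have sample_id and age columns")
    meta = meta.set_index("sample_id")
    meta["age"] = pd.to_numeric(meta["age"], errors="coerce")

    overlap = [s for s in values.columns if s in meta.index]
    if not overlap:
        raise ValueError("no samples shared between matrix and metadata")
    dropped = [s for s in values.columns if s not in meta.index]
    if dropped:
        logger.warning(
            "dropping %d matrix samples absent from metadata", len(dropped)
        )
    values = values[overlap]
    meta = meta.loc[overlap]
    return BetaMatrix(values=values, metadata=meta)


def write_beta_matrix(
    matrix: BetaMatrix,
    path: str | Path,
    metadata_path: str | Path,
    delimiter: str = "\t",
) -> None:
    """Write a beta matrix and its metadata; lossless round-trip to 1e-12."""
    matrix.values.to_csv(
        path, sep=delimiter, index_label="probe_id", na_rep="NA",
        float_format="%.17g",
    )
    matrix.metadata.to_csv(
        metadata_path, sep=delimiter, index_label="sample_id", na_rep="NA"
    )


def load_probe_set(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    """Load a probe list, optionally with per-probe delta/beta0 columns.

    Accepts either one probe id per line, or a delimited table with a
    ``probe_id`` header and optional numeric ``delta`` and ``beta0``
    columns.  Returns a DataFrame indexed by probe_id (empty columns when
    the file is a bare list).  Duplicate probes are an error.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
    if "probe_id" in first:
        sep = _sniff_sep(path, delimiter)
        df = pd.read_csv(path, sep=sep, na_values=_NA_VALUES, keep_default_na=False)
        df = df.set_index("probe_id")
        for col in ("delta", "beta0"):
            if col in df.columns:
                df[col] = pd.to_numeric(df[col], errors="raise")
    else:
        probes = [
            line.strip() for line in open(path) if line.strip()
        ]
        df = pd.DataFrame(index=pd.Index(probes, name="probe_id"))
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique()
        raise ValueError(f"duplicate probes in {path}: {list(dupes[:5])}")
    return df


def read_parameter_table(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    """Read a per-probe parameter table (probe_id, delta, beta0, ...)."""
    sep = _sniff_sep(Path(path), delimiter)
    df = pd.read_csv(path, sep=sep, na_values=_NA_VALUES, keep_default_na=False)
    if "probe_id" not in df.columns:
        raise ValueError("parameter table must have a probe_id column")
    df = df.set_index("probe_id")
    if df.index.duplicated().any():
        raise ValueError("duplicate probe ids in parameter table")
    for col in ("delta", "beta0", "ir_site", "rss"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="raise")
    return df


def write_parameter_table(
    table: pd.DataFrame, path: str | Path, delimiter: str = "\t"
) -> None:
    """Write a per-probe parameter table, round-trippable to 1e-12."""
    table.to_csv(
        path, sep=delimiter, index_label="probe_id", na_rep="NA",
        float_format="%.17g",
    )
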