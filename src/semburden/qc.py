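"""Matrix/metadata I/O and quality control.

Matrices are plain TSV files: row identifiers (CpG probes or genes) in the
first column, sample identifiers in the header. In memory a matrix is a
``pandas.DataFrame`` (rows = probes/genes, columns = samples) with ``NaN``
marking missing cells.

The QC chain mirrors the standard methylation-array workflow: mask cells
whose detection p-value exceeds a threshold, drop rows and then columns whose
call rate falls below a minimum, and median-impute the few cells that remain
missing. Expression matrices get the analogous transcript filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "QCConfig",
    "QCReport",
    "MatrixParseError",
    "read_matrix",
    "write_matrix",
    "read_meta",
    "write_meta",
    "apply_detection_mask",
    "filter_call_rate",
    "impute_median",
    "filter_transcripts",
    "select_analysis_samples",
    "run_qc",
]

VALID_GROUPS = {"ID", "NO_ID", "FLARE", "CONTROL"}
VALID_TIMEPOINTS = {"T0", "Tend"}
META_COLUMNS = ["sample_id", "subject_id", "group", "timepoint", "age", "sex"]


class MatrixParseError(ValueError):
    """Raised when a TSV matrix violates the format contract."""


@dataclass(frozen=True)
class QCConfig:
    """Thresholds for the QC chain.

    detection_p_max
        Cells with detection p-value strictly greater than this become missing.
    min_call_rate
        Rows/columns with non-missing fraction strictly below this are removed.
    transcript_max_missing
        Transcripts/samples with missing fraction strictly above this are removed.
    """

    detection_p_max: float = 0.01
    min_call_rate: float = 0.95
    transcript_max_missing: float = 0.05

    def __post_init__(self) -> None:
        for name in ("detection_p_max", "min_call_rate", "transcript_max_missing"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0, 1), got {v!r}")


@dataclass
class QCReport:
    """Identifiers removed at each QC step."""

    masked_cells: int = 0
    removed_rows: list = field(default_factory=list)
    removed_cols: list = field(default_factory=list)
    imputed_cells: int = 0

    def as_dict(self) -> dict:
        return {
            "masked_cells": self.masked_cells,
            "n_removed_rows": len(self.removed_rows),
            "n_removed_cols": len(self.removed_cols),
            "imputed_cells": self.imputed_cells,
        }


def read_matrix(path, kind: str = "beta") -> pd.DataFrame:
    """Read a TSV matrix (row ids in column 1, sample ids in the header).

    ``kind`` is one of ``beta``, ``expression``, ``detection_p``. Empty cells
    and "NA" become missing. Beta and detection-p values are checked against
    [0, 1]; a violation raises :class:`MatrixParseError` naming the cell.
    """
    if kind not in {"beta", "expression", "detection_p"}:
        raise ValueError(f"unknown matrix kind {kind!r}")
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if raw.index.has_duplicates:
        dups = raw.index[raw.index.duplicated()].unique().tolist()
        raise MatrixParseError(f"duplicate row ids: {dups[:5]}")
    if raw.columns.has_duplicates:
        dups = raw.columns[raw.columns.duplicated()].unique().tolist()
        raise MatrixParseError(f"duplicate sample ids: {dups[:5]}")
    df = raw.replace({"": np.nan, "NA": np.nan, "nan": np.nan})
    try:
        df = df.astype(float)
    except ValueError:
        # locate the offending cell for the error message
        for col in df.columns:
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any():
                row = df.index[bad][0]
                raise MatrixParseError(
                    f"non-numeric cell at row {row!r}, column {col!r}: {df.loc[row, col]!r}"
                ) from None
        raise
    if kind in {"beta", "detection_p"}:
        vals = df.to_numpy(dtype=float)
        bad = (vals < 0.0) | (vals > 1.0)
        if np.nansum(bad):
            i, j = np.argwhere(bad & ~np.isnan(vals))[0]
            raise MatrixParseError(
                f"{kind} value outside [0,1] at row {df.index[i]!r}, "
                f"column {df.columns[j]!r}: {vals[i, j]}"
            )
    df.index.name = "id"
    return df


def write_matrix(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out.index.name = "id"
    out.to_csv(path, sep="\t", na_rep="NA")


def read_meta(path) -> pd.DataFrame:
    """Read sample metadata TSV with the required column set."""
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "subject_id": str})
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise MatrixParseError(f"metadata is missing columns: {missing}")
    return validate_meta(meta)


def write_meta(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def validate_meta(meta: pd.DataFrame) -> pd.DataFrame:
    bad_groups = set(meta["group"]) - VALID_GROUPS
    if bad_groups:
        raise MatrixParseError(f"unknown groups in metadata: {sorted(bad_groups)}")
    bad_tp = set(meta["timepoint"]) - VALID_TIMEPOINTS
    if bad_tp:
        raise MatrixParseError(f"unknown timepoints in metadata: {sorted(bad_tp)}")
    if meta.duplicated(["subject_id", "timepoint"]).any():
        raise MatrixParseError("duplicate (subject_id, timepoint) pairs in metadata")
    if (meta["age"] <= 0).any():
        raise MatrixParseError("ages must be positive")
    return meta


def apply_detection_mask(
    beta: pd.DataFrame, detp: pd.DataFrame, cfg: QCConfig | None = None
) -> tuple[pd.DataFrame, int]:
    """Set cells with detection p-value above the threshold to missing.

    Returns the masked matrix and the number of newly masked cells.
    """
    cfg = cfg or QCConfig()
    if not beta.index.equals(detp.index) or not beta.columns.equals(detp.columns):
        raise ValueError("beta and detection-p matrices must share ids in the same order")
    mask = detp.to_numpy(dtype=float) > cfg.detection_p_max
    out = beta.copy()
    vals = out.to_numpy(dtype=float, copy=True)
    n_new = int(np.sum(mask & ~np.isnan(vals)))
    vals[mask] = np.nan
    out.loc[:, :] = vals
    return out, n_new


def filter_call_rate(
    matrix: pd.DataFrame,
    cfg: QCConfig | None = None,
    order: str = "rows_first",
) -> tuple[pd.DataFrame, QCReport]:
    """Drop rows, then columns, whose call rate is strictly below the minimum.

    "Call rate" is the non-missing fraction. The comparison is strict: a row
    at exactly the threshold is retained. ``order`` may be ``rows_first``
    (default) or ``cols_first``.
    """
    cfg = cfg or QCConfig()
    if order not in {"rows_first", "cols_first"}:
        raise ValueError(f"order must be 'rows_first' or 'cols_first', got {order!r}")
    report = QCReport()
    out = matrix

    def _drop(df: pd.DataFrame, axis: int) -> pd.DataFrame:
        rate = df.notna().mean(axis=1 - axis)
        keep = rate >= cfg.min_call_rate
        dropped = list(rate.index[~keep])
        if axis == 0:
            report.removed_rows.extend(dropped)
            return df.loc[keep]
        report.removed_cols.extend(dropped)
        return df.loc[:, keep]

    axes = (0, 1) if order == "rows_first" else (1, 0)
    for ax in axes:
        out = _drop(out, ax)
    if out.shape[0] == 0 or out.shape[1] == 0:
        raise ValueError("call-rate filter removed every row or every column")
    return out, report


def impute_median(matrix: pd.DataFrame) -> pd.DataFrame:
    """Replace missing cells with the row median across samples.

    The median over an even number of values is the mean of the central pair.
    An all-missing row is an error.
    """
    vals = matrix.to_numpy(dtype=float, copy=True)
    all_missing = np.isnan(vals).all(axis=1)
    if all_missing.any():
        raise ValueError(
            f"rows with no observed values cannot be imputed: "
            f"{list(matrix.index[all_missing][:5])}"
        )
    med = np.nanmedian(vals, axis=1)
    idx = np.where(np.isnan(vals))
    vals[idx] = med[idx[0]]
    out = matrix.copy()
    out.loc[:, :] = vals
    return out


def filter_transcripts(
    expr: pd.DataFrame, cfg: QCConfig | None = None, impute: bool = True
) -> tuple[pd.DataFrame, QCReport]:
    """Drop transcripts, then samples, with more than the allowed missing fraction.

    "More than" is strict: a transcript at exactly the threshold is retained.
    Survivors are median-imputed by default.
    """
    cfg = cfg or QCConfig()
    report = QCReport()
    frac = expr.isna().mean(axis=1)
    keep_rows = frac <= cfg.transcript_max_missing
    report.removed_rows = list(expr.index[~keep_rows])
    out = expr.loc[keep_rows]
    frac_c = out.isna().mean(axis=0)
    keep_cols = frac_c <= cfg.transcript_max_missing
    report.removed_cols = list(out.columns[~keep_cols])
    out = out.loc[:, keep_cols]
    if out.shape[0] == 0 or out.shape[1] == 0:
        raise ValueError("transcript filter removed every row or every column")
    if impute:
        report.imputed_cells = int(out.isna().to_numpy().sum())
        out = impute_median(out)
    return out, report


def select_analysis_samples(
    meta: pd.DataFrame, exclude: set[str] | frozenset[str] = frozenset({"FLARE"})
) -> pd.DataFrame:
    """Subset metadata to the analysis groups.

    The discovery contrast excludes acutely flaring patients, leaving the
    inactive-disease (ID) vs reactivated (NO_ID) comparison.
    """
    unknown = set(exclude) - VALID_GROUPS
    if unknown:
        raise ValueError(f"unknown groups in exclude set: {sorted(unknown)}")
    out = meta.loc[~meta["group"].isin(exclude)].reset_index(drop=True)
    if out.empty:
        raise ValueError("no samples remain after group exclusion")
    return out


def run_qc(
    beta: pd.DataFrame,
    detp: pd.DataFrame | None = None,
    cfg: QCConfig | None = None,
    order: str = "rows_first",
) -> tuple[pd.DataFrame, QCReport]:
    """Full methylation QC chain: mask -> call-rate filter -> median imputation."""
    cfg = cfg or QCConfig()
    masked_cells = 0
    if detp is not None:
        beta, masked_cells = apply_detection_mask(beta, detp, cfg)
    out, report = filter_call_rate(beta, cfg, order=order)
    report.masked_cells = masked_cells
    report.imputed_cells = int(out.isna().to_numpy().sum())
    out = impute_median(out)
    return out, report
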