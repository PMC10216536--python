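"""Feature-table conditioning: QC → mean imputation → log → batch scale → winsorize.

The stage order is fixed and enforced; it mirrors the original analysis
protocol for high-content morphometric tables:

1. **QC** — drop cells with no data across all features and features with no
   data across all cells.
2. **Imputation** — remaining missing entries are replaced by the feature
   (column) mean over observed entries.
3. **Log transform** — a signed log1p, ``sign(x)·ln(1+|x|)``, monotone and
   defined for all reals (co-occurrence statistics can be negative).
4. **Batch scaling** — within each staining batch, every feature is centered
   to mean 0 and scaled to unit sample sd, removing batch intensity shifts.
5. **Winsorization** — per-feature quartile fences with multiplier 3; values
   outside the fences are replaced by the adjacent quartile value.

The protocol's printed lower-fence formula reads ``Q1 + 3·IQR``, which places
the lower fence *above* the upper quartile whenever IQR > 0 and would flag
the bulk of a distribution as "lower outliers"; almost surely a sign typo.
The default ``fence_mode="corrected"`` uses ``Q1 − 3·IQR``; the printed form
is retained as ``fence_mode="literal"`` for faithfulness audits.  Quartiles
use linear interpolation throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FENCE_MODES = ("corrected", "literal")


@dataclass
class WinsorizeParams:
    """Per-feature quartiles and fence configuration."""

    q1: pd.Series
    q3: pd.Series
    multiplier: float = 3.0
    fence_mode: str = "corrected"

    @property
    def iqr(self) -> pd.Series:
        return self.q3 - self.q1

    def fences(self) -> tuple[pd.Series, pd.Series]:
        if self.fence_mode == "corrected":
            lower = self.q1 - self.multiplier * self.iqr
        elif self.fence_mode == "literal":
            lower = self.q1 + self.multiplier * self.iqr
        else:
            raise ValueError(f"unknown fence_mode {self.fence_mode!r}")
        upper = self.q3 + self.multiplier * self.iqr
        return lower, upper

    @classmethod
    def from_table(cls, table: pd.DataFrame, multiplier: float = 3.0,
                   fence_mode: str = "corrected") -> "WinsorizeParams":
        if fence_mode not in FENCE_MODES:
            raise ValueError(f"unknown fence_mode {fence_mode!r}")
        return cls(
            q1=table.quantile(0.25, interpolation="linear"),
            q3=table.quantile(0.75, interpolation="linear"),
            multiplier=multiplier,
            fence_mode=fence_mode,
        )


@dataclass
class PreprocessReport:
    """Audit trail of one preprocessing run."""

    n_cells_in: int = 0
    n_cells_out: int = 0
    n_cells_dropped: int = 0
    n_features_dropped: int = 0
    n_imputed: int = 0
    n_winsorized_low: int = 0
    n_winsorized_high: int = 0
    constant_features_by_batch: dict = field(default_factory=dict)
    batch_stats_before: dict = field(default_factory=dict)
    batch_stats_after: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_cells_in": self.n_cells_in,
            "n_cells_out": self.n_cells_out,
            "n_cells_dropped": self.n_cells_dropped,
            "n_features_dropped": self.n_features_dropped,
            "n_imputed": self.n_imputed,
            "n_winsorized_low": self.n_winsorized_low,
            "n_winsorized_high": self.n_winsorized_high,
            "constant_features_by_batch": {
                str(k): list(v) for k, v in self.constant_features_by_batch.items()
            },
            "batch_stats_before": self.batch_stats_before,
            "batch_stats_after": self.batch_stats_after,
        }


def qc_filter(table: pd.DataFrame) -> tuple[pd.DataFrame, PreprocessReport]:
    """Drop all-missing cells (rows) and all-missing features (columns)."""
    if table.empty:
        raise ValueError("qc_filter: empty table")
    report = PreprocessReport(n_cells_in=len(table))
    row_empty = table.isna().all(axis=1)
    col_empty = table.isna().all(axis=0)
    out = table.loc[~row_empty, ~col_empty]
    report.n_cells_dropped = int(row_empty.sum())
    report.n_features_dropped = int(col_empty.sum())
    report.n_cells_out = len(out)
    if out.empty:
        raise ValueError("no cells survive QC")
    return out, report


def impute_mean(table: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Replace missing entries by the column mean over observed entries."""
    all_missing = table.isna().all(axis=0)
    if all_missing.any():
        cols = list(table.columns[all_missing])
        raise ValueError(
            f"impute_mean called with all-missing feature(s) {cols[:5]}; "
            "run qc_filter first"
        )
    n_missing = int(table.isna().sum().sum())
    return table.fillna(table.mean()), n_missing


def log_transform(table: pd.DataFrame) -> pd.DataFrame:
    """Signed log1p: sign(x)·ln(1+|x|), elementwise."""
    arr = table.to_numpy(dtype=float)
    return pd.DataFrame(np.sign(arr) * np.log1p(np.abs(arr)),
                        index=table.index, columns=table.columns)


def batch_scale(
    table: pd.DataFrame, batch_labels: pd.Series
) -> tuple[pd.DataFrame, dict]:
    """Within-batch z-scoring of every feature (sample sd, ddof=1).

    Features constant within a batch scale to 0 there and are reported.
    """
    batch_labels = pd.Series(batch_labels).reindex(table.index)
    if batch_labels.isna().any():
        missing = list(table.index[batch_labels.isna()])
        raise ValueError(f"cells without batch label: {missing[:5]}")
    sizes = batch_labels.value_counts()
    small = sizes[sizes < 2]
    if not small.empty:
        raise ValueError(
            f"batch(es) of size < 2: {sorted(small.index.tolist())}"
        )
    grouped = table.groupby(batch_labels)
    mean = grouped.transform("mean")
    sd = grouped.transform(lambda s: s.std(ddof=1))
    constant = {}
    for b, sub in table.groupby(batch_labels):
        const_cols = sub.columns[sub.std(ddof=1).fillna(0.0) == 0.0]
        if len(const_cols):
            constant[b] = list(const_cols)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (table - mean) / sd
    out = out.where(sd > 0, 0.0)
    return out, constant


def winsorize_iqr(
    table: pd.DataFrame, params: WinsorizeParams
) -> tuple[pd.DataFrame, int, int]:
    """Replace values outside the quartile fences by the adjacent quartile."""
    lower, upper = params.fences()
    below = table.lt(lower, axis=1)
    above = table.gt(upper, axis=1)
    out = table.mask(below, params.q1, axis=1).mask(above, params.q3, axis=1)
    return out, int(below.sum().sum()), int(above.sum().sum())


_STAGES = ("qc", "impute", "log", "batch_scale", "winsorize")


class Preprocessor:
    """Runs the five stages in their fixed order; out-of-order calls raise."""

    def __init__(self, fence_mode: str = "corrected", multiplier: float = 3.0):
        if fence_mode not in FENCE_MODES:
            raise ValueError(f"unknown fence_mode {fence_mode!r}")
        self.fence_mode = fence_mode
        self.multiplier = multiplier
        self._done: list[str] = []
        self.report = PreprocessReport()
        self.params: WinsorizeParams | None = None

    def _check_order(self, stage: str) -> None:
        expected = _STAGES[len(self._done)]
        if stage != expected:
            raise RuntimeError(
                f"preprocessing stage {stage!r} called out of order; "
                f"expected {expected!r} (done: {self._done})"
            )
        self._done.append(stage)

    def qc(self, table: pd.DataFrame) -> pd.DataFrame:
        self._check_order("qc")
        out, rep = qc_filter(table)
        self.report.n_cells_in = rep.n_cells_in
        self.report.n_cells_out = rep.n_cells_out
        self.report.n_cells_dropped = rep.n_cells_dropped
        self.report.n_features_dropped = rep.n_features_dropped
        return out

    def impute(self, table: pd.DataFrame) -> pd.DataFrame:
        self._check_order("impute")
        out, n = impute_mean(table)
        self.report.n_imputed = n
        return out

    def log(self, table: pd.DataFrame) -> pd.DataFrame:
        self._check_order("log")
        return log_transform(table)

    def scale(self, table: pd.DataFrame, batch_labels: pd.Series) -> pd.DataFrame:
        self._check_order("batch_scale")
        self.report.batch_stats_before = _batch_summary(table, batch_labels)
        out, constant = batch_scale(table, batch_labels)
        self.report.constant_features_by_batch = constant
        self.report.batch_stats_after = _batch_summary(out, batch_labels)
        if constant:
            warnings.warn(
                f"features constant within batch(es) {sorted(constant)} "
                "were set to 0", stacklevel=2)
        return out

    def winsorize(self, table: pd.DataFrame) -> pd.DataFrame:
        self._check_order("winsorize")
        self.params = WinsorizeParams.from_table(
            table, multiplier=self.multiplier, fence_mode=self.fence_mode)
        out, n_low, n_high = winsorize_iqr(table, self.params)
        self.report.n_winsorized_low = n_low
        self.report.n_winsorized_high = n_high
        return out

    def run(self, table: pd.DataFrame,
            batch_labels: pd.Series) -> tuple[pd.DataFrame, PreprocessReport]:
        out = self.qc(table)
        batch_labels = pd.Series(batch_labels).reindex(out.index)
        out = self.impute(out)
        out = self.log(out)
        out = self.scale(out, batch_labels)
        out = self.winsorize(out)
        return out, self.report


def _batch_summary(table: pd.DataFrame, batch_labels: pd.Series) -> dict:
    out = {}
    for b, sub in table.groupby(pd.Series(batch_labels).reindex(table.index)):
        out[str(b)] = {
            "n_cells": int(len(sub)),
            "grand_mean": float(np.nanmean(sub.to_numpy())),
            "grand_sd": float(np.nanstd(sub.to_numpy())),
        }
    return out


def preprocess_table(
    table: pd.DataFrame,
    batch_labels: pd.Series,
    fence_mode: str = "corrected",
) -> tuple[pd.DataFrame, PreprocessReport]:
    """Run the full conditioning chain in its fixed order."""
    return Preprocessor(fence_mode=fence_mode).run(table, batch_labels)
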