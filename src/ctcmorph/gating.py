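"""In-silico FACS gating: quantile gates on size and mitochondrial proxies.

The sorting strategy this emulates classifies cells by fluorescence alone:
the smallest 10% of cells are "Small", the largest 10% "Large"; Small cells
are split by Mito-Tracker signal into "Small/High" (top 10% of mitochondrial
signal — SLR-like) and "Small/Low" (lowest 40% — SSR-like).  Small cells in
neither mitochondrial gate are left ungated, mirroring the sorter's discarded
middle; "Large" corresponds to LSS.

FACS measures whole-cell fluorescence, so the default proxies are the
integrated cytoplasm-channel intensity (size) and the integrated
mitochondria-channel intensity (mitochondrial signal).  The mitochondrial
quantiles are computed over all cells by default; ``mito_ref="small"``
restricts the reference population to the Small gate, since the protocol's
phrasing supports either reading.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GATE_LABELS = ("Small/High", "Small/Low", "Large", "ungated")


@dataclass(frozen=True)
class GateConfig:
    """Quantile gates and proxy feature names."""

    size_low_q: float = 0.10
    size_high_q: float = 0.90
    mito_high_q: float = 0.90
    mito_low_q: float = 0.40
    size_proxy: str = "intensity_cytoplasm"
    mito_proxy: str = "intensity_mitochondria"
    mito_ref: str = "all"   # "all" | "small"

    def __post_init__(self):
        if not (0.0 < self.size_low_q < self.size_high_q < 1.0):
            raise ValueError("need 0 < size_low_q < size_high_q < 1")
        if not (0.0 < self.mito_low_q <= self.mito_high_q < 1.0):
            raise ValueError("need 0 < mito_low_q <= mito_high_q < 1")
        if self.mito_ref not in ("all", "small"):
            raise ValueError(f"unknown mito_ref {self.mito_ref!r}")


@dataclass
class GateResult:
    labels: pd.Series                  # cell_id -> gate label
    thresholds: dict[str, float]
    fractions: dict[str, float] = field(default_factory=dict)
    #: Fractions passing the raw size gates, before the mitochondrial split.
    size_gate_fractions: dict[str, float] = field(default_factory=dict)
    degenerate: bool = False

    def __post_init__(self):
        counts = self.labels.value_counts()
        n = len(self.labels)
        self.fractions = {
            lab: float(counts.get(lab, 0)) / n if n else 0.0
            for lab in GATE_LABELS
        }


def apply_gates(table: pd.DataFrame, config: GateConfig | None = None) -> GateResult:
    """Classify every cell into Small/High, Small/Low, Large or ungated.

    ``table`` must carry the proxy columns named in the config with no
    missing values; quantile cutoffs use linear interpolation.  If every cell
    ties on the size proxy the gates are degenerate: all cells come back
    ungated with a warning.
    """
    config = config or GateConfig()
    n = len(table)
    if n < 20:
        raise ValueError(f"gating needs >= 20 cells (got {n}): quantiles unstable")
    for proxy in (config.size_proxy, config.mito_proxy):
        if proxy not in table.columns:
            raise ValueError(f"proxy column {proxy!r} missing from table")
        bad = table.index[table[proxy].isna()]
        if len(bad):
            raise ValueError(
                f"missing {proxy!r} values for cells {list(bad[:5])}"
            )
    size = table[config.size_proxy].to_numpy(dtype=float)
    mito = table[config.mito_proxy].to_numpy(dtype=float)

    size_low = float(np.quantile(size, config.size_low_q))
    size_high = float(np.quantile(size, config.size_high_q))
    thresholds = {"size_low": size_low, "size_high": size_high}

    labels = pd.Series("ungated", index=table.index, name="gate")
    if size_low == size_high:
        warnings.warn(
            "degenerate size gates (all cells tie); every cell ungated",
            stacklevel=2)
        return GateResult(labels, thresholds, degenerate=True,
                          size_gate_fractions={"Small": 0.0, "Large": 0.0})

    small = size <= size_low
    large = size >= size_high
    mito_ref = mito[small] if config.mito_ref == "small" else mito
    mito_high = float(np.quantile(mito_ref, config.mito_high_q))
    mito_low = float(np.quantile(mito_ref, config.mito_low_q))
    thresholds.update({"mito_high": mito_high, "mito_low": mito_low})

    labels[large] = "Large"
    labels[small & (mito >= mito_high)] = "Small/High"
    labels[small & (mito <= mito_low)] = "Small/Low"

    for name, arr, cut in (("size_low", size, size_low),
                           ("size_high", size, size_high)):
        n_tied = int((arr == cut).sum())
        if n_tied > 1:
            warnings.warn(f"{n_tied} cells tie at the {name} cutoff",
                          stacklevel=2)
    return GateResult(
        labels, thresholds,
        size_gate_fractions={"Small": float(small.mean()),
                             "Large": float(large.mean())})


def apply_gates_by_batch(
    table: pd.DataFrame,
    batch_labels: pd.Series,
    config: GateConfig | None = None,
) -> GateResult:
    """Gate each staining batch separately and pool the labels.

    A sort is one cytometer run: quantile gates are set per run, which also
    makes them invariant to multiplicative staining-batch shifts.  The
    returned thresholds are keyed by batch.
    """
    config = config or GateConfig()
    batch_labels = pd.Series(batch_labels).reindex(table.index)
    if batch_labels.isna().any():
        missing = list(table.index[batch_labels.isna()])
        raise ValueError(f"cells without batch label: {missing[:5]}")
    labels, thresholds = [], {}
    n_small = n_large = 0
    degenerate = False
    for b, sub in table.groupby(batch_labels):
        res = apply_gates(sub, config)
        labels.append(res.labels)
        thresholds[str(b)] = res.thresholds
        n_small += res.size_gate_fractions["Small"] * len(sub)
        n_large += res.size_gate_fractions["Large"] * len(sub)
        degenerate |= res.degenerate
    pooled = pd.concat(labels).reindex(table.index)
    return GateResult(
        pooled, thresholds, degenerate=degenerate,
        size_gate_fractions={"Small": n_small / len(table),
                             "Large": n_large / len(table)})


#: Gate label → the imaging archetype it is meant to capture.
GATE_TO_ARCHETYPE = {"Small/High": "SLR", "Small/Low": "SSR", "Large": "LSS"}


@dataclass
class ConcordanceReport:
    crosstab: pd.DataFrame              # gate label × archetype counts
    purity: dict[str, float]            # per gate: fraction of target archetype
    recall: dict[str, float]            # per gate: fraction of target captured

    def to_dict(self) -> dict:
        return {
            "crosstab": {str(k): v for k, v in
                         self.crosstab.to_dict(orient="index").items()},
            "purity": self.purity,
            "recall": self.recall,
        }


def validate_gates_vs_imaging(
    gate_labels: pd.Series, archetypes: pd.Series
) -> ConcordanceReport:
    """Cross-tabulate gate labels against image-derived archetypes.

    Purity of a gate is the fraction of its cells whose archetype is the one
    the gate targets; recall is the fraction of that archetype's cells the
    gate captures.  Gates with no cells (or absent archetypes) give NaN.
    """
    common = gate_labels.index.intersection(archetypes.index)
    if len(common) == 0:
        raise ValueError("gate and archetype results cover disjoint cell sets")
    g = gate_labels.loc[common]
    a = archetypes.loc[common]
    crosstab = pd.crosstab(g, a)
    purity, recall = {}, {}
    for gate, target in GATE_TO_ARCHETYPE.items():
        in_gate = g == gate
        is_target = a == target
        purity[gate] = (
            float((in_gate & is_target).sum() / in_gate.sum())
            if in_gate.any() else float("nan"))
        recall[gate] = (
            float((in_gate & is_target).sum() / is_target.sum())
            if is_target.any() else float("nan"))
    return ConcordanceReport(crosstab, purity, recall)
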