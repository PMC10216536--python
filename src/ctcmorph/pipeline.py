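"""End-to-end study pipeline: simulate → extract → preprocess → cluster → gate.

A single global seed fans out to per-stage seeds through
``numpy.random.SeedSequence(seed).spawn``, so each stage is independently
rerunnable and the whole run is bit-reproducible.  :func:`run_study` executes
the chain in memory (features are extracted streamingly, one cell at a time,
so image data never accumulates); :func:`run_pipeline` additionally persists
every stage's tables, reports and a manifest of content hashes that makes a
rerun checkable byte for byte.

The FACS-emulation stage gates on the integrated cytoplasm and mitochondria
channel intensities of a single staining batch by default (a sort is one
cytometer run); gating across batches is available but conflates staining
scale with cell size.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pathlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import features as feat
from . import registry as reg
from . import synthgen
from .gating import ConcordanceReport, GateConfig, GateResult, \
    apply_gates_by_batch, validate_gates_vs_imaging
from .preprocess import PreprocessReport, preprocess_table
from .subtype import SubtypeResult, discover_subtypes

_STAGE_NAMES = ("simulate", "extract", "preprocess", "cluster", "gate")


def stage_seeds(seed: int) -> dict[str, int]:
    """Deterministic per-stage integer seeds derived from one global seed."""
    children = np.random.SeedSequence(seed).spawn(len(_STAGE_NAMES))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(_STAGE_NAMES, children)
    }


@dataclass
class PipelineConfig:
    """One reproducible pipeline run: cohort, gates, flags, global seed."""

    cohort: synthgen.CohortConfig = field(
        default_factory=synthgen.CohortConfig)
    gate: GateConfig = field(default_factory=GateConfig)
    fence_mode: str = "corrected"
    k: int | None = None          # None = select by silhouette
    linkage: str = "ward"
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "cohort": synthgen.config_to_dict(self.cohort),
            "gate": dataclasses.asdict(self.gate),
            "fence_mode": self.fence_mode,
            "k": self.k,
            "linkage": self.linkage,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        cohort = synthgen.config_from_dict(d.pop("cohort", {}))
        gate = GateConfig(**d.pop("gate", {}))
        return cls(cohort=cohort, gate=gate, **d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class StudyResult:
    config: PipelineConfig
    truth: pd.DataFrame
    features: pd.DataFrame           # metadata + 500 features
    preprocessed: pd.DataFrame
    preprocess_report: PreprocessReport
    subtypes: SubtypeResult
    gates: GateResult | None
    concordance: ConcordanceReport | None

    def archetype_fractions(self) -> dict[str, float]:
        """Fraction of cells in each archetype-labeled cluster."""
        per_cell = self.subtypes.archetype_assignment
        return per_cell.value_counts(normalize=True).to_dict()


def run_study(config: PipelineConfig, gate_cells: bool = True) -> StudyResult:
    """Execute the full chain in memory and return every stage's result."""
    seeds = stage_seeds(config.seed)
    cohort_cfg = dataclasses.replace(config.cohort, seed=seeds["simulate"])

    # Single streaming pass: each rendered cell is reduced to its feature row
    # and truth row, then freed.
    truth_rows: list[dict] = []

    def _stream():
        for cell in synthgen.iter_cohort(cohort_cfg):
            truth_rows.append(synthgen.truth_row(cell))
            yield cell

    features = feat.assemble_feature_table(_stream())
    truth = pd.DataFrame(truth_rows, columns=list(synthgen.TRUTH_COLUMNS))
    meta, matrix = feat.split_meta(features)

    clean, report = preprocess_table(
        matrix, meta["batch"], fence_mode=config.fence_mode)
    meta = meta.loc[clean.index]

    n = len(clean)
    k_range = range(2, min(10, n - 1) + 1)
    if k_range.stop < 11:
        warnings.warn(f"k search range clamped to {k_range} for n={n} cells",
                      stacklevel=2)
    subtypes = discover_subtypes(
        clean, k=config.k, k_range=k_range, method=config.linkage)

    gates = concordance = None
    if gate_cells:
        indexed = truth.set_index("cell_id")
        min_batch = int(indexed["batch"].value_counts().min())
        if min_batch < 20:
            warnings.warn(
                f"smallest staining batch has {min_batch} cells (< 20); "
                "skipping the FACS-emulation stage", stacklevel=2)
        else:
            proxies = indexed[[config.gate.size_proxy, config.gate.mito_proxy]]
            gates = apply_gates_by_batch(proxies, indexed["batch"],
                                         config.gate)
            concordance = validate_gates_vs_imaging(
                gates.labels, indexed["archetype"])
    return StudyResult(
        config=config,
        truth=truth,
        features=features,
        preprocessed=clean,
        preprocess_report=report,
        subtypes=subtypes,
        gates=gates,
        concordance=concordance,
    )


def facs_cohort_config(n_cells: int = 1000, seed: int = 0,
                       **overrides) -> synthgen.CohortConfig:
    """A single-staining-batch cohort, as a FACS sort sees it."""
    return synthgen.CohortConfig(
        n_cells=n_cells, n_batches=1, batch_factors=(1.0,), seed=seed,
        **overrides)


# ---------------------------------------------------------------------------
# Persisted runs


def _sha256(path: pathlib.Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, outdir,
                 write_images: bool = False) -> pathlib.Path:
    """Run the study and persist every stage under ``outdir``.

    Writes the truth table, feature table, preprocessed table, assignments,
    group statistics, pairwise tests, gate labels, stage reports and a
    ``manifest.json`` recording the package version, per-stage seeds and the
    SHA-256 of every written file.  Identical config + seed reproduce the
    manifest exactly.
    """
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result = run_study(config)

    config.to_yaml(outdir / "config.yaml")
    reg.save_registry(outdir / "registry.yaml")
    result.truth.to_csv(outdir / "truth.csv", index=False)
    feat.write_feature_table(result.features, outdir / "features.csv")
    feat.write_feature_table(result.preprocessed, outdir / "preprocessed.csv")

    sub = result.subtypes
    assign = pd.DataFrame({
        "cluster": sub.assignment,
        "archetype": sub.archetype_assignment,
    })
    assign.to_csv(outdir / "assignments.csv")
    sub.group_stats.to_csv(outdir / "group_stats.csv")
    sub.tests.to_csv(outdir / "tests.csv", index=False)
    diagnostics = {
        "k_optimal": sub.k_optimal,
        "silhouette_curve": {str(k): v for k, v in sub.silhouette_curve.items()},
        "proportions": {str(k): float(v) for k, v in sub.proportions.items()},
        "archetype_labels": {str(k): v for k, v in sub.archetype_labels.items()},
        "pca_explained_variance_ratio": (
            [float(x) for x in sub.pca.explained_variance_ratio[:10]]
            if sub.pca is not None else None),
        "preprocess_report": result.preprocess_report.to_dict(),
        "flags": {"fence_mode": config.fence_mode,
                  "mito_ref": config.gate.mito_ref,
                  "linkage": config.linkage},
    }
    with open(outdir / "diagnostics.json", "w") as fh:
        json.dump(diagnostics, fh, indent=2, sort_keys=True)

    if result.gates is not None:
        result.gates.labels.to_frame().to_csv(outdir / "gates.csv")
        gate_info = {"thresholds": result.gates.thresholds,
                     "fractions": result.gates.fractions,
                     "concordance": result.concordance.to_dict()}
        with open(outdir / "gate_report.json", "w") as fh:
            json.dump(gate_info, fh, indent=2, sort_keys=True)

    if write_images:
        cohort_cfg = dataclasses.replace(
            config.cohort, seed=stage_seeds(config.seed)["simulate"])
        synthgen.write_cohort(list(synthgen.iter_cohort(cohort_cfg)),
                              outdir / "images")

    manifest = {
        "package": "ctcmorph",
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": stage_seeds(config.seed),
        "files": {
            p.name: _sha256(p)
            for p in sorted(outdir.glob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return outdir
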