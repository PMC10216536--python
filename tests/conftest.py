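"""Shared fixtures: expensive cohorts are built once per session."""

from __future__ import annotations

import warnings

import pandas as pd
import pytest

from ctcmorph import synthgen as sg
from ctcmorph.pipeline import PipelineConfig, facs_cohort_config, run_study

#: Seeds of the replicate end-to-end study runs examined by the test suite.
STUDY_SEEDS = (1, 2, 3)


@pytest.fixture(scope="session")
def study_runs():
    """Full pipeline runs of the default 500-cell cohort, one per seed."""
    runs = {}
    for seed in STUDY_SEEDS:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            runs[seed] = run_study(PipelineConfig(seed=seed))
    return runs


@pytest.fixture(scope="session")
def small_cohort():
    """A 40-cell default-mixture cohort kept fully in memory (with masks)."""
    cfg = sg.CohortConfig(n_cells=40, seed=7)
    cells, truth = sg.sample_cohort(cfg)
    return cfg, cells, truth


@pytest.fixture(scope="session")
def noisefree_cohort():
    """50 noise-free cells, equal archetype weights, for oracle comparisons.

    Equal weights guarantee all three shape regimes are represented; the
    oracle checks are per cell, so the mixture itself is irrelevant here.
    """
    import dataclasses

    archetypes = [dataclasses.replace(a, weight=1 / 3)
                  for a in sg.default_archetypes()]
    cfg = sg.CohortConfig(n_cells=50, seed=13, noise_sd=0.0, n_batches=1,
                          batch_factors=(1.0,), archetypes=archetypes)
    cells, truth = sg.sample_cohort(cfg)
    return cfg, cells, truth


@pytest.fixture(scope="session")
def facs_truth():
    """Ground-truth table of a 1000-cell single-batch cohort (gating proxies)."""
    cfg = facs_cohort_config(n_cells=1000, seed=4)
    rows = [sg.truth_row(c) for c in sg.iter_cohort(cfg)]
    return pd.DataFrame(rows, columns=list(sg.TRUTH_COLUMNS)).set_index("cell_id")
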