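#!/usr/bin/env python
"""Discover the morphometric subtypes and characterize them.

Reads results/preprocessed.csv, selects the number of groups by mean
silhouette width over cuts of the agglomerative tree (Main Features only),
maps the three-group solution to the SLR/SSR/LSS archetypes, and compares
the headline ratio features across groups with Student's t-tests.

Outputs: results/assignments.csv, results/group_stats.csv,
results/subtype_tests.csv, results/subtype_diagnostics.json.
"""

import json
import pathlib
import warnings

import pandas as pd

from ctcmorph import features as ft
from ctcmorph.subtype import discover_subtypes

ROOT = pathlib.Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"

HEADLINE = ["cell_volume", "ratio_nuc_cell_volume", "ratio_mito_cell_volume",
            "ratio_densenuc_nuc_volume", "cell_boundary_roughness"]


def main() -> None:
    warnings.filterwarnings("ignore")
    clean = ft.read_feature_table(RESULTS / "preprocessed.csv")
    truth = pd.read_csv(RESULTS / "truth.csv").set_index("cell_id")

    result = discover_subtypes(clean)
    print(f"optimal k = {result.k_optimal} "
          f"(silhouette {result.silhouette_curve[result.k_optimal]:.3f})")
    labels = result.archetype_assignment
    fractions = labels.value_counts(normalize=True)
    print("archetype-mapped cluster fractions:",
          {k: f"{100 * v:.1f}%" for k, v in fractions.items()})

    crosstab = pd.crosstab(truth.loc[labels.index, "archetype"], labels)
    print("clusters vs ground truth:")
    print(crosstab)

    pd.DataFrame({"cluster": result.assignment, "archetype": labels}) \
        .to_csv(RESULTS / "assignments.csv")
    result.group_stats.to_csv(RESULTS / "group_stats.csv")
    result.tests.to_csv(RESULTS / "subtype_tests.csv", index=False)
    with open(RESULTS / "subtype_diagnostics.json", "w") as fh:
        json.dump({
            "k_optimal": result.k_optimal,
            "silhouette_curve": {str(k): v
                                 for k, v in result.silhouette_curve.items()},
            "archetype_labels": {str(k): v
                                 for k, v in result.archetype_labels.items()},
            "pca_explained_variance_ratio":
                [float(x) for x in result.pca.explained_variance_ratio[:5]],
        }, fh, indent=2, sort_keys=True)

    inv = {v: k for k, v in result.archetype_labels.items()}
    t = result.tests
    print("headline feature z-score means per archetype "
          "(and SLR-vs-SSR raw p):")
    for feature in HEADLINE:
        means = {a: result.group_stats.loc[c, feature]
                 for a, c in inv.items()}
        row = t[(t.feature == feature)
                & (t.cluster_a.isin([inv['SLR'], inv['SSR']]))
                & (t.cluster_b.isin([inv['SLR'], inv['SSR']]))]
        p = float(row["p_raw"].iloc[0])
        print(f"  {feature}: "
              + " ".join(f"{a}={means[a]:+.2f}" for a in ("SLR", "SSR", "LSS"))
              + f"  p={p:.2e}")


if __name__ == "__main__":
    main()
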