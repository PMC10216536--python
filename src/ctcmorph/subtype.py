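"""Morphometric subtype discovery: PCA, optimal k, tree cut, group stats.

Clustering operates on the *Main Features* (every registry feature except
granularity and texture) of the preprocessed table, using agglomerative
clustering on Euclidean distances.  Ward linkage is the default: on z-scored
morphometric tables it recovers compact subpopulations far more reliably
than the complete linkage that heatmap tools default to, which tends to
siphon the larger cells of a small-cell subtype into the large-cell cluster;
``method`` accepts any scipy linkage.  The number of groups is
chosen by mean silhouette width over cuts of the same tree (k = 2..10), and
the three-group solution is mapped onto the named archetypes by a
deterministic rule operationalizing their cartoon definitions:

* **LSS** — the cluster with the largest mean cell volume;
* **SLR** — of the remaining two, the one with the higher mean Mito/Cell
  volume ratio;
* **SSR** — the other.

Group characterization reports per-cluster mean feature values (z-scores on
the preprocessed scale) and pairwise two-sided Student's t-tests with raw
p-values — no multiple-testing correction is applied, and the output says so.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from . import registry as reg

ARCHETYPES = ("SLR", "SSR", "LSS")

#: Features driving the archetype-labeling rule.
VOLUME_FEATURE = "cell_volume"
MITO_RATIO_FEATURE = "ratio_mito_cell_volume"

SIGNIFICANCE_LEVEL = 0.05


@dataclass
class PCAResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray


@dataclass
class SubtypeResult:
    k_optimal: int
    assignment: pd.Series                 # cell_id -> cluster id (1..k)
    archetype_labels: dict[int, str]      # cluster id -> SLR/SSR/LSS/unlabeled
    proportions: pd.Series                # cluster id -> fraction
    group_stats: pd.DataFrame             # clusters × features, mean values
    tests: pd.DataFrame                   # feature × cluster-pair t statistics
    pca: PCAResult | None = None
    silhouette_curve: dict[int, float] = field(default_factory=dict)

    @property
    def archetype_assignment(self) -> pd.Series:
        """Per-cell archetype name (or 'unlabeled')."""
        return self.assignment.map(self.archetype_labels)


def main_feature_columns(table: pd.DataFrame) -> list[str]:
    """Main-Feature columns present in the table, registry order."""
    cols = [n for n in reg.main_feature_names() if n in table.columns]
    if not cols:
        raise ValueError("table has no Main-Feature columns")
    return cols


def pca_embed(table: pd.DataFrame, feature_set: str = "main") -> PCAResult:
    """Centered PCA of the table, on all features or Main Features only."""
    if len(table) < 3:
        raise ValueError("PCA needs at least 3 cells")
    if feature_set == "main":
        cols = main_feature_columns(table)
    elif feature_set == "all":
        cols = list(table.columns)
    else:
        raise ValueError(f"unknown feature_set {feature_set!r}")
    X = table[cols].to_numpy(dtype=float)
    n_comp = min(len(table) - 1, len(cols))
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(X)
    comp_names = [f"PC{i + 1}" for i in range(n_comp)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=table.index, columns=comp_names),
        loadings=pd.DataFrame(pca.components_.T, index=cols, columns=comp_names),
        explained_variance_ratio=pca.explained_variance_ratio_,
    )


def _linkage_tree(X: np.ndarray, method: str = "ward") -> np.ndarray:
    return linkage(X, method=method, metric="euclidean")


def cluster_cut(table: pd.DataFrame, k: int,
                method: str = "ward") -> pd.Series:
    """Cut the agglomerative tree over Main Features into k groups."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(table):
        raise ValueError(f"k={k} exceeds the number of cells ({len(table)})")
    X = table[main_feature_columns(table)].to_numpy(dtype=float)
    labels = fcluster(_linkage_tree(X, method), t=k, criterion="maxclust")
    return pd.Series(labels, index=table.index, name="cluster")


def optimal_k(
    table: pd.DataFrame,
    k_range: range = range(2, 11),
    method: str = "ward",
) -> tuple[int, dict[int, float]]:
    """Mean silhouette width over hierarchical cuts; returns argmax and curve."""
    ks = [k for k in k_range if 2 <= k <= len(table) - 1]
    if not ks:
        raise ValueError(
            f"k_range {k_range!r} incompatible with {len(table)} cells")
    X = table[main_feature_columns(table)].to_numpy(dtype=float)
    if np.allclose(X, X[0], atol=1e-12):
        raise ValueError("degenerate distance matrix: all cells identical")
    tree = _linkage_tree(X, method)
    curve: dict[int, float] = {}
    for k in ks:
        labels = fcluster(tree, t=k, criterion="maxclust")
        if len(np.unique(labels)) < 2:
            curve[k] = np.nan
            continue
        curve[k] = float(silhouette_score(X, labels, metric="euclidean"))
    best = max((k for k in curve if np.isfinite(curve[k])),
               key=lambda k: curve[k])
    return best, curve


def characterize_groups(
    table: pd.DataFrame, assignment: pd.Series
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cluster feature means and pairwise two-sided Student's t-tests.

    Clusters of size 1 are excluded from testing (with a warning).  p-values
    are raw: the protocol applies no multiple-testing correction, and the
    output column is named accordingly.
    """
    assignment = assignment.reindex(table.index)
    group_stats = table.groupby(assignment).mean()
    group_stats.index.name = "cluster"

    sizes = assignment.value_counts()
    testable = sorted(sizes[sizes >= 2].index)
    if len(testable) < len(sizes):
        warnings.warn(
            f"cluster(s) of size 1 excluded from tests: "
            f"{sorted(set(sizes.index) - set(testable))}", stacklevel=2)
    rows = []
    for a, b in itertools.combinations(testable, 2):
        xa = table[assignment == a].to_numpy(dtype=float)
        xb = table[assignment == b].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            t, p = stats.ttest_ind(xa, xb, axis=0)  # pooled-variance Student
        for j, feat in enumerate(table.columns):
            rows.append((feat, a, b, float(t[j]), float(p[j])))
    tests = pd.DataFrame(
        rows, columns=["feature", "cluster_a", "cluster_b", "t", "p_raw"])
    tests["significant"] = tests["p_raw"] < SIGNIFICANCE_LEVEL
    return group_stats, tests


def label_archetypes(group_stats: pd.DataFrame) -> dict[int, str]:
    """Map the three-cluster solution onto SLR/SSR/LSS (else all unlabeled).

    LSS is the cluster with maximal mean cell volume; of the remaining two,
    SLR has the higher mean Mito/Cell volume ratio.  An exact volume tie is
    broken toward the cluster with the *lower* Mito/Cell ratio (and logged).
    """
    clusters = list(group_stats.index)
    if len(clusters) != 3:
        return {c: "unlabeled" for c in clusters}
    vol = group_stats[VOLUME_FEATURE]
    mito = group_stats[MITO_RATIO_FEATURE]
    vmax = vol.max()
    top = [c for c in clusters if vol[c] == vmax]
    if len(top) > 1:
        warnings.warn(
            f"exact tie on mean cell volume between clusters {top}; "
            "breaking toward lower Mito/Cell ratio", stacklevel=2)
        lss = min(top, key=lambda c: (mito[c], c))
    else:
        lss = top[0]
    rest = [c for c in clusters if c != lss]
    slr = max(rest, key=lambda c: (mito[c], -c))
    ssr = next(c for c in rest if c != slr)
    return {lss: "LSS", slr: "SLR", ssr: "SSR"}


def discover_subtypes(
    table: pd.DataFrame,
    k: int | None = None,
    k_range: range = range(2, 11),
    method: str = "ward",
    with_pca: bool = True,
) -> SubtypeResult:
    """The full subtype-discovery chain on a preprocessed feature table."""
    curve: dict[int, float] = {}
    if k is None:
        k, curve = optimal_k(table, k_range=k_range, method=method)
    assignment = cluster_cut(table, k, method=method)
    proportions = assignment.value_counts(normalize=True).sort_index()
    group_stats, tests = characterize_groups(table, assignment)
    labels = label_archetypes(group_stats)
    pca = pca_embed(table, feature_set="main") if with_pca else None
    return SubtypeResult(
        k_optimal=k,
        assignment=assignment,
        archetype_labels=labels,
        proportions=proportions,
        group_stats=group_stats,
        tests=tests,
        pca=pca,
        silhouette_curve=curve,
    )


def proliferation_rate(
    counts: np.ndarray, removed_for_imaging: np.ndarray
) -> np.ndarray:
    """Per-interval growth rates: N_t / (N_{t-1} − removed_{t-1}).

    Entry t (t ≥ 1) is the fold change over the preceding interval after
    deducting cells taken for imaging; undefined intervals (denominator ≤ 0)
    come back as NaN with a warning.  Entry 0 is NaN (no preceding count).
    """
    counts = np.asarray(counts, dtype=float)
    removed = np.asarray(removed_for_imaging, dtype=float)
    if counts.shape != removed.shape:
        raise ValueError("counts and removed_for_imaging must align")
    if (counts < 0).any() or (removed < 0).any():
        raise ValueError("counts and removed_for_imaging must be >= 0")
    if (removed > counts).any():
        raise ValueError("removed_for_imaging cannot exceed counts")
    rates = np.full(counts.shape, np.nan)
    denom = counts[:-1] - removed[:-1]
    bad = denom <= 0
    if bad.any():
        warnings.warn(
            f"undefined proliferation rate at interval(s) "
            f"{list(np.flatnonzero(bad) + 1)}: denominator <= 0", stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        rates[1:] = np.where(bad, np.nan, counts[1:] / denom)
    return rates
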