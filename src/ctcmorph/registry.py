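"""The morphometric feature registry: the single source of truth for names.

Exactly :data:`N_FEATURES` named scalar features are extracted per cell,
grouped by component (Cell, Nucleus, DenseNuc, Mito) and category.  The
"around 500 features" of the original protocol is hardened here into an exact,
versioned contract so that table shapes are testable.

Inventory (summing to 500):

====================  ==========================================  =====
block                 layout                                      count
====================  ==========================================  =====
volume                1 per component                                 4
surface_area          1 per component                                 4
intensity             integrated / mean / sd per component           12
shape2D               11 descriptors per component, central slice    44
shape2D (Cell only)   boundary_roughness                              1
granularity           16-scale opening spectrum per component        64
texture               13 Haralick stats × 4 directions × 2 offsets
                      (Cell, Nucleus, Mito); 1 offset for DenseNuc  364
ratio                 Nuc/Cell, DenseNuc/Cell, Mito/Cell volume
                      and surface-area ratios + DenseNuc/Nuc vol      7
====================  ==========================================  =====

Main Features are all features whose category is neither ``granularity`` nor
``texture`` (the clustering feature set); there are 72 of them.

DenseNuc — the smallest component — carries a single co-occurrence offset:
its central slice is often too small for the 2-pixel offset to be populated,
and trimming it is what pins the total at exactly 500.
"""

from __future__ import annotations

from dataclasses import dataclass

import yaml

REGISTRY_VERSION = "1.0"
N_FEATURES = 500

COMPONENTS = ("cell", "nucleus", "densenuc", "mito")

#: Which image channel each component's texture/intensity is measured on.
COMPONENT_CHANNEL = {"cell": 0, "nucleus": 1, "densenuc": 1, "mito": 2}

HARALICK_STATS = (
    "asm",                # angular second moment (energy)
    "contrast",
    "correlation",
    "variance",           # sum of squares
    "idm",                # inverse difference moment (homogeneity)
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_variance",
    "difference_entropy",
    "imc1",               # information measure of correlation 1
    "imc2",               # information measure of correlation 2
)

TEXTURE_ANGLES_DEG = (0, 45, 90, 135)
TEXTURE_OFFSETS = {"cell": (1, 2), "nucleus": (1, 2), "mito": (1, 2),
                   "densenuc": (1,)}

GRANULARITY_SCALES = 16

SHAPE2D_NAMES = (
    "area2d",
    "perimeter2d",
    "eccentricity",
    "solidity",
    "extent",
    "major_axis_length",
    "minor_axis_length",
    "equivalent_diameter2d",
    "circularity",
    "feret_diameter_max",
    "aspect_ratio",
)

INTENSITY_NAMES = ("intensity_integrated", "intensity_mean", "intensity_sd")

RATIO_NAMES = (
    "ratio_nuc_cell_volume",
    "ratio_densenuc_cell_volume",
    "ratio_mito_cell_volume",
    "ratio_nuc_cell_surface",
    "ratio_densenuc_cell_surface",
    "ratio_mito_cell_surface",
    "ratio_densenuc_nuc_volume",
)

MAIN_EXCLUDED_CATEGORIES = ("granularity", "texture")


@dataclass(frozen=True)
class FeatureDef:
    name: str
    component: str | None   # None for cross-component ratios
    category: str

    @property
    def main(self) -> bool:
        return self.category not in MAIN_EXCLUDED_CATEGORIES


def build_registry() -> list[FeatureDef]:
    feats: list[FeatureDef] = []
    for comp in COMPONENTS:
        feats.append(FeatureDef(f"{comp}_volume", comp, "volume"))
        feats.append(FeatureDef(f"{comp}_surface_area", comp, "surface_area"))
        for n in INTENSITY_NAMES:
            feats.append(FeatureDef(f"{comp}_{n}", comp, "intensity"))
        for n in SHAPE2D_NAMES:
            feats.append(FeatureDef(f"{comp}_{n}", comp, "shape2D"))
        if comp == "cell":
            feats.append(FeatureDef("cell_boundary_roughness", comp, "shape2D"))
        for i in range(1, GRANULARITY_SCALES + 1):
            feats.append(FeatureDef(f"{comp}_granularity_{i:02d}", comp,
                                    "granularity"))
        for off in TEXTURE_OFFSETS[comp]:
            for ang in TEXTURE_ANGLES_DEG:
                for stat in HARALICK_STATS:
                    feats.append(FeatureDef(
                        f"{comp}_texture_{stat}_d{off}_a{ang:03d}",
                        comp, "texture"))
    for n in RATIO_NAMES:
        feats.append(FeatureDef(n, None, "ratio"))
    assert len(feats) == N_FEATURES, len(feats)
    assert len({f.name for f in feats}) == N_FEATURES
    return feats


_REGISTRY = build_registry()


def feature_names() -> list[str]:
    return [f.name for f in _REGISTRY]


def main_feature_names() -> list[str]:
    return [f.name for f in _REGISTRY if f.main]


def registry_frame():
    import pandas as pd

    return pd.DataFrame(
        [{"name": f.name, "component": f.component, "category": f.category,
          "main": f.main} for f in _REGISTRY]
    )


def save_registry(path) -> None:
    payload = {
        "version": REGISTRY_VERSION,
        "n_features": N_FEATURES,
        "features": [
            {"name": f.name, "component": f.component, "category": f.category,
             "main": f.main}
            for f in _REGISTRY
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def load_registry(path) -> list[FeatureDef]:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return [FeatureDef(f["name"], f["component"], f["category"])
            for f in payload["features"]]
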