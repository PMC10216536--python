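"""Segmentation of the three channels and per-cell morphometric features.

Each fluorescence channel is segmented independently by global Otsu
thresholding (the threshold is estimated on a lightly smoothed copy and
applied to the raw intensities, so binary inputs reproduce themselves
exactly).  Four components are derived per cell:

* **Cell** — cytoplasm channel, largest connected component, holes closed
  (the cytoplasmic dye leaves the nuclear region dim, so hole closing is what
  recovers the full cell body);
* **Nucleus** — nucleus channel, largest component, holes closed, clipped to
  the cell;
* **DenseNuc** — a second, higher Otsu split *inside* the raw nucleus mask
  (no hole closing), clipped to the nucleus;
* **Mito** — mitochondria channel, all connected components, no closing.

From each component, volume (voxel count × voxel volume), iso-surface mesh
area, intensity summaries, 2D shape descriptors on the most-centered z
section, a 16-scale granularity spectrum and Haralick co-occurrence texture
are extracted; cross-component volume and surface-area ratios complete the
registry's 500 named features.  Empty components propagate as missing values
(never zeros) so the preprocessing QC can act on them.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import marching_cubes, mesh_surface_area, regionprops

from . import registry as reg
from .synthgen import ComponentMasks, VoxelCell
from .texture import glcm_features, granularity_spectrum


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(mask)
    if n <= 1:
        return mask
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    return labels == sizes.argmax()


def segment_channel(image: np.ndarray, component: str) -> np.ndarray:
    """Global-threshold segmentation of one 3D channel.

    Returns an all-False mask (an empty-mask signal, not an error) when the
    channel carries no foreground.  For ``cell`` and ``nucleus`` only the
    largest connected component is kept.
    """
    if image.min() < 0:
        raise ValueError("intensities must be nonnegative")
    if image.max() <= image.min():
        return np.zeros(image.shape, dtype=bool)
    smoothed = ndimage.gaussian_filter(image.astype(float), sigma=(0, 1, 1))
    try:
        thresh = threshold_otsu(smoothed)
    except ValueError:
        return np.zeros(image.shape, dtype=bool)
    mask = image >= thresh
    if not mask.any() or mask.all():
        return np.zeros(image.shape, dtype=bool)
    if component in ("cell", "nucleus"):
        mask = _largest_component(mask)
    return mask


def segment_densenuc(image: np.ndarray, nucleus_raw: np.ndarray) -> np.ndarray:
    """Dense-nuclear foci: a second Otsu split inside the raw nucleus mask."""
    if not nucleus_raw.any():
        return np.zeros(image.shape, dtype=bool)
    vals = image[nucleus_raw]
    if vals.max() <= vals.min():
        return np.zeros(image.shape, dtype=bool)
    try:
        thresh = threshold_otsu(vals)
    except ValueError:
        return np.zeros(image.shape, dtype=bool)
    return nucleus_raw & (image > thresh)


def close_holes(mask: np.ndarray) -> np.ndarray:
    """Morphological closing followed by interior-cavity filling.

    Output is a superset of the input; empty in → empty out.
    """
    if not mask.any():
        return mask.copy()
    closed = ndimage.binary_closing(mask, structure=np.ones((3, 3, 3)))
    closed |= mask  # border voxels lost by closing's erosion step stay in
    return ndimage.binary_fill_holes(closed)


def segment_cell(image: np.ndarray, voxel_xy: float, voxel_z: float) -> ComponentMasks:
    """Segment a three-channel stack into the four component masks.

    Nesting is enforced by intersection: nucleus ⊆ cell, densenuc ⊆ nucleus.
    """
    cell = close_holes(segment_channel(image[0], "cell"))
    cell = _largest_component(cell)
    nuc_raw = segment_channel(image[1], "nucleus")
    densenuc = segment_densenuc(image[1], nuc_raw)
    nucleus = close_holes(nuc_raw)
    if cell.any():
        nucleus = nucleus & cell
    densenuc = densenuc & nucleus
    mito = segment_channel(image[2], "mito")
    return ComponentMasks(cell, nucleus, densenuc, mito, voxel_xy, voxel_z)


def mesh_area(mask: np.ndarray, voxel_xy: float, voxel_z: float) -> float:
    """Iso-surface area (μm²) of a binary mask via marching cubes.

    The binary volume is smoothed before meshing so the surface estimate of a
    smooth object is not inflated by voxel staircasing; structures too thin to
    survive smoothing fall back to the raw binary surface.
    """
    if not mask.any():
        return np.nan
    padded = np.pad(mask, 2).astype(float)
    smoothed = ndimage.gaussian_filter(padded, sigma=1.0)
    field = smoothed if smoothed.max() > 0.5 else padded
    try:
        verts, faces, _, _ = marching_cubes(
            field, level=0.5, spacing=(voxel_z, voxel_xy, voxel_xy)
        )
    except (ValueError, RuntimeError):
        return np.nan
    return float(mesh_surface_area(verts, faces))


def _central_slice(mask: np.ndarray) -> int:
    """Index of the most-centered section: the z-slice of the mask centroid."""
    zc = int(round(ndimage.center_of_mass(mask)[0]))
    zc = min(max(zc, 0), mask.shape[0] - 1)
    if mask[zc].any():
        return zc
    return int(mask.sum(axis=(1, 2)).argmax())


def _shape2d(mask2d: np.ndarray, voxel_xy: float) -> dict[str, float]:
    props = regionprops(mask2d.astype(np.uint8))[0]
    perimeter = props.perimeter * voxel_xy
    area = props.area * voxel_xy**2
    major = props.axis_major_length * voxel_xy
    minor = props.axis_minor_length * voxel_xy
    return {
        "area2d": area,
        "perimeter2d": perimeter,
        "eccentricity": props.eccentricity,
        "solidity": props.solidity,
        "extent": props.extent,
        "major_axis_length": major,
        "minor_axis_length": minor,
        "equivalent_diameter2d": props.equivalent_diameter_area * voxel_xy,
        "circularity": (4 * np.pi * area / perimeter**2) if perimeter > 0 else np.nan,
        "feret_diameter_max": props.feret_diameter_max * voxel_xy,
        "aspect_ratio": major / minor if minor > 0 else np.nan,
    }


def _boundary_roughness(mask2d: np.ndarray) -> float:
    """Relative spread (sd/mean) of boundary-to-centroid distance."""
    eroded = ndimage.binary_erosion(mask2d)
    boundary = mask2d & ~eroded
    ys, xs = np.nonzero(boundary)
    if ys.size < 3:
        return np.nan
    cy, cx = ndimage.center_of_mass(mask2d)
    r = np.sqrt((ys - cy) ** 2 + (xs - cx) ** 2)
    m = r.mean()
    return float(r.std() / m) if m > 0 else np.nan


_COMPONENT_FEATURES = {
    comp: [f.name for f in reg.build_registry() if f.component == comp]
    for comp in reg.COMPONENTS
}


def extract_component_features(
    mask: np.ndarray,
    image: np.ndarray,
    component: str,
    voxel_xy: float,
    voxel_z: float,
) -> dict[str, float]:
    """All registry features of one component (NaN-filled when the mask is empty)."""
    names = _COMPONENT_FEATURES[component]
    out = {n: np.nan for n in names}
    if not mask.any():
        return out
    voxel_volume = voxel_z * voxel_xy**2
    out[f"{component}_volume"] = float(mask.sum()) * voxel_volume
    out[f"{component}_surface_area"] = mesh_area(mask, voxel_xy, voxel_z)

    vals = image[mask].astype(float)
    out[f"{component}_intensity_integrated"] = float(vals.sum())
    out[f"{component}_intensity_mean"] = float(vals.mean())
    out[f"{component}_intensity_sd"] = float(vals.std())

    zc = _central_slice(mask)
    mask2d, img2d = mask[zc], image[zc].astype(float)
    for key, value in _shape2d(mask2d, voxel_xy).items():
        out[f"{component}_{key}"] = value
    if component == "cell":
        out["cell_boundary_roughness"] = _boundary_roughness(mask2d)

    spectrum = granularity_spectrum(img2d, mask2d, reg.GRANULARITY_SCALES)
    for i, g in enumerate(spectrum, start=1):
        out[f"{component}_granularity_{i:02d}"] = g

    tex = glcm_features(
        img2d, mask2d,
        offsets=reg.TEXTURE_OFFSETS[component],
        angles_deg=reg.TEXTURE_ANGLES_DEG,
    )
    for (stat, d, a), value in tex.items():
        out[f"{component}_texture_{stat}_d{d}_a{a:03d}"] = value
    return out


def compute_ratios(partials: dict[str, float]) -> dict[str, float]:
    """The seven cross-component volume and surface-area ratio features."""

    def _ratio(num, den):
        num, den = partials.get(num, np.nan), partials.get(den, np.nan)
        if not np.isfinite(den) or den <= 0 or not np.isfinite(num):
            return np.nan
        return num / den

    return {
        "ratio_nuc_cell_volume": _ratio("nucleus_volume", "cell_volume"),
        "ratio_densenuc_cell_volume": _ratio("densenuc_volume", "cell_volume"),
        "ratio_mito_cell_volume": _ratio("mito_volume", "cell_volume"),
        "ratio_nuc_cell_surface": _ratio("nucleus_surface_area", "cell_surface_area"),
        "ratio_densenuc_cell_surface": _ratio("densenuc_surface_area",
                                              "cell_surface_area"),
        "ratio_mito_cell_surface": _ratio("mito_surface_area", "cell_surface_area"),
        "ratio_densenuc_nuc_volume": _ratio("densenuc_volume", "nucleus_volume"),
    }


def extract_cell_features(cell: VoxelCell,
                          masks: ComponentMasks | None = None) -> dict[str, float]:
    """The full 500-feature vector of one cell (segmentation included)."""
    if masks is None:
        masks = segment_cell(cell.image, cell.voxel_xy, cell.voxel_z)
    partials: dict[str, float] = {}
    for comp in reg.COMPONENTS:
        mask = getattr(masks, comp if comp != "mito" else "mito")
        channel = cell.image[reg.COMPONENT_CHANNEL[comp]]
        partials.update(extract_component_features(
            mask, channel, comp, cell.voxel_xy, cell.voxel_z))
    partials.update(compute_ratios(partials))
    return partials


def assemble_feature_table(cells: Iterable[VoxelCell]) -> pd.DataFrame:
    """Cells × (metadata + 500 features) table; index is cell_id.

    Metadata columns are ``batch`` and ``archetype`` (empty string when a
    cell carries no ground truth).  Duplicate cell ids are an error.
    """
    names = reg.feature_names()
    rows, index, meta = [], [], []
    for cell in cells:
        feats = extract_cell_features(cell)
        rows.append([feats[n] for n in names])
        index.append(cell.cell_id)
        meta.append({
            "batch": cell.batch,
            "archetype": cell.truth.archetype if cell.truth is not None else "",
        })
    if len(set(index)) != len(index):
        dupes = sorted({i for i in index if index.count(i) > 1})
        raise ValueError(f"duplicate cell_id(s): {dupes}")
    table = pd.DataFrame(rows, index=pd.Index(index, name="cell_id"),
                         columns=names)
    meta_df = pd.DataFrame(meta, index=table.index)
    return pd.concat([meta_df, table], axis=1)


META_COLUMNS = ("batch", "archetype")


def split_meta(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split an assembled table into (metadata, feature matrix)."""
    meta_cols = [c for c in META_COLUMNS if c in table.columns]
    return table[meta_cols], table.drop(columns=meta_cols)


def read_cohort_dir(indir) -> Iterable[VoxelCell]:
    """Yield cells from a directory of per-cell multi-channel TIFF stacks.

    Expects the layout written by ``synthgen.write_cohort``: one ZCYX TIFF per
    cell plus an optional ``truth.csv`` carrying batch labels and archetypes.
    """
    import pathlib

    import tifffile

    from .synthgen import GroundTruth

    indir = pathlib.Path(indir)
    if not indir.is_dir():
        raise FileNotFoundError(f"cohort directory {indir} does not exist")
    truth_path = indir / "truth.csv"
    meta = (pd.read_csv(truth_path).set_index("cell_id")
            if truth_path.exists() else None)
    paths = sorted(indir.glob("*.tif"))
    if not paths:
        raise FileNotFoundError(f"no TIFF stacks under {indir}")
    for path in paths:
        with tifffile.TiffFile(path) as tf:
            arr = tf.asarray()
            md = tf.shaped_metadata[0] if tf.shaped_metadata else {}
        image = np.asarray(arr).transpose(1, 0, 2, 3)  # ZCYX -> CZYX
        cell_id = path.stem
        batch = int(md.get("batch", 0))
        archetype = ""
        if meta is not None and cell_id in meta.index:
            batch = int(meta.loc[cell_id, "batch"])
            archetype = str(meta.loc[cell_id, "archetype"])
        truth = GroundTruth(
            archetype=archetype, true_masks=None, true_cell_volume=np.nan,
            nuc_cell=np.nan, densenuc_nuc=np.nan, mito_cell=np.nan,
            radius_um=np.nan, roughness_amplitude=np.nan,
            integrated_intensity=image.sum(axis=(1, 2, 3)).astype(float),
        )
        yield VoxelCell(
            cell_id=cell_id, image=image,
            voxel_xy=float(md.get("voxel_xy_um", 0.3)),
            voxel_z=float(md.get("voxel_z_um", 0.9)),
            batch=batch, truth=truth,
        )


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="cell_id")


def write_feature_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path)
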