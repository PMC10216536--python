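"""Texture (co-occurrence) and granularity descriptors on 2D sections.

Texture is summarized by 13 classical Haralick statistics of the gray-level
co-occurrence matrix (GLCM), evaluated at multiple pixel offsets and the four
in-plane directions.  The GLCM itself comes from scikit-image; the statistics
beyond the few exposed by ``graycoprops`` are computed here from the
normalized matrix.

Granularity is an opening-based size spectrum: the fraction of total masked
intensity removed by grayscale openings with disks of increasing radius.
Fine speckle loses its mass at small scales, large blobs at large scales.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.feature import graycomatrix

from .registry import HARALICK_STATS

_EPS = 1e-12


def quantize(img2d: np.ndarray, mask2d: np.ndarray, levels: int = 32) -> np.ndarray:
    """Quantize masked intensities to 1..levels; background stays 0."""
    out = np.zeros(img2d.shape, dtype=np.uint8)
    vals = img2d[mask2d]
    if vals.size == 0:
        return out
    vmin, vmax = float(vals.min()), float(vals.max())
    if vmax > vmin:
        q = np.floor((img2d - vmin) / (vmax - vmin) * levels).astype(int) + 1
        q = np.clip(q, 1, levels)
    else:
        q = np.ones(img2d.shape, dtype=int)
    out[mask2d] = q[mask2d]
    return out


def haralick_from_glcm(P: np.ndarray) -> dict[str, float]:
    """The 13 Haralick statistics of one normalized GLCM.

    Statistics that are undefined on a degenerate matrix (e.g. correlation of
    a constant image, where the marginal variance is zero) come back as NaN.
    """
    n = P.shape[0]
    i = np.arange(n, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")

    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float((i * px).sum())
    mu_y = float((i * py).sum())
    var_x = float(((i - mu_x) ** 2 * px).sum())
    var_y = float(((i - mu_y) ** 2 * py).sum())

    out: dict[str, float] = {}
    out["asm"] = float((P**2).sum())
    out["contrast"] = float(((ii - jj) ** 2 * P).sum())
    if var_x > _EPS and var_y > _EPS:
        out["correlation"] = float(
            ((ii * jj * P).sum() - mu_x * mu_y) / np.sqrt(var_x * var_y)
        )
    else:
        out["correlation"] = np.nan
    out["variance"] = float(((ii - mu_x) ** 2 * P).sum())
    out["idm"] = float((P / (1.0 + (ii - jj) ** 2)).sum())

    # Sum / difference distributions.
    ssum = (ii + jj).astype(int)
    sdiff = np.abs(ii - jj).astype(int)
    p_sum = np.bincount(ssum.ravel(), weights=P.ravel(), minlength=2 * n - 1)
    p_diff = np.bincount(sdiff.ravel(), weights=P.ravel(), minlength=n)
    k_sum = np.arange(p_sum.size, dtype=float)
    k_diff = np.arange(p_diff.size, dtype=float)

    sa = float((k_sum * p_sum).sum())
    out["sum_average"] = sa
    out["sum_variance"] = float(((k_sum - sa) ** 2 * p_sum).sum())
    out["sum_entropy"] = float(-(p_sum * np.log(p_sum + _EPS)).sum())
    out["entropy"] = float(-(P * np.log(P + _EPS)).sum())
    da = float((k_diff * p_diff).sum())
    out["difference_variance"] = float(((k_diff - da) ** 2 * p_diff).sum())
    out["difference_entropy"] = float(-(p_diff * np.log(p_diff + _EPS)).sum())

    hxy = out["entropy"]
    pxy = np.outer(px, py)
    hxy1 = float(-(P * np.log(pxy + _EPS)).sum())
    hxy2 = float(-(pxy * np.log(pxy + _EPS)).sum())
    hx = float(-(px * np.log(px + _EPS)).sum())
    hy = float(-(py * np.log(py + _EPS)).sum())
    denom = max(hx, hy)
    out["imc1"] = float((hxy - hxy1) / denom) if denom > _EPS else np.nan
    arg = 1.0 - np.exp(-2.0 * (hxy2 - hxy))
    out["imc2"] = float(np.sqrt(max(arg, 0.0)))
    return out


def glcm_features(
    img2d: np.ndarray,
    mask2d: np.ndarray,
    offsets: tuple[int, ...],
    angles_deg: tuple[int, ...],
    levels: int = 32,
) -> dict[tuple[str, int, int], float]:
    """Haralick statistics per (offset, direction) on a masked 2D section.

    Background pixels are held out of the co-occurrence counts by assigning
    them a reserved gray level that is dropped before normalization.
    """
    keys = [(stat, d, a) for d in offsets for a in angles_deg
            for stat in HARALICK_STATS]
    if int(mask2d.sum()) < 2:
        return {k: np.nan for k in keys}
    qimg = quantize(img2d, mask2d, levels=levels)
    angles_rad = [np.deg2rad(a) for a in angles_deg]
    glcm = graycomatrix(
        qimg, distances=list(offsets), angles=angles_rad,
        levels=levels + 1, symmetric=True, normed=False,
    )
    out: dict[tuple[str, int, int], float] = {}
    for di, d in enumerate(offsets):
        for ai, a in enumerate(angles_deg):
            P = glcm[1:, 1:, di, ai].astype(float)
            total = P.sum()
            if total <= 0:
                for stat in HARALICK_STATS:
                    out[(stat, d, a)] = np.nan
                continue
            stats = haralick_from_glcm(P / total)
            for stat in HARALICK_STATS:
                out[(stat, d, a)] = stats[stat]
    return out


def granularity_spectrum(
    img2d: np.ndarray,
    mask2d: np.ndarray,
    n_scales: int = 16,
) -> np.ndarray:
    """Percent of masked intensity removed at each of ``n_scales`` opening radii.

    Entry *i* is 100 × (mass removed between openings at radius i−1 and i) /
    total masked mass.  The opening at radius *r* uses the r-fold iterated
    3×3 structuring element (the usual granulometry family in high-content
    screening pipelines); erosions are shared incrementally across scales, so
    the whole spectrum costs O(n_scales²) small filters.  Because the family
    is dilation-closed the openings are pointwise non-increasing in r and
    every spectrum entry is ≥ 0.
    """
    if not mask2d.any():
        return np.full(n_scales, np.nan)
    # Crop to the mask bounding box (plus margin) — openings are local.
    ys, xs = np.nonzero(mask2d)
    pad = 1
    y0, y1 = max(ys.min() - pad, 0), ys.max() + pad + 1
    x0, x1 = max(xs.min() - pad, 0), xs.max() + pad + 1
    vals = np.where(mask2d, img2d, 0.0)[y0:y1, x0:x1].astype(float)
    total = vals.sum()
    if total <= 0:
        return np.full(n_scales, np.nan)
    footprint = np.ones((3, 3), dtype=bool)
    spectrum = np.empty(n_scales)
    eroded = vals
    prev_sum = total
    for r in range(1, n_scales + 1):
        eroded = ndimage.grey_erosion(eroded, footprint=footprint)
        opened = eroded
        for _ in range(r):
            opened = ndimage.grey_dilation(opened, footprint=footprint)
        opened_sum = min(float(opened.sum()), prev_sum)
        spectrum[r - 1] = 100.0 * (prev_sum - opened_sum) / total
        prev_sum = opened_sum
    return spectrum
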