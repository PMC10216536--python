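"""Synthetic three-channel 3D single-cell phantoms with known morphometry.

Circulating tumor cells (CTCs) imaged live with a cytoplasmic dye, a nuclear
dye and a mitochondrial dye fall into three recurring morphometric archetypes:

* **SLR** — small cell, large Nuc/Cell and Mito/Cell volume ratios, dense
  nuclear foci, rough membrane;
* **SSR** — small cell, small Nuc/Cell and Mito/Cell ratios, dense nuclear
  foci, rough membrane;
* **LSS** — large cell, large Nuc/Cell ratio, small Mito/Cell ratio, sparse
  dense-nuclear foci, smooth membrane.

This module renders voxelized single-cell phantoms (one cell per frame, three
channels, anisotropic z-spacing) drawn from a configurable mixture of such
archetypes, with exact ground-truth component masks so every downstream stage
of the pipeline can be validated against a known answer.

Channel order is fixed everywhere in this package:
``(cytoplasm, nucleus, mitochondria)``.

Geometry of a rendered cell
---------------------------
The cell body is a sphere whose radius is modulated by a band-limited random
field (membrane roughness).  The nucleus is the set of voxels closest to the
center under an anisotropic ellipsoidal metric, chosen so the Nuc/Cell voxel
ratio matches the drawn value exactly (up to one voxel).  Dense-nuclear foci
and mitochondria are the top quantile of a smoothed noise field inside the
nucleus and the cytoplasmic shell respectively, again hitting the drawn
volume ratios exactly.  Intensities are piecewise-constant foreground means
times a per-batch staining factor, plus additive Gaussian noise, clipped at
zero.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

CHANNELS = ("cytoplasm", "nucleus", "mitochondria")

#: Intensity of the cytoplasm channel over the nuclear region, relative to
#: the cytoplasmic foreground.  The cytoplasmic dye is partially excluded
#: from the nucleus, dimming that region; hole closing in the cell
#: segmentation guards against the cavity this can leave behind.  (A much
#: dimmer cavity is physically plausible but makes the cell mask of a
#: thin-shelled cell depend on a watertight shell, which voxelized rough
#: membranes cannot guarantee.)
NUCLEAR_DIMMING = 0.6

#: Dense-nuclear foci intensity relative to the nuclear foreground.
DENSENUC_CONTRAST = 1.8


class ConfigurationError(ValueError):
    """Raised for invalid cohort configurations (e.g. weights not summing to 1)."""


class GenerationError(RuntimeError):
    """Raised when a sampled cell cannot be rendered in the configured volume."""


@dataclass(frozen=True)
class Dist:
    """A truncated-normal sampling spec: N(mean, sd) clipped to [lo, hi].

    Defaults truncate at ±3 sd; ratio-valued specs are additionally clipped
    away from {0, 1} by the sampler.
    """

    mean: float
    sd: float
    lo: float | None = None
    hi: float | None = None

    def bounds(self) -> tuple[float, float]:
        lo = self.mean - 3.0 * self.sd if self.lo is None else self.lo
        hi = self.mean + 3.0 * self.sd if self.hi is None else self.hi
        return lo, hi

    def sample(self, rng: np.random.Generator) -> float:
        lo, hi = self.bounds()
        return float(np.clip(rng.normal(self.mean, self.sd), lo, hi))


def _as_dist(value) -> "Dist":
    if isinstance(value, Dist):
        return value
    if isinstance(value, dict):
        return Dist(**value)
    mean, sd = value
    return Dist(float(mean), float(sd))


RATIO_EPS = 1e-3


@dataclass(frozen=True)
class ArchetypeSpec:
    """One morphometric archetype of the cohort mixture.

    All ratio distributions are truncated to the open interval (0, 1).
    ``roughness_amplitude`` is the standard deviation of the relative radial
    perturbation of the membrane (dimensionless, ≥ 0).
    """

    name: str
    weight: float
    cell_radius: Dist          # μm
    nuc_cell_ratio: Dist       # nucleus/cell volume ratio
    densenuc_nuc_ratio: Dist   # dense-chromatin/nucleus volume ratio
    mito_cell_ratio: Dist      # mitochondria/cell volume ratio
    roughness_amplitude: float
    intensity_means: tuple[float, float, float] = (100.0, 110.0, 120.0)

    def __post_init__(self):
        object.__setattr__(self, "cell_radius", _as_dist(self.cell_radius))
        for f in ("nuc_cell_ratio", "densenuc_nuc_ratio", "mito_cell_ratio"):
            d = _as_dist(getattr(self, f))
            lo, hi = d.bounds()
            d = dataclasses.replace(
                d, lo=max(lo, RATIO_EPS), hi=min(hi, 1.0 - RATIO_EPS)
            )
            object.__setattr__(self, f, d)
        if self.roughness_amplitude < 0:
            raise ConfigurationError("roughness_amplitude must be >= 0")
        if not (0.0 <= self.weight <= 1.0):
            raise ConfigurationError("archetype weight must lie in [0, 1]")


# Published subtype proportions are 32% / 62.6% / 5.7%, which sum to 100.3%;
# the mixture weights are those proportions normalized to sum exactly 1.
_RAW_PROPORTIONS = {"SLR": 0.32, "SSR": 0.626, "LSS": 0.057}
_PROP_TOTAL = sum(_RAW_PROPORTIONS.values())


def default_archetypes() -> list[ArchetypeSpec]:
    """The default three-archetype mixture.

    Numeric values operationalize the qualitative subtype profiles (the
    study quantifies them only as z-scores): SLR and LSS share the same
    Nuc/Cell mean so that contrast is null by construction, LSS is large but
    not so extreme that 3×IQR winsorization erases it, and the mitochondrial
    load is drawn as an absolute volume (ratio × archetype-typical cell
    volume) so integrated mitochondrial intensity within an archetype is
    decoupled from cell size, as FACS sorting of small/high-mito cells
    presumes.
    """
    return [
        ArchetypeSpec(
            name="SLR",
            weight=_RAW_PROPORTIONS["SLR"] / _PROP_TOTAL,
            cell_radius=Dist(5.0, 0.30),
            nuc_cell_ratio=Dist(0.52, 0.04),
            densenuc_nuc_ratio=Dist(0.38, 0.035),
            mito_cell_ratio=Dist(0.20, 0.015),
            roughness_amplitude=0.14,
            intensity_means=(100.0, 110.0, 170.0),
        ),
        ArchetypeSpec(
            name="SSR",
            weight=_RAW_PROPORTIONS["SSR"] / _PROP_TOTAL,
            cell_radius=Dist(5.6, 0.40),
            nuc_cell_ratio=Dist(0.28, 0.035),
            densenuc_nuc_ratio=Dist(0.30, 0.035),
            mito_cell_ratio=Dist(0.05, 0.012),
            roughness_amplitude=0.06,
            intensity_means=(100.0, 110.0, 110.0),
        ),
        ArchetypeSpec(
            name="LSS",
            weight=_RAW_PROPORTIONS["LSS"] / _PROP_TOTAL,
            cell_radius=Dist(8.0, 0.45),
            nuc_cell_ratio=Dist(0.52, 0.04),
            densenuc_nuc_ratio=Dist(0.16, 0.03),
            mito_cell_ratio=Dist(0.05, 0.012),
            roughness_amplitude=0.02,
            intensity_means=(100.0, 110.0, 110.0),
        ),
    ]


@dataclass
class CohortConfig:
    """Everything needed to synthesize one cohort reproducibly."""

    n_cells: int = 500
    archetypes: list[ArchetypeSpec] = field(default_factory=default_archetypes)
    n_batches: int = 2
    batch_factors: tuple[float, ...] = (1.0, 1.4)
    voxel_xy: float = 0.3   # μm per in-plane pixel (40x objective class)
    voxel_z: float = 0.9    # μm per optical slice
    image_shape: tuple[int, int, int] = (30, 80, 80)  # (z, y, x)
    noise_sd: float = 0.05  # additive Gaussian noise, fraction of foreground mean
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells < 0:
            raise ConfigurationError("n_cells must be >= 0")
        if not self.archetypes:
            raise ConfigurationError("at least one archetype required")
        total = sum(a.weight for a in self.archetypes)
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"archetype weights must sum to 1 (got {total!r})"
            )
        if self.n_batches < 1:
            raise ConfigurationError("n_batches must be >= 1")
        if len(self.batch_factors) != self.n_batches:
            raise ConfigurationError(
                "batch_factors must have one entry per batch "
                f"({len(self.batch_factors)} != {self.n_batches})"
            )
        if self.voxel_xy <= 0 or self.voxel_z <= 0:
            raise ConfigurationError("voxel sizes must be positive")
        if len(self.image_shape) != 3 or any(s < 4 for s in self.image_shape):
            raise ConfigurationError("image_shape must be 3 axes of >= 4 voxels")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")


@dataclass
class ComponentMasks:
    """Binary 3D masks of the four cellular components of one cell."""

    cell: np.ndarray
    nucleus: np.ndarray
    densenuc: np.ndarray
    mito: np.ndarray
    voxel_xy: float
    voxel_z: float

    @property
    def voxel_volume(self) -> float:
        return self.voxel_z * self.voxel_xy * self.voxel_xy


@dataclass
class GroundTruth:
    """Generator-side truth for one phantom cell."""

    archetype: str
    true_masks: ComponentMasks
    true_cell_volume: float            # μm³
    nuc_cell: float
    densenuc_nuc: float
    mito_cell: float
    radius_um: float
    roughness_amplitude: float
    integrated_intensity: np.ndarray   # per-channel sum of the final image


@dataclass
class VoxelCell:
    """One cell's three-channel z-stack plus geometry, batch and truth."""

    cell_id: str
    image: np.ndarray                  # float32, shape (3, z, y, x)
    voxel_xy: float
    voxel_z: float
    batch: int
    truth: GroundTruth


@dataclass(frozen=True)
class CellDraw:
    """One sampled parameter set for :func:`render_cell`."""

    archetype: str
    radius: float
    nuc_cell: float
    densenuc_nuc: float
    mito_cell: float
    roughness: float
    intensity_means: tuple[float, float, float]


def _draw_params(spec: ArchetypeSpec, rng: np.random.Generator,
                 archetype_mean_volume: float) -> CellDraw:
    radius = spec.cell_radius.sample(rng)
    volume = (4.0 / 3.0) * np.pi * radius**3
    # Mitochondrial load is an absolute volume re-expressed as a per-cell
    # ratio: conserved organelle mass within an archetype.
    mito_volume = spec.mito_cell_ratio.sample(rng) * archetype_mean_volume
    mito_cell = float(np.clip(mito_volume / volume, RATIO_EPS, 0.45))
    return CellDraw(
        archetype=spec.name,
        radius=radius,
        nuc_cell=spec.nuc_cell_ratio.sample(rng),
        densenuc_nuc=spec.densenuc_nuc_ratio.sample(rng),
        mito_cell=mito_cell,
        roughness=spec.roughness_amplitude,
        intensity_means=spec.intensity_means,
    )


def _smooth_noise(shape, sigma_vox, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean unit-sd band-limited Gaussian random field."""
    w = rng.standard_normal(shape)
    w = ndimage.gaussian_filter(w, sigma=sigma_vox, mode="nearest")
    sd = w.std()
    if sd < 1e-12:
        return np.zeros(shape)
    return (w - w.mean()) / sd


def _top_k_mask(values: np.ndarray, region: np.ndarray, k: int) -> np.ndarray:
    """Boolean mask of the k largest `values` within `region` (3D)."""
    out = np.zeros(values.shape, dtype=bool)
    if k <= 0:
        return out
    idx = np.flatnonzero(region)
    if k >= idx.size:
        out.ravel()[idx] = True
        return out
    vals = values.ravel()[idx]
    sel = np.argpartition(vals, -k)[-k:]
    out.ravel()[idx[sel]] = True
    return out


def render_cell(
    draw: CellDraw,
    *,
    image_shape: tuple[int, int, int],
    voxel_xy: float,
    voxel_z: float,
    seed,
    cell_index: int | None = None,
) -> VoxelCell:
    """Render one phantom cell (noise-free, unit batch factor).

    Raises :class:`GenerationError` if the perturbed cell cannot fit inside
    ``image_shape`` with a 2-voxel margin, naming the offending cell index.
    """
    if not (0.0 < draw.nuc_cell < 1.0 and 0.0 < draw.densenuc_nuc < 1.0
            and 0.0 < draw.mito_cell < 1.0):
        raise GenerationError(f"cell {cell_index}: ratios must lie in (0, 1)")
    if draw.radius <= 3.0 * voxel_xy:
        raise GenerationError(
            f"cell {cell_index}: radius {draw.radius:.3g} μm too small "
            f"(need > 3 voxels in-plane)"
        )
    rng = np.random.default_rng(seed)
    spacing = np.array([voxel_z, voxel_xy, voxel_xy])
    shape = tuple(image_shape)

    # Maximum possible boundary excursion: perturbation field clipped at ±2.5 sd.
    r_max = draw.radius * (1.0 + 2.5 * draw.roughness)
    half_extent_vox = np.ceil(r_max / spacing).astype(int) + 2
    center_vox = np.array([s // 2 for s in shape])
    lo = center_vox - half_extent_vox
    hi = center_vox + half_extent_vox + 1
    if (lo < 0).any() or (hi > np.array(shape)).any():
        raise GenerationError(
            f"cell {cell_index}: radius {draw.radius:.3g} μm (max excursion "
            f"{r_max:.3g} μm) does not fit image_shape {shape} with a "
            f"2-voxel margin"
        )

    # Work inside the bounding box only; paste into the full frame at the end.
    box_shape = tuple(hi - lo)
    zz, yy, xx = np.meshgrid(
        (np.arange(lo[0], hi[0]) - center_vox[0]) * spacing[0],
        (np.arange(lo[1], hi[1]) - center_vox[1]) * spacing[1],
        (np.arange(lo[2], hi[2]) - center_vox[2]) * spacing[2],
        indexing="ij",
    )
    rho = np.sqrt(zz**2 + yy**2 + xx**2)

    # Membrane roughness: band-limited relative radial perturbation.
    if draw.roughness > 0:
        corr_len = 0.4 * draw.radius  # μm
        sigma_vox = corr_len / spacing
        w = np.clip(_smooth_noise(box_shape, sigma_vox, rng), -2.5, 2.5)
    else:
        w = np.zeros(box_shape)
    cell = rho <= draw.radius * (1.0 + draw.roughness * w)
    n_cell = int(cell.sum())
    if n_cell == 0:
        raise GenerationError(f"cell {cell_index}: empty cell mask")

    # Nucleus: the k closest voxels (ellipsoidal metric, slight offset) inside
    # the 1-voxel-eroded cell, so the voxel ratio is exact and the nucleus
    # stays strictly interior.
    interior = ndimage.binary_erosion(cell)
    ax_y, ax_x = rng.uniform(0.85, 1.0, size=2)
    off = rng.uniform(-0.5, 0.5, size=3)  # μm
    d_ell = np.sqrt(
        (zz - off[0]) ** 2
        + ((yy - off[1]) / ax_y) ** 2
        + ((xx - off[2]) / ax_x) ** 2
    )
    k_nuc = int(round(draw.nuc_cell * n_cell))
    k_nuc = min(max(k_nuc, 1), int(interior.sum()))
    nucleus = _top_k_mask(-d_ell, interior, k_nuc)

    # Dense-nuclear foci: top quantile of a smoothed field inside the nucleus.
    focus_sigma = 0.8 / spacing  # ~0.8 μm foci
    f_dn = _smooth_noise(box_shape, focus_sigma, rng)
    k_dn = max(int(round(draw.densenuc_nuc * k_nuc)), 1)
    densenuc = _top_k_mask(f_dn, nucleus, k_dn)

    # Mitochondria: scattered blobs in the cytoplasmic shell.
    shell = cell & ~nucleus
    mito_sigma = 0.5 / spacing
    f_mt = _smooth_noise(box_shape, mito_sigma, rng)
    k_mt = max(int(round(draw.mito_cell * n_cell)), 1)
    k_mt = min(k_mt, int(shell.sum()))
    mito = _top_k_mask(f_mt, shell, k_mt)

    def _paste(box: np.ndarray, dtype=bool) -> np.ndarray:
        full = np.zeros(shape, dtype=dtype)
        full[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = box
        return full

    cell_f, nuc_f, dn_f, mt_f = (_paste(m) for m in (cell, nucleus, densenuc, mito))

    i_cyt, i_nuc, i_mit = draw.intensity_means
    image = np.zeros((3,) + shape, dtype=np.float32)
    image[0][cell_f] = i_cyt
    image[0][nuc_f] = NUCLEAR_DIMMING * i_cyt
    image[1][nuc_f] = i_nuc
    image[1][dn_f] = DENSENUC_CONTRAST * i_nuc
    image[2][mt_f] = i_mit

    voxel_volume = float(np.prod(spacing))
    masks = ComponentMasks(cell_f, nuc_f, dn_f, mt_f, voxel_xy, voxel_z)
    truth = GroundTruth(
        archetype=draw.archetype,
        true_masks=masks,
        true_cell_volume=n_cell * voxel_volume,
        nuc_cell=k_nuc / n_cell,
        densenuc_nuc=int(dn_f.sum()) / k_nuc,
        mito_cell=int(mt_f.sum()) / n_cell,
        radius_um=draw.radius,
        roughness_amplitude=draw.roughness,
        integrated_intensity=image.sum(axis=(1, 2, 3)).astype(float),
    )
    cid = f"cell_{cell_index:04d}" if cell_index is not None else "cell"
    return VoxelCell(cid, image, voxel_xy, voxel_z, batch=0, truth=truth)


def sample_archetype_labels(config: CohortConfig,
                            rng: np.random.Generator) -> np.ndarray:
    """Draw archetype indices from the categorical mixture of weights."""
    weights = np.array([a.weight for a in config.archetypes])
    return rng.choice(len(weights), size=config.n_cells, p=weights / weights.sum())


def _stage_rngs(config: CohortConfig):
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_cells + 2)
    assign_rng = np.random.default_rng(children[0])
    noise_rng = np.random.default_rng(children[1])
    return assign_rng, noise_rng, children[2:]


def iter_cohort(config: CohortConfig) -> Iterator[VoxelCell]:
    """Yield the cohort one finished cell at a time (constant memory).

    Batches are assigned uniformly at random; the batch intensity factor and
    additive noise are applied before the cell is yielded, and the truth's
    integrated intensities are recomputed from the final image.
    """
    config.validate()
    assign_rng, noise_rng, cell_seeds = _stage_rngs(config)
    labels = sample_archetype_labels(config, assign_rng)
    batches = assign_rng.integers(0, config.n_batches, size=config.n_cells)
    mean_volumes = {
        a.name: (4.0 / 3.0) * np.pi * a.cell_radius.mean**3
        for a in config.archetypes
    }
    for i in range(config.n_cells):
        spec = config.archetypes[labels[i]]
        draw_rng = np.random.default_rng(cell_seeds[i])
        draw = _draw_params(spec, draw_rng, mean_volumes[spec.name])
        cell = render_cell(
            draw,
            image_shape=config.image_shape,
            voxel_xy=config.voxel_xy,
            voxel_z=config.voxel_z,
            seed=draw_rng,
            cell_index=i,
        )
        cell.batch = int(batches[i])
        factor = config.batch_factors[cell.batch]
        cell.image *= factor
        if config.noise_sd > 0:
            fg_means = np.array(draw.intensity_means) * factor
            noise = noise_rng.standard_normal(cell.image.shape,
                                              dtype=np.float32)
            scale = (config.noise_sd * fg_means).astype(np.float32)
            cell.image += scale[:, None, None, None] * noise
            np.clip(cell.image, 0.0, None, out=cell.image)
        cell.truth.integrated_intensity = (
            cell.image.sum(axis=(1, 2, 3)).astype(float)
        )
        yield cell


def sample_cohort(config: CohortConfig) -> tuple[list[VoxelCell], pd.DataFrame]:
    """Materialize the whole cohort plus its ground-truth table."""
    cells = list(iter_cohort(config))
    return cells, truth_table(cells)


TRUTH_COLUMNS = (
    "cell_id", "archetype", "batch", "true_cell_volume", "true_nuc_cell",
    "true_densenuc_nuc", "true_mito_cell", "radius_um", "roughness",
    "intensity_cytoplasm", "intensity_nucleus", "intensity_mitochondria",
)


def truth_row(cell: VoxelCell) -> dict:
    """One ground-truth table row (scalar fields only, no masks)."""
    t = cell.truth
    return {
        "cell_id": cell.cell_id,
        "archetype": t.archetype,
        "batch": cell.batch,
        "true_cell_volume": t.true_cell_volume,
        "true_nuc_cell": t.nuc_cell,
        "true_densenuc_nuc": t.densenuc_nuc,
        "true_mito_cell": t.mito_cell,
        "radius_um": t.radius_um,
        "roughness": t.roughness_amplitude,
        "intensity_cytoplasm": t.integrated_intensity[0],
        "intensity_nucleus": t.integrated_intensity[1],
        "intensity_mitochondria": t.integrated_intensity[2],
    }


def truth_table(cells: Sequence[VoxelCell]) -> pd.DataFrame:
    return pd.DataFrame([truth_row(c) for c in cells],
                        columns=list(TRUTH_COLUMNS))


def apply_batch_effect(cells: Sequence[VoxelCell],
                       config: CohortConfig) -> list[VoxelCell]:
    """Multiply each cell's intensities by its batch factor (masks unchanged).

    ``iter_cohort`` already applies the batch effect; this standalone form
    exists for cells rendered at unit factor (e.g. via :func:`render_cell`).
    """
    out = []
    for c in cells:
        if not (0 <= c.batch < len(config.batch_factors)):
            raise ConfigurationError(f"unknown batch label {c.batch!r}")
        factor = config.batch_factors[c.batch]
        c2 = dataclasses.replace(c, image=c.image * factor)
        c2.truth = dataclasses.replace(
            c.truth,
            integrated_intensity=c2.image.sum(axis=(1, 2, 3)).astype(float),
        )
        out.append(c2)
    return out


# ---------------------------------------------------------------------------
# Config and cohort serialization

def config_to_dict(config: CohortConfig) -> dict:
    d = dataclasses.asdict(config)
    d["archetypes"] = [dataclasses.asdict(a) for a in config.archetypes]
    d["batch_factors"] = list(config.batch_factors)
    d["image_shape"] = list(config.image_shape)
    return d


def config_from_dict(d: dict) -> CohortConfig:
    d = dict(d)
    archetypes = []
    for a in d.pop("archetypes", []):
        a = dict(a)
        for f in ("cell_radius", "nuc_cell_ratio", "densenuc_nuc_ratio",
                  "mito_cell_ratio"):
            a[f] = _as_dist(a[f])
        if "intensity_means" in a:
            a["intensity_means"] = tuple(a["intensity_means"])
        archetypes.append(ArchetypeSpec(**a))
    cfg = CohortConfig(**d)
    if archetypes:
        cfg.archetypes = archetypes
    cfg.batch_factors = tuple(cfg.batch_factors)
    cfg.image_shape = tuple(cfg.image_shape)
    return cfg


def load_config(path) -> CohortConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))


def save_config(config: CohortConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=True)


def write_cohort(cells: Sequence[VoxelCell], outdir) -> None:
    """Write each cell as a multi-channel TIFF z-stack plus a truth CSV."""
    import pathlib

    import tifffile

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for c in cells:
        tifffile.imwrite(
            outdir / f"{c.cell_id}.tif",
            c.image.transpose(1, 0, 2, 3),  # ZCYX
            photometric="minisblack",
            metadata={
                "axes": "ZCYX",
                "channels": list(CHANNELS),
                "voxel_xy_um": c.voxel_xy,
                "voxel_z_um": c.voxel_z,
                "batch": c.batch,
            },
        )
    truth_table(cells).to_csv(outdir / "truth.csv", index=False)
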