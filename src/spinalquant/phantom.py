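"""Synthetic cervical-cord phantom generator with exact ground truth.

Produces desk-scale stand-ins for serial-section two-photon volumes of
mouse cervical spinal cord: an autofluorescence channel showing a cord
whose outline and butterfly-shaped gray matter vary smoothly along the
rostrocaudal (Z) axis, an annotation volume consistent with the region
ontology, and a signal channel carrying punctate presynaptic-terminal-
like blobs, curvilinear axon-like structure in the dorsal white-matter
column, and motoneuron-soma-like blobs in lamina 9 — all deposited at
known per-region densities, with per-region intensity sums recorded
exactly before noise is added.

Per-sample variability is created by applying a known rigid + affine +
smooth elastic deformation whose parameters are returned, so that the
registration stages can be validated against ground truth.

Every output is a pure function of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import SimpleITK as sitk

from .atlas import (
    CERVICAL_LEVELS,
    AnnotationVolume,
    RegionOntology,
    build_region_ontology,
    default_laminae_rule,
)
from .registration import FixedGeometry, TransformChain, TransformStep
from .volume import ImageVolume

__all__ = [
    "PhantomConfig",
    "PhantomTruth",
    "CohortSample",
    "TRUTH_CLASS_CODES",
    "generate_template_phantom",
    "deposit_signal",
    "deform_sample",
    "generate_cohort",
    "make_known_chain",
    "default_density_profile",
    "render_blobs",
]

#: Per-voxel truth class codes used by PhantomTruth.class_labels.
TRUTH_CLASS_CODES = {"background": 0, "gray": 1, "white": 2, "synapse": 3,
                     "axon": 4, "soma": 5}

#: Relative dorsoventral thickness of laminae 1-9 within hemicord gray
#: matter (lamina 10 is the pericanal zone, carved separately).
_LAMINA_WEIGHTS = {1: 0.07, 2: 0.07, 3: 0.09, 4: 0.10, 5: 0.13, 6: 0.09,
                   7: 0.17, 8: 0.12, 9: 0.16}

WHITE_TRACTS = ("dorsal column", "ventrolateral white")


@dataclass
class PhantomConfig:
    """Study conditions for phantom generation.

    The grid defaults to a desk-scale 50 sections x 256 x 256 at 10 um
    in-plane / 60 um section spacing so a full registration runs in
    minutes; all sizes are configurable.
    """

    n_sections: int = 50
    ny: int = 256
    nx: int = 256
    voxel_size_um: tuple[float, float, float] = (60.0, 10.0, 10.0)
    levels: tuple[str, ...] = CERVICAL_LEVELS
    motor_pools: Mapping[str, Sequence[str]] | None = None

    # autofluorescence channel
    white_intensity: float = 600.0
    gray_contrast: float = 0.6          # gray = white * (1 + contrast)
    border_width_px: int = 3
    border_gain: float = 0.8            # rim adds gain * white_intensity
    autofluor_smooth_px: float = 1.0

    # signal channel
    puncta_density: Mapping[int, float] | None = None  # puncta per 1000 voxels, by region id
    puncta_sigma_px: tuple[float, float] = (1.0, 2.0)
    puncta_amplitude: float = 2000.0
    axon_tract: str = "dorsal column"
    axon_count: int = 6                 # axon paths per hemicord
    axon_amplitude: float = 1500.0
    axon_radius_px: float = 1.0
    somas_per_lamina9_region: int = 2
    soma_sigma_px: tuple[float, float] = (2.0, 3.0)
    soma_amplitude: float = 3000.0

    # noise model: Poisson-like shot component plus additive Gaussian
    noise_sigma: float = 30.0
    shot_gain: float = 10.0             # 0 disables the shot component
    background_offset: float = 50.0

    # deformation magnitudes (per sample)
    translation_vox: float = 8.0
    rotation_deg: float = 4.0
    scale_jitter: float = 0.04
    shear_jitter: float = 0.02
    # smooth elastic component of inter-animal variability: a coarse
    # control mesh (~1.3 mm spacing at the default grid) keeps the warp
    # at the anatomical scale rather than introducing sub-millimetre
    # distortion no serial-section cord exhibits
    elastic_amp_vox: float = 2.0
    elastic_mesh: tuple[int, int, int] = (2, 2, 2)   # (x, y, z) control cells

    def __post_init__(self):
        if self.n_sections < 1:
            raise ValueError("n_sections must be >= 1")
        if self.puncta_density is not None and any(d < 0 for d in self.puncta_density.values()):
            raise ValueError("puncta densities must be >= 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.n_sections, self.ny, self.nx)


@dataclass
class PhantomTruth:
    """Exact ground truth recorded at generation time (pre-noise)."""

    region_sums: dict[int, float]
    class_labels: np.ndarray                      # uint8, TRUTH_CLASS_CODES
    soma_placements: list[dict]                   # center (z,y,x), sigma, amplitude, region_id
    seed: int
    masked_total: float = 0.0                     # pre-noise deposit within annotated mask
    transform_parameters: dict | None = None      # filled by deform_sample

    def total_deposited(self) -> float:
        return float(sum(self.region_sums.values()))


@dataclass
class CohortSample:
    sample_id: str
    group: str
    autofluorescence: ImageVolume
    signal: ImageVolume
    annotation_moved: AnnotationVolume
    truth: PhantomTruth
    true_chain: TransformChain | None
    seed: int


# ---------------------------------------------------------------------------
# geometry


def _enlargement(t: float) -> float:
    # cervical enlargement bump around the C5-C7 portion of the cord
    return math.exp(-(((t - 0.72) / 0.18) ** 2))


def _section_masks(cfg: PhantomConfig, z: int):
    """Boolean masks for one transverse section.

    Returns (cord, gray, lamina10, dorsal_white, level_index).  All
    shapes are exactly mirror-symmetric about the inter-column midline
    because they are functions of |x - xc| with xc = (nx-1)/2.
    """
    t = z / max(cfg.n_sections - 1, 1)
    ny, nx = cfg.ny, cfg.nx
    yc, xc = (ny - 1) / 2.0, (nx - 1) / 2.0
    e = _enlargement(t)
    ax = nx * (0.30 + 0.03 * math.sin(math.pi * t) + 0.05 * e)
    ay = ny * (0.24 + 0.02 * math.sin(math.pi * t) + 0.03 * e)
    if ax < 8 or ay < 8:
        raise ValueError(
            f"grid {ny}x{nx} too small to contain the cord cross-section "
            f"(semi-axes {ax:.1f}, {ay:.1f} px)")

    y, x = np.mgrid[0:ny, 0:nx].astype(float)
    dx = np.abs(x - xc)
    dy = y - yc

    def ellipse(cy, cdx, ry, rx):
        return ((dx - cdx) / rx) ** 2 + ((dy - cy) / ry) ** 2 <= 1.0

    cord = (dx / ax) ** 2 + (dy / ay) ** 2 <= 1.0
    dorsal = ellipse(-0.45 * ay, 0.32 * ax, 0.38 * ay, 0.16 * ax)
    ventral_scale = 1.0 + 0.3 * e
    ventral = ellipse(0.38 * ay, 0.30 * ax, 0.30 * ay * ventral_scale,
                      0.26 * ax * ventral_scale)
    central = ellipse(0.05 * ay, 0.0, 0.16 * ay, 0.30 * ax)
    inner_cord = (dx / (0.92 * ax)) ** 2 + (dy / (0.92 * ay)) ** 2 <= 1.0
    gray = (dorsal | ventral | central) & inner_cord
    lamina10 = ellipse(0.0, 0.0, 0.10 * ay, 0.08 * ax) & gray
    white = cord & ~gray
    dorsal_white = white & (dy < -0.30 * ay) & (dx < 0.28 * ax)
    n_levels = len(cfg.levels)
    level_idx = min(int(t * n_levels), n_levels - 1) if cfg.n_sections > 1 else 0
    return cord, gray, lamina10, dorsal_white, level_idx


def _phantom_ontology(cfg: PhantomConfig) -> RegionOntology:
    return build_region_ontology(
        levels=cfg.levels,
        motor_pools=cfg.motor_pools,
        white_tracts={t: cfg.levels for t in WHITE_TRACTS},
        version="phantom-1",
    )


def generate_template_phantom(cfg: PhantomConfig, seed: int
                              ) -> tuple[ImageVolume, AnnotationVolume]:
    """Template-space phantom: autofluorescence volume + annotation.

    The cord outline and gray/white boundary vary smoothly along Z,
    gray matter is brighter than white matter by ``gray_contrast``, a
    bright rim runs just inside the tissue border, and with
    ``noise_sigma == 0`` and ``shot_gain == 0`` the autofluorescence is
    exactly left/right symmetric by construction.
    """
    from scipy import ndimage

    rng = np.random.default_rng(seed)
    ontology = _phantom_ontology(cfg)
    nz, ny, nx = cfg.shape
    labels = np.zeros((nz, ny, nx), dtype=np.int32)
    autofluor = np.zeros((nz, ny, nx), dtype=np.float32)
    midline = nx // 2
    x_idx = np.arange(nx)
    left_cols = x_idx < midline

    # fast region-id lookup tables built once
    def rec_id(**crit):
        recs = ontology.select(**crit)
        return recs[0].id if recs else 0

    pool_names = list(cfg.motor_pools) if cfg.motor_pools else []

    for z in range(nz):
        cord, gray, lam10, dorsal_white, lv_i = _section_masks(cfg, z)
        level = cfg.levels[lv_i]
        laminae = sorted(default_laminae_rule(level))
        weights = np.array([_LAMINA_WEIGHTS[l] for l in laminae if l != 10], dtype=float)
        lam_order = [l for l in laminae if l != 10]
        weights /= weights.sum()
        cum = np.cumsum(weights)

        sec = labels[z]
        for hemi, hemi_cols in (("left", left_cols), ("right", ~left_cols)):
            hmask = gray & hemi_cols[None, :] & ~lam10
            ys = np.nonzero(hmask.any(axis=1))[0]
            if ys.size == 0:
                continue
            y0, y1 = ys.min(), ys.max()
            depth = (np.arange(cfg.ny) - y0) / max(y1 - y0, 1)
            band = np.clip(np.searchsorted(cum, np.clip(depth, 0, 1), side="left"),
                           0, len(lam_order) - 1)
            for bi, lam in enumerate(lam_order):
                rid = rec_id(level=level, lamina=lam, hemicord=hemi)
                rows = band == bi
                sec[np.outer(rows, np.ones(cfg.nx, bool)) & hmask] = rid
            # lamina 10: pericanal zone
            rid10 = rec_id(level=level, lamina=10, hemicord=hemi)
            sec[lam10 & hemi_cols[None, :]] = rid10
            # motor pools carve x-wise sub-blocks out of lamina 9
            pools_here = [p for p in pool_names
                          if level in cfg.motor_pools[p]]  # type: ignore[index]
            if pools_here:
                rid9 = rec_id(level=level, lamina=9, hemicord=hemi)
                l9 = sec == rid9
                xs = np.nonzero(l9.any(axis=0))[0]
                if xs.size:
                    edges = np.linspace(xs.min(), xs.max() + 1, len(pools_here) + 1)
                    for pi, pool in enumerate(pools_here):
                        ridp = rec_id(level=level, pool=pool, hemicord=hemi)
                        cols = (x_idx >= edges[pi]) & (x_idx < edges[pi + 1])
                        sec[l9 & cols[None, :]] = ridp
            # white matter tracts
            ridd = rec_id(level=level, tract="dorsal column", hemicord=hemi)
            ridv = rec_id(level=level, tract="ventrolateral white", hemicord=hemi)
            white = cord & ~gray & hemi_cols[None, :]
            sec[white & dorsal_white] = ridd
            sec[white & ~dorsal_white] = ridv

        base = np.zeros((ny, nx), dtype=np.float32)
        base[cord] = cfg.white_intensity
        base[gray] = cfg.white_intensity * (1.0 + cfg.gray_contrast)
        if cfg.border_width_px > 0 and cfg.border_gain > 0:
            rim = cord & ~ndimage.binary_erosion(cord, iterations=cfg.border_width_px)
            base[rim] += cfg.border_gain * cfg.white_intensity
        autofluor[z] = base

    if cfg.autofluor_smooth_px > 0:
        autofluor = ndimage.gaussian_filter(
            autofluor, sigma=(0, cfg.autofluor_smooth_px, cfg.autofluor_smooth_px))
    autofluor = _add_noise(autofluor, cfg, rng)

    annotation = AnnotationVolume(labels, cfg.voxel_size_um, ontology, midline_x=midline)
    return (ImageVolume(autofluor, cfg.voxel_size_um, channel="autofluorescence"),
            annotation)


def _add_noise(img: np.ndarray, cfg: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    out = img.astype(np.float32)
    if cfg.shot_gain > 0:
        out = rng.poisson(np.maximum(out, 0) / cfg.shot_gain).astype(np.float32) * cfg.shot_gain
    if cfg.noise_sigma > 0:
        out = out + rng.normal(0.0, cfg.noise_sigma, size=out.shape).astype(np.float32)
    if cfg.background_offset:
        out = out + cfg.background_offset
    return np.maximum(out, 0.0, dtype=np.float32) if out.dtype == np.float32 else np.maximum(out, 0)


# ---------------------------------------------------------------------------
# signal deposition


def default_density_profile(ontology: RegionOntology,
                            contralateral: str = "left",
                            ipsilateral_factor: float = 0.05,
                            base: float = 1.0) -> dict[int, float]:
    """Laminar density profile emulating corticospinal innervation.

    Densest in laminae 5 and 7 contralaterally; the ipsilateral
    hemicord carries a small fraction of the contralateral signal with
    lamina 7 remaining the dominant target.  Units: expected puncta
    per 1000 voxels.
    """
    lam_weight = {1: 0.1, 2: 0.1, 3: 0.2, 4: 1.0, 5: 2.0, 6: 1.0,
                  7: 2.0, 8: 1.0, 9: 0.3, 10: 1.0}
    densities: dict[int, float] = {}
    for rec in ontology:
        if rec.tissue_class != "gray":
            continue
        lam = rec.lamina if rec.lamina is not None else 9  # pools sit in lamina 9
        w = lam_weight[lam] * base
        if rec.hemicord != contralateral:
            w *= ipsilateral_factor
            if lam == 7:
                w *= 2.0
        densities[rec.id] = w
    return densities


def render_blobs(shape: tuple[int, int, int],
                 placements: Sequence[Mapping]) -> np.ndarray:
    """Render isotropic in-plane Gaussian blobs into a fresh volume.

    Each placement has keys center=(z, y, x), sigma (px, in-plane) and
    amplitude.  Blobs are truncated at 3 sigma.  Used both for signal
    deposition and to reconstruct component volumes (e.g. soma-only)
    from recorded truth placements.
    """
    out = np.zeros(shape, dtype=np.float32)
    nz, ny, nx = shape
    for p in placements:
        z, yc, xc = p["center"]
        sig = float(p["sigma"])
        amp = float(p["amplitude"])
        r = max(int(math.ceil(3 * sig)), 1)
        z = int(round(z))
        if not 0 <= z < nz:
            continue
        y0, y1 = max(int(yc) - r, 0), min(int(yc) + r + 1, ny)
        x0, x1 = max(int(xc) - r, 0), min(int(xc) + r + 1, nx)
        yy, xx = np.mgrid[y0:y1, x0:x1].astype(float)
        g = amp * np.exp(-((yy - yc) ** 2 + (xx - xc) ** 2) / (2 * sig ** 2))
        out[z, y0:y1, x0:x1] += g.astype(np.float32)
    return out


def _erosion_levels(mask: np.ndarray, max_r: int) -> list[tuple]:
    """In-plane erosions of a region mask, radii 0..max_r.

    Returns nonzero-coordinate tuples per radius, truncated at the last
    non-empty erosion (thin regions simply stop early).  Erosion runs
    on the mask's bounding box for speed.
    """
    from scipy import ndimage

    zs, ys, xs = np.nonzero(mask)
    z0, z1 = zs.min(), zs.max() + 1
    y0, y1 = max(ys.min() - 1, 0), ys.max() + 2
    x0, x1 = max(xs.min() - 1, 0), xs.max() + 2
    sub = mask[z0:z1, y0:y1, x0:x1]
    offsets = np.array([z0, y0, x0])
    levels = [tuple(c + o for c, o in zip(np.nonzero(sub), offsets))]
    current = sub
    for _ in range(max_r):
        current = ndimage.binary_erosion(current, structure=np.ones((1, 3, 3), bool))
        if not current.any():
            break
        levels.append(tuple(c + o for c, o in zip(np.nonzero(current), offsets)))
    return levels


def _sample_axon_paths(cfg: PhantomConfig, annotation: AnnotationVolume,
                       rng: np.random.Generator) -> np.ndarray:
    """Curvilinear axon-like tubes descending through the axon tract.

    Each path is a quadratic Bezier in (y, x) over the full Z extent,
    constrained to the configured tract's cross-section, rasterised
    with a Gaussian cross-profile of the configured radius.
    """
    sig = np.zeros(annotation.shape, dtype=np.float32)
    labels = annotation.labels
    ont = annotation.ontology
    tract_ids = [r.id for r in ont if r.tract == cfg.axon_tract]
    if not tract_ids and cfg.axon_count > 0:
        raise ValueError(f"axon tract {cfg.axon_tract!r} not present in ontology")
    nz = annotation.shape[0]
    tract_mask = np.isin(labels, tract_ids)
    for hemi in ("left", "right"):
        hemi_ids = [r.id for r in ont if r.tract == cfg.axon_tract and r.hemicord == hemi]
        hmask = np.isin(labels, hemi_ids)
        if not hmask.any():
            continue
        for _ in range(cfg.axon_count):
            ctrl = []
            for zq in (0, nz // 2, nz - 1):
                ys, xs = np.nonzero(hmask[zq])
                if ys.size == 0:
                    zq2 = int(np.nonzero(hmask.any(axis=(1, 2)))[0][0])
                    ys, xs = np.nonzero(hmask[zq2])
                k = rng.integers(ys.size)
                ctrl.append((float(ys[k]), float(xs[k])))
            (y0, x0), (y1, x1), (y2, x2) = ctrl
            for z in range(nz):
                t = z / max(nz - 1, 1)
                yb = (1 - t) ** 2 * y0 + 2 * (1 - t) * t * y1 + t ** 2 * y2
                xb = (1 - t) ** 2 * x0 + 2 * (1 - t) * t * x1 + t ** 2 * x2
                r = max(int(math.ceil(3 * cfg.axon_radius_px)), 1)
                ylo, yhi = max(int(yb) - r, 0), min(int(yb) + r + 1, annotation.shape[1])
                xlo, xhi = max(int(xb) - r, 0), min(int(xb) + r + 1, annotation.shape[2])
                yy, xx = np.mgrid[ylo:yhi, xlo:xhi].astype(float)
                g = cfg.axon_amplitude * np.exp(
                    -((yy - yb) ** 2 + (xx - xb) ** 2) / (2 * cfg.axon_radius_px ** 2))
                patch = sig[z, ylo:yhi, xlo:xhi]
                keep = tract_mask[z, ylo:yhi, xlo:xhi]
                patch[keep] += g.astype(np.float32)[keep]
    return sig


def deposit_signal(annotation: AnnotationVolume, cfg: PhantomConfig, seed: int
                   ) -> tuple[ImageVolume, PhantomTruth]:
    """Deposit puncta / axon / soma signal on the annotation's grid.

    Puncta counts per region are Poisson with mean density/1000 x
    region voxel count; positions are uniform over the region mask.
    Axon-like tubes run through the configured white-matter tract and
    soma-like blobs are centred inside lamina-9 (or pool) regions.
    The per-region truth sums are computed from the clean (pre-noise)
    deposited volume, so summed over regions they exactly equal the
    total deposited signal within the annotated mask.
    """
    rng = np.random.default_rng(seed)
    ont = annotation.ontology
    labels = annotation.labels
    densities = cfg.puncta_density
    if densities is None:
        densities = default_density_profile(ont)
    unknown = [rid for rid in densities if ont.get(int(rid)) is None]
    if unknown:
        raise ValueError(f"density map references unknown region ids: {unknown}")

    placements: list[dict] = []
    smin, smax = cfg.puncta_sigma_px
    for rid, dens in sorted(densities.items()):
        if dens <= 0:
            continue
        mask = labels == rid
        n_vox = int(mask.sum())
        if n_vox == 0:
            continue
        n = rng.poisson(dens / 1000.0 * n_vox)
        if n == 0:
            continue
        # puncta are deposited wholly inside their region so the
        # recorded per-region sums are clean ground truth: centres are
        # drawn from the mask eroded by ~2.5 sigma (the 99% radius of
        # the blob), relaxing toward the full mask for thin regions
        erosions = _erosion_levels(mask, max_r=int(math.ceil(2.5 * smax)))
        sig = rng.uniform(smin, smax, size=n)
        amp = cfg.puncta_amplitude * rng.uniform(0.5, 1.0, size=n)
        jit = rng.uniform(-0.5, 0.5, size=(n, 2))
        for i in range(n):
            want = int(math.ceil(2.5 * sig[i]))
            zs, ys, xs = erosions[min(want, len(erosions) - 1)]
            k = rng.integers(zs.size)
            placements.append({
                "center": (int(zs[k]), float(ys[k] + jit[i, 0]),
                           float(xs[k] + jit[i, 1])),
                "sigma": float(sig[i]), "amplitude": float(amp[i]),
                "kind": "synapse", "region_id": int(rid),
            })
    puncta_vol = render_blobs(annotation.shape, placements)

    axon_vol = (_sample_axon_paths(cfg, annotation, rng)
                if cfg.axon_count > 0 else np.zeros(annotation.shape, np.float32))

    soma_placements: list[dict] = []
    if cfg.somas_per_lamina9_region > 0:
        from scipy import ndimage

        lam9 = [r for r in ont if (r.lamina == 9 or r.pool is not None)]
        for rec in lam9:
            mask = labels == rec.id
            if not mask.any():
                continue
            for _ in range(cfg.somas_per_lamina9_region):
                sig_px = float(rng.uniform(*cfg.soma_sigma_px))
                # somas sit inside the pool, so centres are drawn from
                # the mask eroded by roughly one soma radius (falling
                # back to the full mask for very thin regions)
                r_erode = int(round(sig_px))
                eroded = ndimage.binary_erosion(
                    mask, structure=np.ones((1, 3, 3), bool), iterations=r_erode)
                zs, ys, xs = np.nonzero(eroded if eroded.any() else mask)
                k = rng.integers(zs.size)
                soma_placements.append({
                    "center": (int(zs[k]), float(ys[k]), float(xs[k])),
                    "sigma": sig_px,
                    "amplitude": float(cfg.soma_amplitude),
                    "kind": "soma", "region_id": rec.id,
                })
    soma_vol = render_blobs(annotation.shape, soma_placements)

    clean = puncta_vol + axon_vol + soma_vol
    # exact per-region sums of the pre-noise deposit
    sums = np.bincount(labels.ravel(), weights=clean.ravel(),
                       minlength=int(labels.max()) + 1)
    region_sums = {r.id: float(sums[r.id]) if r.id < sums.size else 0.0 for r in ont}

    class_labels = np.zeros(annotation.shape, dtype=np.uint8)
    gray_ids = [r.id for r in ont if r.tissue_class == "gray"]
    white_ids = [r.id for r in ont if r.tissue_class == "white"]
    class_labels[np.isin(labels, gray_ids)] = TRUTH_CLASS_CODES["gray"]
    class_labels[np.isin(labels, white_ids)] = TRUTH_CLASS_CODES["white"]
    # a structure's extent is its FWHM (half the peak), the standard
    # definition of spot size; amplitudes jitter in [0.5, 1] x nominal,
    # so half of the mean per-blob peak is 0.375 x the nominal amplitude
    class_labels[puncta_vol > 0.375 * cfg.puncta_amplitude] = TRUTH_CLASS_CODES["synapse"]
    class_labels[axon_vol > 0.5 * cfg.axon_amplitude] = TRUTH_CLASS_CODES["axon"]
    class_labels[soma_vol > 0.5 * cfg.soma_amplitude] = TRUTH_CLASS_CODES["soma"]

    noisy = _add_noise(clean, cfg, rng)
    truth = PhantomTruth(region_sums=region_sums, class_labels=class_labels,
                         soma_placements=soma_placements, seed=int(seed),
                         masked_total=float(clean[labels > 0].sum(dtype=np.float64)))
    return ImageVolume(noisy, annotation.voxel_size_um, channel="signal"), truth


# ---------------------------------------------------------------------------
# deformation


def _physical_center_of(shape, voxel_size_um):
    nz, ny, nx = shape
    vz, vy, vx = voxel_size_um
    return ((nx - 1) / 2.0 * vx, (ny - 1) / 2.0 * vy, (nz - 1) / 2.0 * vz)


def deform_sample(volumes: Mapping[str, ImageVolume | AnnotationVolume],
                  cfg: PhantomConfig, seed: int, magnitude: float = 1.0,
                  ) -> tuple[dict, TransformChain]:
    """Apply a known rigid + affine + elastic deformation to a sample.

    ``magnitude`` scales every deformation component; 0 yields the
    identity.  Annotations move with nearest-neighbour interpolation,
    intensity volumes with linear interpolation.

    Returns ``(moved, chain, parameters)``: the moved volumes, the
    exact transform chain used (mapping moved-space points back to the
    source grid, the resampling convention), and the scalar parameters
    it was built from.

    Raises ValueError if the deformation pushes tissue out of frame.
    """
    rng = np.random.default_rng(seed)
    ref = next(iter(volumes.values()))
    shape = ref.shape if isinstance(ref, ImageVolume) else ref.labels.shape
    voxel = ref.voxel_size_um
    vz, vy, vx = voxel
    geometry = FixedGeometry(shape=tuple(shape), voxel_size_um=tuple(voxel))
    center = _physical_center_of(shape, voxel)

    m = float(magnitude)
    params = {
        "translation_vox": (m * rng.uniform(-cfg.translation_vox, cfg.translation_vox),
                            m * rng.uniform(-cfg.translation_vox, cfg.translation_vox)),
        "rotation_deg": m * rng.uniform(-cfg.rotation_deg, cfg.rotation_deg),
        "scale": (1.0 + m * rng.uniform(-cfg.scale_jitter, cfg.scale_jitter),
                  1.0 + m * rng.uniform(-cfg.scale_jitter, cfg.scale_jitter)),
        "shear": m * rng.uniform(-cfg.shear_jitter, cfg.shear_jitter),
        "elastic_amp_vox": m * cfg.elastic_amp_vox,
    }

    steps: list[TransformStep] = []
    rigid = sitk.Euler3DTransform()
    rigid.SetCenter(center)
    rigid.SetRotation(0.0, 0.0, math.radians(params["rotation_deg"]))
    ty, tx = params["translation_vox"]
    rigid.SetTranslation((tx * vx, ty * vy, 0.0))
    steps.append(TransformStep("rigid", rigid))

    aff = sitk.AffineTransform(3)
    aff.SetCenter(center)
    sx, sy = params["scale"][1], params["scale"][0]
    h = params["shear"]
    aff.SetMatrix((sx, h, 0.0,
                   h, sy, 0.0,
                   0.0, 0.0, 1.0))
    steps.append(TransformStep("affine", aff))

    if params["elastic_amp_vox"] > 0:
        ref_img = geometry.reference_image()
        bsp = sitk.BSplineTransformInitializer(ref_img, [int(c) for c in cfg.elastic_mesh])
        n = len(bsp.GetParameters())
        coeffs = rng.uniform(-params["elastic_amp_vox"], params["elastic_amp_vox"], size=n)
        # zero out the z displacement component (last third of parameters)
        coeffs[2 * n // 3:] = 0.0
        coeffs[: n // 3] *= vx
        coeffs[n // 3: 2 * n // 3] *= vy
        bsp.SetParameters(tuple(coeffs))
        steps.append(TransformStep("bspline", bsp))

    chain = TransformChain(steps=steps, fixed_geometry=geometry)

    from .registration import apply_transform

    moved: dict = {}
    for name, vol in volumes.items():
        if isinstance(vol, AnnotationVolume):
            lbl = apply_transform(vol.as_volume(), chain, interpolation="nearest")
            moved[name] = AnnotationVolume(lbl.data.astype(vol.labels.dtype),
                                           vol.voxel_size_um, vol.ontology,
                                           midline_x=vol.midline_x)
        else:
            interp = "nearest" if np.issubdtype(vol.data.dtype, np.integer) else "linear"
            moved[name] = apply_transform(vol, chain, interpolation="linear"
                                          if interp == "linear" else "nearest")

    for name, vol in volumes.items():
        if isinstance(vol, AnnotationVolume):
            before = int(np.count_nonzero(vol.labels))
            after = int(np.count_nonzero(moved[name].labels))
            scale_area = params["scale"][0] * params["scale"][1]
            if before and after < 0.95 * before / max(scale_area, 1e-9):
                raise ValueError(
                    f"deformation pushed tissue out of frame: annotated voxels "
                    f"{before} -> {after}")

    return moved, chain, dict(params)


def make_known_chain(shape: tuple[int, int, int],
                     voxel_size_um: tuple[float, float, float],
                     translation_vox: tuple[float, float] = (0.0, 0.0),
                     rotation_deg: float = 0.0,
                     scale: tuple[float, float] = (1.0, 1.0),
                     shear: float = 0.0) -> TransformChain:
    """Build an exact in-plane rigid(+affine) chain with given parameters.

    ``translation_vox`` is (y, x); ``scale`` is (y, x) about the volume
    centre.  Useful for controlled transform-recovery experiments where
    the applied deformation must hit prescribed magnitudes exactly.
    """
    vz, vy, vx = voxel_size_um
    center = _physical_center_of(shape, voxel_size_um)
    steps: list[TransformStep] = []
    rigid = sitk.Euler3DTransform()
    rigid.SetCenter(center)
    rigid.SetRotation(0.0, 0.0, math.radians(rotation_deg))
    ty, tx = translation_vox
    rigid.SetTranslation((tx * vx, ty * vy, 0.0))
    steps.append(TransformStep("rigid", rigid))
    if scale != (1.0, 1.0) or shear != 0.0:
        aff = sitk.AffineTransform(3)
        aff.SetCenter(center)
        sy, sx = scale
        aff.SetMatrix((sx, shear, 0.0, shear, sy, 0.0, 0.0, 0.0, 1.0))
        steps.append(TransformStep("affine", aff))
    return TransformChain(steps=steps,
                          fixed_geometry=FixedGeometry(tuple(shape), tuple(voxel_size_um)))


# ---------------------------------------------------------------------------
# cohorts


def generate_cohort(cfg: PhantomConfig,
                    n_per_group: Mapping[str, int] | int,
                    group_effects: Mapping[str, Mapping[int, float] | float] | None,
                    seed: int,
                    deform: bool = True,
                    template: tuple[ImageVolume, AnnotationVolume] | None = None,
                    ) -> tuple[list[CohortSample], ImageVolume, AnnotationVolume]:
    """Generate a multi-group phantom cohort with known effects.

    ``group_effects`` maps group name -> either a scalar density
    multiplier or a {region_id: multiplier} mapping (missing regions
    default to 1.0); every effect key must name a group present in
    ``n_per_group``.  Each sample gets an independent signal deposit
    and (if ``deform``) an independent deformation; all samples share
    one template-space anatomy.

    Returns (samples, template autofluorescence, template annotation).
    """
    if isinstance(n_per_group, int):
        groups = {g: n_per_group for g in (group_effects or {"control": 1.0})}
    else:
        groups = dict(n_per_group)
    if not groups:
        raise ValueError("no groups requested")
    for g, n in groups.items():
        if n < 1:
            raise ValueError(f"n_per_group must be >= 1 (group {g!r} has {n})")
    effects = dict(group_effects or {})
    unknown_groups = [g for g in effects if g not in groups]
    if unknown_groups:
        raise ValueError(f"group_effects references unknown groups: {unknown_groups}")

    ss = np.random.SeedSequence(int(seed))
    template_seed = int(ss.generate_state(1)[0] % (2**31 - 1))
    if template is None:
        template = generate_template_phantom(cfg, template_seed)
    autofluor, annotation = template
    base_density = cfg.puncta_density
    if base_density is None:
        base_density = default_density_profile(annotation.ontology)

    samples: list[CohortSample] = []
    child_seeds = ss.spawn(sum(groups.values()))
    k = 0
    for group in groups:
        eff = effects.get(group, 1.0)
        if isinstance(eff, Mapping):
            unknown = [rid for rid in eff if annotation.ontology.get(int(rid)) is None]
            if unknown:
                raise ValueError(f"group {group!r} effect references unknown regions: {unknown}")
            dens = {rid: d * float(eff.get(rid, 1.0)) for rid, d in base_density.items()}
        else:
            dens = {rid: d * float(eff) for rid, d in base_density.items()}
        for i in range(groups[group]):
            s_rng = child_seeds[k].generate_state(2)
            k += 1
            dep_seed = int(s_rng[0] % (2**31 - 1))
            def_seed = int(s_rng[1] % (2**31 - 1))
            sample_cfg = replace(cfg, puncta_density=dens)
            signal, truth = deposit_signal(annotation, sample_cfg, dep_seed)
            if deform:
                moved, chain, params = deform_sample(
                    {"autofluorescence": autofluor, "signal": signal,
                     "annotation": annotation},
                    cfg, def_seed)
                truth.transform_parameters = params
                samples.append(CohortSample(
                    sample_id=f"{group}_{i + 1}", group=group,
                    autofluorescence=moved["autofluorescence"],
                    signal=moved["signal"],
                    annotation_moved=moved["annotation"],
                    truth=truth, true_chain=chain, seed=dep_seed))
            else:
                samples.append(CohortSample(
                    sample_id=f"{group}_{i + 1}", group=group,
                    autofluorescence=autofluor, signal=signal,
                    annotation_moved=annotation,
                    truth=truth, true_chain=None, seed=dep_seed))
    return samples, autofluor, annotation
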