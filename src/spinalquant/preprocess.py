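"""Raw-section preprocessing: acquisition accounting, MIP, downsampling,
depth padding and per-section recentering.

Raw acquisition produces, per physical section, several optical planes
per emission channel as mosaic tiles; after stitching (out of scope
here) each (section, plane, channel) is one 2-D image.  These
operations convert such stacks into registration-ready volumes: the
optical planes of each physical section are collapsed by maximum
intensity projection, images are area-downsampled to the working pixel
size, the stack is padded or cropped to a fixed number of sections at
the caudal end, and each section's tissue centroid is shifted to the
image centre to help registration initialisation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .volume import ImageVolume

__all__ = [
    "AcquisitionGeometry",
    "acquisition_accounting",
    "mip_project",
    "downsample_xy",
    "pad_or_crop_depth",
    "recenter_sections",
]


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Mosaic/stack geometry of a serial two-photon acquisition."""

    mosaic_rows: int
    mosaic_cols: int
    sections: int
    optical_planes: int
    channels: int
    lateral_um_per_px: float = 0.875
    axial_um: float = 20.0

    def __post_init__(self):
        for name in ("mosaic_rows", "mosaic_cols", "sections", "optical_planes", "channels"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


def acquisition_accounting(g: AcquisitionGeometry) -> tuple[int, int]:
    """Tile and stitched-image counts implied by the geometry.

    All emission channels are collected simultaneously during one tile
    scan, so the tile count is rows x cols x sections x planes, while
    stitching emits one 2-D image per (section, plane, channel):
    n_stitched = sections x planes x channels.
    """
    n_tiles = g.mosaic_rows * g.mosaic_cols * g.sections * g.optical_planes
    n_stitched = g.sections * g.optical_planes * g.channels
    return n_tiles, n_stitched


def mip_project(planes: Sequence[np.ndarray]) -> np.ndarray:
    """Maximum intensity projection across the optical planes of one section."""
    if len(planes) == 0:
        raise ValueError("mip_project needs at least one plane")
    arrs = [np.asarray(p) for p in planes]
    shape = arrs[0].shape
    for i, a in enumerate(arrs[1:], 1):
        if a.shape != shape:
            raise ValueError(f"plane {i} shape {a.shape} != plane 0 shape {shape}")
    return np.maximum.reduce(arrs)


def _area_weights(n_in: int, ratio: float) -> tuple[int, np.ndarray]:
    """Row-stochastic area-overlap matrix for 1-D downsampling by ``ratio``."""
    n_out = max(int(np.floor(n_in / ratio)), 1)
    w = np.zeros((n_out, n_in))
    for i in range(n_out):
        lo, hi = i * ratio, (i + 1) * ratio
        j0, j1 = int(np.floor(lo)), int(np.ceil(hi))
        for j in range(j0, min(j1, n_in)):
            w[i, j] = min(hi, j + 1) - max(lo, j)
        w[i] /= w[i].sum()
    return n_out, w


def downsample_xy(image: np.ndarray, source_um_per_px: float,
                  target_um_per_px: float) -> np.ndarray:
    """Anti-aliased area downsampling of a 2-D section image.

    Each output pixel is the area-weighted mean of the input pixels it
    covers, so the mean intensity of smooth images is preserved.  The
    target spacing must be >= the source spacing (this is a
    downsampling step, not an interpolator).
    """
    if target_um_per_px < source_um_per_px:
        raise ValueError(
            f"target spacing {target_um_per_px} um < source {source_um_per_px} um; "
            "downsample_xy only reduces resolution")
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("downsample_xy expects a 2-D section image")
    ratio = target_um_per_px / source_um_per_px
    if ratio == 1.0:
        return img.copy()
    _, wy = _area_weights(img.shape[0], ratio)
    _, wx = _area_weights(img.shape[1], ratio)
    return wy @ img @ wx.T


def pad_or_crop_depth(volume: ImageVolume, target_sections: int = 200) -> ImageVolume:
    """Force the stack to exactly ``target_sections`` along Z.

    Shorter stacks are padded with blank (zero) sections appended at
    the caudal end; longer stacks are cropped by dropping caudal
    excess.  Retained sections are untouched.
    """
    if target_sections < 1:
        raise ValueError("target_sections must be >= 1")
    nz = volume.n_sections
    if nz == target_sections:
        return volume.copy()
    if nz > target_sections:
        return ImageVolume(volume.data[:target_sections].copy(),
                           volume.voxel_size_um, volume.channel)
    pad = np.zeros((target_sections - nz,) + volume.data.shape[1:], dtype=volume.data.dtype)
    return ImageVolume(np.concatenate([volume.data, pad], axis=0),
                       volume.voxel_size_um, volume.channel)


def _section_centroid(section: np.ndarray) -> tuple[float, float] | None:
    """Centroid (y, x) of the largest tissue component, or None if blank.

    Tissue is segmented by Otsu's threshold over the nonzero
    intensities, then the largest 4-connected component is kept.
    """
    from scipy import ndimage
    from skimage.filters import threshold_otsu

    nz_vals = section[section > 0]
    if nz_vals.size < 16 or np.ptp(nz_vals) == 0:
        return None
    thr = threshold_otsu(nz_vals)
    mask = section > thr
    if not mask.any():
        return None
    lab, n = ndimage.label(mask)  # default structure = 4-connectivity
    if n == 0:
        return None
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    biggest = int(np.argmax(sizes)) + 1
    cy, cx = ndimage.center_of_mass(lab == biggest)
    return float(cy), float(cx)


def recenter_sections(volume: ImageVolume) -> tuple[ImageVolume, np.ndarray]:
    """Shift each section so its tissue centroid sits at the image centre.

    Shifts are integer pixels (no resampling blur); blank sections get
    shift (0, 0).  Returns the recentered volume and the (Z, 2) array
    of applied (dy, dx) shifts.
    """
    nz, ny, nx = volume.shape
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    out = np.zeros_like(volume.data)
    shifts = np.zeros((nz, 2), dtype=int)
    for z in range(nz):
        c = _section_centroid(volume.data[z])
        if c is None:
            out[z] = volume.data[z]
            continue
        dy = int(round(cy - c[0]))
        dx = int(round(cx - c[1]))
        shifts[z] = (dy, dx)
        out[z] = _shift_int(volume.data[z], dy, dx)
    return ImageVolume(out, volume.voxel_size_um, volume.channel), shifts


def _shift_int(img: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """Integer-pixel shift with zero fill (no wrap-around)."""
    out = np.zeros_like(img)
    ny, nx = img.shape
    ys = slice(max(dy, 0), min(ny + dy, ny))
    xs = slice(max(dx, 0), min(nx + dx, nx))
    ys_src = slice(max(-dy, 0), min(ny - dy, ny))
    xs_src = slice(max(-dx, 0), min(nx - dx, nx))
    out[ys, xs] = img[ys_src, xs_src]
    return out
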