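"""File formats: multi-page TIFF volumes, NIfTI label volumes,
per-section raw TIFF trees, truth/metadata JSON and manifest CSV.

Voxel sizes ride along in headers wherever the format supports it
(ImageJ-style TIFF metadata, NIfTI zooms); units are micrometres
everywhere.
"""

from __future__ import annotations

import json
import os
import re
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .atlas import AnnotationVolume, RegionOntology
from .volume import ImageVolume

__all__ = [
    "save_volume_tiff",
    "load_volume_tiff",
    "save_annotation_nifti",
    "load_annotation_nifti",
    "save_sections_tree",
    "load_sections_tree",
    "save_truth_json",
    "load_truth_json",
]


def save_volume_tiff(volume: ImageVolume, path) -> None:
    """Write a volume as a multi-page TIFF with ImageJ voxel metadata."""
    import tifffile

    vz, vy, vx = volume.voxel_size_um
    data = volume.data
    if data.dtype == np.float64:
        data = data.astype(np.float32)
    tifffile.imwrite(
        path, data, imagej=True,
        resolution=(1.0 / vx, 1.0 / vy),
        metadata={"spacing": vz, "unit": "um", "axes": "ZYX",
                  "channel_role": volume.channel})


def load_volume_tiff(path, channel: str = "") -> ImageVolume:
    import tifffile

    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        vz = vy = vx = 1.0
        if tif.imagej_metadata:
            vz = float(tif.imagej_metadata.get("spacing", 1.0))
            channel = channel or tif.imagej_metadata.get("channel_role", "")
        page = tif.pages[0]
        res = page.tags.get("XResolution")
        if res is not None:
            num, den = res.value
            if num:
                vx = den / num
        res = page.tags.get("YResolution")
        if res is not None:
            num, den = res.value
            if num:
                vy = den / num
    if data.ndim == 2:
        data = data[None]
    return ImageVolume(data, (vz, vy, vx), channel=channel)


def save_annotation_nifti(annotation: AnnotationVolume, path,
                          ontology_path=None) -> None:
    """Write the label grid as NIfTI (int32) with voxel sizes in the
    header; optionally write the ontology JSON next to it."""
    import nibabel as nib

    vz, vy, vx = annotation.voxel_size_um
    # NIfTI is (x, y, z) ordered on disk
    arr = np.ascontiguousarray(annotation.labels.astype(np.int32).transpose(2, 1, 0))
    img = nib.Nifti1Image(arr, affine=np.diag([vx, vy, vz, 1.0]))
    img.header.set_zooms((vx, vy, vz))
    nib.save(img, str(path))
    if ontology_path is not None:
        annotation.ontology.to_json(ontology_path)


def load_annotation_nifti(path, ontology: RegionOntology | str,
                          midline_x: int | None = None) -> AnnotationVolume:
    import nibabel as nib

    if not isinstance(ontology, RegionOntology):
        ontology = RegionOntology.from_json(ontology)
    img = nib.load(str(path))
    vx, vy, vz = img.header.get_zooms()[:3]
    labels = np.asarray(img.dataobj).astype(np.int32).transpose(2, 1, 0)
    return AnnotationVolume(labels, (float(vz), float(vy), float(vx)),
                            ontology, midline_x=midline_x)


_SECTION_RE = re.compile(r"^(\d{4})_(\w+)_(\w+)\.tif$")


def save_sections_tree(root, sample: str,
                       sections: Mapping[tuple[int, str, str], np.ndarray]) -> None:
    """Write per-section TIFFs named {sample}/{section:04d}_{plane}_{channel}.tif."""
    import tifffile

    base = Path(root) / sample
    base.mkdir(parents=True, exist_ok=True)
    for (sec, plane, channel), img in sections.items():
        tifffile.imwrite(base / f"{sec:04d}_{plane}_{channel}.tif", np.asarray(img))


def load_sections_tree(root, sample: str,
                       channel: str) -> dict[int, dict[str, np.ndarray]]:
    """Read one channel of a section tree: {section: {plane: image}}."""
    import tifffile

    base = Path(root) / sample
    if not base.is_dir():
        raise FileNotFoundError(f"sample directory not found: {base}")
    out: dict[int, dict[str, np.ndarray]] = {}
    for name in sorted(os.listdir(base)):
        m = _SECTION_RE.match(name)
        if not m or m.group(3) != channel:
            continue
        sec, plane = int(m.group(1)), m.group(2)
        out.setdefault(sec, {})[plane] = tifffile.imread(base / name)
    return out


def save_truth_json(truth, path) -> None:
    """Persist phantom ground truth (region sums, soma placements, seed)."""
    payload = {
        "seed": truth.seed,
        "region_sums": {str(k): v for k, v in truth.region_sums.items()},
        "soma_placements": truth.soma_placements,
        "transform_parameters": truth.transform_parameters,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_truth_json(path) -> dict:
    with open(path) as fh:
        payload = json.load(fh)
    payload["region_sums"] = {int(k): float(v)
                              for k, v in payload["region_sums"].items()}
    return payload
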