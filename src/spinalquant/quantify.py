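"""Region-wise accumulation of thresholded probability-map signal.

The quantification unit is the summed probability-map intensity of one
signal class within one atlas region, per sample: a sample x class x
region matrix.  Sums are exact (integer voxel accumulation), so for
each sample and class the region entries add up to the total map
intensity inside the annotated mask.  Normalisation and aggregation
views (by level, lamina, hemicord or motor pool; ipsi/contralateral
relative to the injection side) are derived from this matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .atlas import AnnotationVolume, RegionOntology
from .classify import ProbabilityMapSet

__all__ = ["QuantMatrix", "quantify_regions", "normalize", "aggregate"]

NORMALIZATION_MODES = ("none", "total_signal", "axon_reference")


@dataclass
class QuantMatrix:
    """Tidy sample x class x region quantification table.

    ``table`` columns: sample, group, class, region_id, region_name,
    level, lamina, pool, tract, hemicord, tissue_class, value.  The
    ``normalization`` tag records which mode produced ``value``.
    """

    table: pd.DataFrame
    ontology: RegionOntology
    normalization: str = "none"

    def __post_init__(self):
        if (self.table["value"] < 0).any():
            raise ValueError("quantification values must be >= 0")

    def values_for(self, sample: str, cls: str) -> pd.Series:
        sub = self.table[(self.table["sample"] == sample) & (self.table["class"] == cls)]
        return sub.set_index("region_id")["value"]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, ontology: RegionOntology,
                 normalization: str = "none") -> "QuantMatrix":
        return cls(pd.read_csv(path), ontology, normalization)


def _region_row(rec) -> dict:
    return {
        "region_id": rec.id, "region_name": rec.name, "level": rec.level,
        "lamina": rec.lamina, "pool": rec.pool, "tract": rec.tract,
        "hemicord": rec.hemicord, "tissue_class": rec.tissue_class,
    }


def quantify_regions(maps: ProbabilityMapSet, annotation: AnnotationVolume,
                     sample: str = "sample", group: str = "",
                     classes: Sequence[str] | None = None) -> QuantMatrix:
    """Sum map intensity over every region mask, per signal class.

    ``maps`` must already be in template space on the annotation's
    grid.  Background voxels (label 0) are excluded, as are the
    scheme's non-signal classes (gray/white/background are trained
    only as negatives for visualisation).
    """
    if maps.shape != annotation.shape:
        raise ValueError(
            f"probability-map grid {maps.shape} does not match annotation grid "
            f"{annotation.shape}")
    use_classes = list(classes if classes is not None
                       else maps.scheme.signal_classes or maps.scheme.names)
    labels = annotation.labels.ravel()
    minlength = int(labels.max()) + 1
    rows = []
    for cls_name in use_classes:
        vol = maps.maps[cls_name]
        sums = np.bincount(labels, weights=vol.data.ravel().astype(np.float64),
                           minlength=minlength)
        for rec in annotation.ontology:
            val = float(sums[rec.id]) if rec.id < minlength else 0.0
            rows.append({"sample": sample, "group": group, "class": cls_name,
                         **_region_row(rec), "value": val})
    return QuantMatrix(pd.DataFrame(rows), annotation.ontology, normalization="none")


def concat(matrices: Sequence[QuantMatrix]) -> QuantMatrix:
    """Stack per-sample matrices into one cohort matrix."""
    if not matrices:
        raise ValueError("nothing to concatenate")
    modes = {m.normalization for m in matrices}
    if len(modes) != 1:
        raise ValueError(f"mixed normalization modes: {modes}")
    return QuantMatrix(pd.concat([m.table for m in matrices], ignore_index=True),
                       matrices[0].ontology, normalization=modes.pop())


def normalize(qm: QuantMatrix, mode: str = "total_signal",
              axon_class: str = "axon") -> QuantMatrix:
    """Per-sample normalisation of the quantification matrix.

    total_signal divides each sample's entries by that sample's grand
    total over all classes and regions; axon_reference divides by the
    sample's classified axon signal within white-matter regions (a
    labeling-efficiency proxy).  A zero denominator raises, naming the
    sample.
    """
    if mode not in NORMALIZATION_MODES:
        raise ValueError(f"mode must be one of {NORMALIZATION_MODES}, got {mode!r}")
    if mode == "none":
        return QuantMatrix(qm.table.copy(), qm.ontology, normalization="none")
    table = qm.table.copy()
    for sample, idx in table.groupby("sample").groups.items():
        sub = table.loc[idx]
        if mode == "total_signal":
            denom = float(sub["value"].sum())
        else:
            white = sub[(sub["class"] == axon_class) & (sub["tissue_class"] == "white")]
            denom = float(white["value"].sum())
        if denom == 0:
            raise ValueError(f"zero normalization denominator for sample {sample!r} "
                             f"(mode={mode})")
        table.loc[idx, "value"] = sub["value"] / denom
    return QuantMatrix(table, qm.ontology, normalization=mode)


AGGREGATE_KEYS = ("level", "lamina", "hemicord", "pool")


def aggregate(qm: QuantMatrix, by: str | Sequence[str],
              percent_within: Sequence[str] | None = None,
              injection_side: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Sum entries within an ontology grouping.

    ``by`` is one or more of level | lamina | hemicord | pool (always
    alongside sample and class).  ``percent_within`` rescales values to
    percentages summing to 100 within the named axes (plus sample and
    class).  ``injection_side`` maps sample -> "left"|"right" and adds
    a laterality column (ipsilateral = hemicord matching the cord side
    of the injected tract's terminals is experiment-specific, so
    laterality is simply hemicord == injection side ? "ipsilateral" :
    "contralateral").
    """
    keys = [by] if isinstance(by, str) else list(by)
    for k in keys:
        if k not in AGGREGATE_KEYS:
            raise ValueError(f"unknown aggregation key {k!r}; choose from {AGGREGATE_KEYS}")
    table = qm.table.copy()
    if injection_side is not None:
        side = table["sample"].map(dict(injection_side))
        if side.isna().any():
            missing = sorted(table.loc[side.isna(), "sample"].unique())
            raise ValueError(f"injection side missing for samples: {missing}")
        table["laterality"] = np.where(table["hemicord"] == side,
                                       "ipsilateral", "contralateral")
    group_cols = ["sample", "group", "class"] + keys
    if injection_side is not None and "hemicord" in keys:
        group_cols.append("laterality")
    out = (table.groupby(group_cols, dropna=False)["value"].sum().reset_index())
    if percent_within:
        norm_cols = ["sample", "class"] + [c for c in percent_within if c in out.columns]
        totals = out.groupby(norm_cols, dropna=False)["value"].transform("sum")
        with np.errstate(invalid="ignore", divide="ignore"):
            out["percent"] = np.where(totals > 0, 100.0 * out["value"] / totals, 0.0)
    return out
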