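"""Region ontology and annotation-volume data model.

The cervical cord is organised as cervical levels C1-C8 along Z.  Within
each level the gray matter is subdivided into Rexed laminae 1-10 per
hemicord (left/right of the midline); motoneuron pools are subregions of
lamina 9; white matter is subdivided into named tracts.  Every
quantified region therefore carries a (level, lamina-or-pool-or-tract,
hemicord) address plus a unique positive integer id used as the voxel
label in the annotation volume.  Label 0 is reserved for background.

Lamina 6 does not exist at levels C1-C3; the ontology builder enforces
this rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .volume import ImageVolume

__all__ = [
    "CERVICAL_LEVELS",
    "DEFAULT_MOTOR_POOLS",
    "RegionRecord",
    "RegionOntology",
    "AnnotationVolume",
    "build_region_ontology",
    "region_lookup",
]

CERVICAL_LEVELS: tuple[str, ...] = ("C1", "C2", "C3", "C4", "C5", "C6", "C7", "C8")

#: Named motoneuron pools of lamina 9 and the levels at which each is
#: present.  The axial pool spans the whole cervical cord; limb pools
#: appear in the cervical enlargement.
DEFAULT_MOTOR_POOLS: dict[str, tuple[str, ...]] = {
    "trapezius": ("C1", "C2", "C3", "C4"),
    "phrenic": ("C3", "C4", "C5"),
    "biceps": ("C5", "C6"),
    "forearm extensor": ("C6", "C7", "C8"),
    "forearm flexor": ("C7", "C8"),
    "axial": CERVICAL_LEVELS,
}

HEMICORDS = ("left", "right")

#: Laminae absent at rostral levels.
_LAMINA6_ABSENT = ("C1", "C2", "C3")


def default_laminae_rule(level: str) -> tuple[int, ...]:
    """Laminae present at a cervical level: 1-10, minus 6 at C1-C3."""
    laminae = range(1, 11)
    if level in _LAMINA6_ABSENT:
        return tuple(l for l in laminae if l != 6)
    return tuple(laminae)


@dataclass(frozen=True)
class RegionRecord:
    """One atlas region: a (level, subdivision, hemicord) address.

    ``lamina`` is an int 1-10 for laminar gray regions and ``None`` for
    motor pools and white-matter tracts, whose names live in ``pool``
    and ``tract`` respectively.  Motor pools are subregions of lamina 9.
    """

    id: int
    name: str
    level: str
    hemicord: str
    tissue_class: str  # "gray" | "white"
    lamina: int | None = None
    pool: str | None = None
    tract: str | None = None

    def __post_init__(self):
        if self.id <= 0:
            raise ValueError(f"region id must be > 0, got {self.id}")
        if self.level not in CERVICAL_LEVELS:
            raise ValueError(f"unknown cervical level {self.level!r}")
        if self.hemicord not in HEMICORDS:
            raise ValueError(f"hemicord must be left|right, got {self.hemicord!r}")
        if self.tissue_class not in ("gray", "white"):
            raise ValueError(f"tissue_class must be gray|white, got {self.tissue_class!r}")
        n_kind = sum(x is not None for x in (self.lamina, self.pool, self.tract))
        if n_kind != 1:
            raise ValueError("exactly one of lamina, pool, tract must be set")
        if self.lamina is not None and not 1 <= self.lamina <= 10:
            raise ValueError(f"lamina must be in 1..10, got {self.lamina}")
        if self.lamina == 6 and self.level in _LAMINA6_ABSENT:
            raise ValueError(f"lamina 6 does not exist at {self.level}")

    @property
    def subdivision(self) -> str:
        """Human-readable lamina / pool / tract label."""
        if self.lamina is not None:
            return f"lamina {self.lamina}"
        return self.pool if self.pool is not None else self.tract  # type: ignore[return-value]

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "name": self.name,
            "level": self.level,
            "hemicord": self.hemicord,
            "tissue_class": self.tissue_class,
            "lamina": self.lamina,
            "pool": self.pool,
            "tract": self.tract,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "RegionRecord":
        return cls(**{k: d.get(k) for k in (
            "id", "name", "level", "hemicord", "tissue_class", "lamina", "pool", "tract")})


@dataclass
class RegionOntology:
    """Catalogue of atlas regions with unique positive ids."""

    regions: list[RegionRecord]
    version: str = "0"

    def __post_init__(self):
        ids = [r.id for r in self.regions]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate region ids in ontology")
        names = [r.name for r in self.regions]
        if len(set(names)) != len(names):
            raise ValueError("duplicate region names in ontology")
        self._by_id = {r.id: r for r in self.regions}

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def __getitem__(self, region_id: int) -> RegionRecord:
        return self._by_id[region_id]

    def get(self, region_id: int) -> RegionRecord | None:
        return self._by_id.get(region_id)

    @property
    def ids(self) -> list[int]:
        return [r.id for r in self.regions]

    def select(self, **criteria) -> list[RegionRecord]:
        """Regions matching all given field values, e.g. select(level="C4")."""
        out = []
        for r in self.regions:
            if all(getattr(r, k) == v for k, v in criteria.items()):
                out.append(r)
        return out

    # -- serialization ---------------------------------------------------

    def to_json(self, path=None) -> str:
        payload = {"version": self.version,
                   "regions": [r.to_dict() for r in self.regions]}
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "RegionOntology":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            text = str(source)
            if text.lstrip().startswith("{"):
                payload = json.loads(text)
            else:
                with open(text) as fh:
                    payload = json.load(fh)
        return cls(regions=[RegionRecord.from_dict(d) for d in payload["regions"]],
                   version=payload["version"])


@dataclass
class AnnotationVolume:
    """Integer label grid in template space plus its ontology.

    ``midline_x`` is the x column index separating the hemicords: left
    hemicord voxels have x < midline_x, right hemicord voxels have
    x >= midline_x.
    """

    labels: np.ndarray
    voxel_size_um: tuple[float, float, float]
    ontology: RegionOntology
    midline_x: int | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("annotation labels must be 3-D (Z,Y,X)")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("annotation labels must be an integer array")
        if self.midline_x is None:
            self.midline_x = self.labels.shape[2] // 2

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def as_volume(self) -> ImageVolume:
        return ImageVolume(self.labels, self.voxel_size_um, channel="annotation")

    def region_mask(self, region_id: int) -> np.ndarray:
        return self.labels == region_id

    def validate(self) -> None:
        """Check label/ontology consistency and hemicord sidedness."""
        present = np.unique(self.labels)
        present = present[present != 0]
        unknown = [int(v) for v in present if self.ontology.get(int(v)) is None]
        if unknown:
            raise ValueError(f"annotation contains labels absent from ontology: {unknown}")
        x_idx = np.arange(self.labels.shape[2])
        for v in present:
            rec = self.ontology[int(v)]
            cols = x_idx[self.region_mask(int(v)).any(axis=(0, 1))]
            if rec.hemicord == "left" and cols.size and cols.max() >= self.midline_x:
                raise ValueError(f"left region {rec.name} crosses midline x={self.midline_x}")
            if rec.hemicord == "right" and cols.size and cols.min() < self.midline_x:
                raise ValueError(f"right region {rec.name} crosses midline x={self.midline_x}")


def build_region_ontology(
    levels: Sequence[str] = CERVICAL_LEVELS,
    laminae_per_level: Callable[[str], Iterable[int]] | Mapping[str, Iterable[int]] | None = None,
    motor_pools: Mapping[str, Sequence[str]] | None = None,
    white_tracts: Mapping[str, Sequence[str]] | None = None,
    version: str = "0",
) -> RegionOntology:
    """Build a region ontology with deterministic id assignment.

    Parameters
    ----------
    levels:
        Cervical levels to include (subset of C1-C8).
    laminae_per_level:
        Rule giving the laminae present at each level; a callable, a
        mapping level -> laminae, or None for the default rule (1-10,
        lamina 6 absent at C1-C3).  Requesting lamina 6 at C1-C3 is an
        error.
    motor_pools:
        Mapping pool name -> levels at which the pool is present; one
        region per (pool, level, hemicord).  Pools are lamina 9
        subregions and are carved out of lamina 9 in annotations.
    white_tracts:
        Mapping tract name -> levels; one white-matter region per
        (tract, level, hemicord).

    Ids are assigned 1..N in a fixed traversal order (level, then
    lamina ascending, then pools, then tracts; left before right), so
    the same arguments always produce the same ontology.
    """
    for lv in levels:
        if lv not in CERVICAL_LEVELS:
            raise ValueError(f"unknown cervical level {lv!r}")
    if laminae_per_level is None:
        rule = default_laminae_rule
    elif callable(laminae_per_level):
        rule = laminae_per_level
    else:
        mapping = dict(laminae_per_level)
        def rule(level: str) -> Iterable[int]:
            return mapping.get(level, ())

    regions: list[RegionRecord] = []
    next_id = 1

    def add(**kw):
        nonlocal next_id
        regions.append(RegionRecord(id=next_id, **kw))
        next_id += 1

    ordered_levels = [lv for lv in CERVICAL_LEVELS if lv in levels]
    for lv in ordered_levels:
        for lam in sorted(rule(lv)):
            for hemi in HEMICORDS:
                add(name=f"{lv} lamina {lam} {hemi}", level=lv, hemicord=hemi,
                    tissue_class="gray", lamina=int(lam))
    if motor_pools:
        for pool, pool_levels in motor_pools.items():
            for lv in ordered_levels:
                if lv not in pool_levels:
                    continue
                for hemi in HEMICORDS:
                    add(name=f"{lv} {pool} pool {hemi}", level=lv, hemicord=hemi,
                        tissue_class="gray", pool=pool)
    if white_tracts:
        for tract, tract_levels in white_tracts.items():
            for lv in ordered_levels:
                if lv not in tract_levels:
                    continue
                for hemi in HEMICORDS:
                    add(name=f"{lv} {tract} {hemi}", level=lv, hemicord=hemi,
                        tissue_class="white", tract=tract)
    return RegionOntology(regions=regions, version=version)


def region_lookup(annotation: AnnotationVolume, voxel: tuple[int, int, int]) -> RegionRecord | None:
    """Region record at a (z, y, x) voxel; None for background (label 0).

    Raises IndexError for out-of-bounds voxels (negative indices are
    out of bounds here: voxel addresses are absolute grid positions).
    """
    z, y, x = voxel
    shape = annotation.labels.shape
    if not (0 <= z < shape[0] and 0 <= y < shape[1] and 0 <= x < shape[2]):
        raise IndexError(f"voxel {voxel} outside annotation grid {shape}")
    label = int(annotation.labels[z, y, x])
    if label == 0:
        return None
    rec = annotation.ontology.get(label)
    if rec is None:
        raise ValueError(f"voxel {voxel} carries label {label} absent from ontology")
    return rec
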