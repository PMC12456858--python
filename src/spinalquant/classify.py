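"""Random-forest pixel classification into 8-bit probability maps.

Sections are classified pixelwise from a bank of multiscale image
features (intensity, Gaussian smoothing, gradient magnitude,
Laplacian-of-Gaussian, Hessian and structure-tensor eigenvalues) by a
random forest trained on sparse brush annotations, the standard
interactive-segmentation recipe for fluorescence microscopy.  Class
probabilities are exported as 8-bit maps (0 -> 0%, 255 -> 100%), and a
fixed intensity-preserving threshold removes low-probability noise
before quantification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .volume import ImageVolume

__all__ = [
    "ClassScheme",
    "SYNAPSE_SCHEME",
    "SOMA_SCHEME",
    "SparseLabels",
    "ProbabilityMapSet",
    "PixelClassifier",
    "DEFAULT_FEATURE_SCALES",
    "extract_features",
    "train_classifier",
    "predict_probability_maps",
    "threshold_probability",
]

#: feature scales (pixels), the ladder interactive segmentation tools use.
DEFAULT_FEATURE_SCALES: tuple[float, ...] = (0.7, 1.0, 1.6, 3.5, 5.0)

#: Default probability threshold (8-bit scale).
DEFAULT_THRESHOLD: int = 86

#: Per-scale feature names, in stack order (raw image is prepended once).
FEATURE_NAMES = ("gaussian", "gradient_magnitude", "laplacian_of_gaussian",
                 "hessian_eig0", "hessian_eig1", "structure_eig0", "structure_eig1")


@dataclass(frozen=True)
class ClassScheme:
    """Ordered, unique class names; the quantified signal classes are
    listed in ``signal_classes`` (tissue/background classes are used
    only for visualisation and are excluded from quantification)."""

    names: tuple[str, ...]
    signal_classes: tuple[str, ...] = ()

    def __post_init__(self):
        if len(self.names) < 2:
            raise ValueError("a class scheme needs >= 2 classes")
        if len(set(self.names)) != len(self.names):
            raise ValueError("class names must be unique")
        unknown = set(self.signal_classes) - set(self.names)
        if unknown:
            raise ValueError(f"signal classes not in scheme: {sorted(unknown)}")

    def index(self, name: str) -> int:
        return self.names.index(name)

    def __len__(self) -> int:
        return len(self.names)


SYNAPSE_SCHEME = ClassScheme(
    names=("presynaptic_terminal", "axon", "gray_matter", "white_matter", "background"),
    signal_classes=("presynaptic_terminal", "axon"))

SOMA_SCHEME = ClassScheme(
    names=("soma", "process", "gray_matter", "white_matter", "background"),
    signal_classes=("soma", "process"))


@dataclass
class SparseLabels:
    """Brush annotations on one section: rows of (y, x, class index)."""

    section_index: int
    coords: np.ndarray          # (N, 2) int (y, x)
    classes: np.ndarray         # (N,) int class indices

    def __post_init__(self):
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=int))
        self.classes = np.asarray(self.classes, dtype=int).ravel()
        if self.coords.shape[0] != self.classes.shape[0]:
            raise ValueError("coords and classes must have equal length")

    def validate(self, shape: tuple[int, int], n_classes: int) -> None:
        ny, nx = shape
        if ((self.coords[:, 0] < 0).any() or (self.coords[:, 0] >= ny).any()
                or (self.coords[:, 1] < 0).any() or (self.coords[:, 1] >= nx).any()):
            raise ValueError("label coordinates out of section bounds")
        if (self.classes < 0).any() or (self.classes >= n_classes).any():
            raise ValueError("label class index out of range")


@dataclass
class ProbabilityMapSet:
    """Per-class 8-bit probability volumes on a common grid.

    Pixel value v encodes probability v/255; per-voxel sums over
    classes lie in [250, 255] (floor rounding of a unit simplex).
    """

    maps: dict[str, ImageVolume]
    scheme: ClassScheme
    threshold: int | None = None

    def __post_init__(self):
        for name in self.maps:
            if name not in self.scheme.names:
                raise ValueError(f"map {name!r} not in class scheme")

    @property
    def shape(self):
        return next(iter(self.maps.values())).shape

    def class_sum(self) -> np.ndarray:
        """Per-voxel sum over class maps (uint16)."""
        return np.sum([m.data.astype(np.uint16) for m in self.maps.values()], axis=0)

    def argmax_labels(self) -> np.ndarray:
        """Per-voxel winning class index (into scheme.names)."""
        stack = np.stack([self.maps[n].data for n in self.scheme.names if n in self.maps])
        names = [n for n in self.scheme.names if n in self.maps]
        win = np.argmax(stack, axis=0)
        lut = np.array([self.scheme.index(n) for n in names])
        return lut[win]


# ---------------------------------------------------------------------------
# features


def extract_features(section: np.ndarray,
                     scales: Sequence[float] = DEFAULT_FEATURE_SCALES) -> np.ndarray:
    """Multiscale per-pixel feature stack for one 2-D section.

    For a single-channel (H, W) section the stack is
    ``1 + 7 * len(scales)`` deep: the raw image plus, per scale,
    Gaussian smoothing, gradient magnitude, Laplacian of Gaussian and
    the two eigenvalues each of the Hessian and the structure tensor.
    Multichannel input (C, H, W) concatenates the per-channel stacks.
    Deterministic; no sampling involved.
    """
    from scipy import ndimage
    from skimage.feature import hessian_matrix, hessian_matrix_eigvals, structure_tensor
    from skimage.feature import structure_tensor_eigenvalues

    if len(scales) == 0:
        raise ValueError("at least one feature scale is required")
    if any(s <= 0 for s in scales):
        raise ValueError("feature scales must be > 0")
    section = np.asarray(section, dtype=np.float32)
    if section.ndim == 3:
        return np.concatenate([extract_features(c, scales) for c in section], axis=0)
    if section.ndim != 2:
        raise ValueError("section must be 2-D (H, W) or (C, H, W)")

    feats = [section]
    for s in scales:
        smooth = ndimage.gaussian_filter(section, s)
        gy = ndimage.gaussian_filter(section, s, order=(1, 0))
        gx = ndimage.gaussian_filter(section, s, order=(0, 1))
        feats.append(smooth)
        feats.append(np.hypot(gy, gx))
        feats.append(ndimage.gaussian_laplace(section, s))
        H = hessian_matrix(section, sigma=s, order="rc", use_gaussian_derivatives=True)
        e0, e1 = hessian_matrix_eigvals(H)
        feats.extend([e0, e1])
        A = structure_tensor(section, sigma=max(s, 0.5), order="rc")
        t0, t1 = structure_tensor_eigenvalues(A)
        feats.extend([t0, t1])
    return np.stack(feats).astype(np.float32)


# ---------------------------------------------------------------------------
# training / prediction


@dataclass
class PixelClassifier:
    """Trained random forest plus the feature/scheme context it needs."""

    model: object
    scheme: ClassScheme
    scales: tuple[float, ...]
    seed: int
    training_accuracy: float
    n_channels: int = 1


def _gather_training_set(samples, scheme, scales):
    X, y = [], []
    n_ch = None
    for section, labels in samples:
        arr = np.asarray(section)
        shape2d = arr.shape[-2:]
        labels.validate(shape2d, len(scheme))
        ch = 1 if arr.ndim == 2 else arr.shape[0]
        if n_ch is None:
            n_ch = ch
        elif ch != n_ch:
            raise ValueError("inconsistent channel counts across training sections")
        feats = extract_features(arr, scales)
        X.append(feats[:, labels.coords[:, 0], labels.coords[:, 1]].T)
        y.append(labels.classes)
    return np.concatenate(X), np.concatenate(y), n_ch


def train_classifier(samples: Sequence[tuple[np.ndarray, SparseLabels]],
                     scheme: ClassScheme,
                     seed: int,
                     scales: Sequence[float] = DEFAULT_FEATURE_SCALES,
                     n_trees: int = 100) -> PixelClassifier:
    """Train a random forest on sparsely labelled sections.

    Every class in the scheme must have at least one labelled pixel
    (a forest that has never seen a class cannot emit calibrated
    probabilities for it).  Deterministic given ``seed``.
    """
    from sklearn.ensemble import RandomForestClassifier

    X, y, n_ch = _gather_training_set(samples, scheme, scales)
    present = set(np.unique(y).tolist())
    missing = [scheme.names[i] for i in range(len(scheme)) if i not in present]
    if missing:
        raise ValueError(f"no training pixels for classes: {missing}")
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=int(seed),
                                    n_jobs=1)
    forest.fit(X, y)
    acc = float(forest.score(X, y))
    return PixelClassifier(model=forest, scheme=scheme, scales=tuple(scales),
                           seed=int(seed), training_accuracy=acc, n_channels=n_ch)


def predict_probability_maps(clf: PixelClassifier,
                             sections: Sequence[np.ndarray],
                             voxel_size_um: tuple[float, float, float] = (60.0, 10.0, 10.0),
                             ) -> ProbabilityMapSet:
    """Classify a stack of sections into per-class 8-bit volumes.

    Vote fractions are scaled by 255 and floored, which keeps every
    per-voxel class sum within [255 - n_classes + 1, 255].
    """
    n_classes = len(clf.scheme)
    first = np.asarray(sections[0])
    shape2d = first.shape[-2:]
    out = np.zeros((n_classes, len(sections)) + shape2d, dtype=np.uint8)
    class_order = np.asarray(clf.model.classes_)
    for z, section in enumerate(sections):
        arr = np.asarray(section)
        if arr.shape[-2:] != shape2d:
            raise ValueError(f"section {z} shape {arr.shape[-2:]} != {shape2d}")
        ch = 1 if arr.ndim == 2 else arr.shape[0]
        if ch != clf.n_channels:
            raise ValueError(f"section {z} has {ch} channels, model expects {clf.n_channels}")
        feats = extract_features(arr, clf.scales)
        flat = feats.reshape(feats.shape[0], -1).T
        proba = clf.model.predict_proba(flat)
        full = np.zeros((flat.shape[0], n_classes), dtype=np.float32)
        full[:, class_order] = proba
        scaled = np.floor(full * 255.0).astype(np.uint8)
        out[:, z] = scaled.T.reshape(n_classes, *shape2d)
    maps = {name: ImageVolume(out[i], voxel_size_um, channel=name)
            for i, name in enumerate(clf.scheme.names)}
    return ProbabilityMapSet(maps=maps, scheme=clf.scheme)


def threshold_probability(maps: ProbabilityMapSet | ImageVolume,
                          tau: int = DEFAULT_THRESHOLD,
                          classes: Sequence[str] | None = None):
    """Zero out voxels below the probability threshold tau.

    Voxels with value >= tau KEEP their original value (the denoise is
    intensity-preserving because downstream quantification sums map
    intensities, not a binary mask).  For a map set, only the scheme's
    signal classes are thresholded by default; tissue/background maps
    pass through untouched.
    """
    if not 0 <= tau <= 255:
        raise ValueError(f"threshold must be in [0, 255], got {tau}")
    if isinstance(maps, ImageVolume):
        data = maps.data.copy()
        data[data < tau] = 0
        return ImageVolume(data, maps.voxel_size_um, maps.channel)
    target = set(classes if classes is not None else maps.scheme.signal_classes
                 or maps.scheme.names)
    new_maps = {}
    for name, vol in maps.maps.items():
        if name in target:
            new_maps[name] = threshold_probability(vol, tau)
        else:
            new_maps[name] = vol.copy()
    return ProbabilityMapSet(maps=new_maps, scheme=maps.scheme, threshold=tau)
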