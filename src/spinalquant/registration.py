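"""Sample-to-template volumetric registration.

The alignment strategy mirrors standard serial-section atlas pipelines:
a multistep chain of rigid, affine and b-spline stages, each optimised
over a multiresolution pyramid with Mattes mutual information as the
similarity metric, followed (optionally) by a landmark-based affine
refinement solved in closed form from paired fiducial points.

Conventions
-----------
* All transforms map points of the FIXED (template) space into the
  MOVING (sample) space, the convention required for resampling the
  sample onto the template grid.
* A :class:`TransformChain` holds stages in the order they were fitted;
  when applied, the chain composes right-to-left (the last stage is
  evaluated first), matching SimpleITK's moving-initial-transform
  composition.
* Physical units are micrometres; b-spline grid spacing is configured
  in millimetres and converted at this boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import SimpleITK as sitk

from .volume import ImageVolume

__all__ = [
    "TransformStep",
    "TransformChain",
    "RegistrationConfig",
    "FiducialSet",
    "register_multistep",
    "landmark_affine",
    "refine_with_landmarks",
    "apply_transform",
    "mutual_information",
]

MM_TO_UM = 1000.0

_STEP_KINDS = ("rigid", "affine", "bspline", "landmark_affine", "displacement")


@dataclass
class TransformStep:
    """One fitted stage: a kind tag plus the underlying SimpleITK transform."""

    kind: str
    transform: sitk.Transform

    def __post_init__(self):
        if self.kind not in _STEP_KINDS:
            raise ValueError(f"unknown transform kind {self.kind!r}")
        if self.kind in ("rigid", "affine", "landmark_affine"):
            det = _linear_determinant(self.transform)
            if det <= 0:
                raise ValueError(f"{self.kind} transform has non-positive Jacobian determinant {det}")

    def to_dict(self) -> dict:
        t = self.transform
        return {
            "kind": self.kind,
            "transform_class": t.GetName(),
            "parameters": list(t.GetParameters()),
            "fixed_parameters": list(t.GetFixedParameters()),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TransformStep":
        t = _construct_transform(d["transform_class"], d["fixed_parameters"], d["parameters"])
        return cls(kind=d["kind"], transform=t)


def _linear_determinant(t: sitk.Transform) -> float:
    flat = t.Downcast() if hasattr(t, "Downcast") else t
    if hasattr(flat, "GetMatrix"):
        m = np.asarray(flat.GetMatrix()).reshape(3, 3)
        return float(np.linalg.det(m))
    return 1.0


def _construct_transform(name: str, fixed_params, params) -> sitk.Transform:
    ctor = {
        "Euler3DTransform": sitk.Euler3DTransform,
        "AffineTransform": lambda: sitk.AffineTransform(3),
        "BSplineTransform": lambda: sitk.BSplineTransform(3),
        "TranslationTransform": lambda: sitk.TranslationTransform(3),
    }.get(name)
    if ctor is None:
        raise ValueError(f"unsupported transform class {name!r}")
    t = ctor()
    t.SetFixedParameters(tuple(float(v) for v in fixed_params))
    t.SetParameters(tuple(float(v) for v in params))
    return t


@dataclass
class FixedGeometry:
    """Output grid the chain resamples into (template space)."""

    shape: tuple[int, int, int]                  # (Z, Y, X)
    voxel_size_um: tuple[float, float, float]    # (z, y, x)

    @classmethod
    def from_volume(cls, vol: ImageVolume) -> "FixedGeometry":
        return cls(shape=tuple(vol.shape), voxel_size_um=tuple(vol.voxel_size_um))

    def reference_image(self) -> sitk.Image:
        nz, ny, nx = self.shape
        img = sitk.Image(int(nx), int(ny), int(nz), sitk.sitkFloat32)
        vz, vy, vx = self.voxel_size_um
        img.SetSpacing((vx, vy, vz))
        return img


@dataclass
class TransformChain:
    """Ordered stages mapping fixed (template) points to moving points.

    ``steps[i]`` was fitted with all later steps already in place, so
    evaluation composes as steps[0](steps[1](...steps[-1](point)));
    this is what :meth:`as_composite` builds.
    """

    steps: list[TransformStep]
    fixed_geometry: FixedGeometry

    def as_composite(self) -> sitk.CompositeTransform:
        comp = sitk.CompositeTransform(3)
        for step in self.steps:
            comp.AddTransform(step.transform)
        return comp

    @property
    def kinds(self) -> list[str]:
        return [s.kind for s in self.steps]

    def prepend(self, step: TransformStep) -> "TransformChain":
        return TransformChain([step] + self.steps, self.fixed_geometry)

    def append(self, step: TransformStep) -> "TransformChain":
        return TransformChain(self.steps + [step], self.fixed_geometry)

    @classmethod
    def identity(cls, geometry: FixedGeometry) -> "TransformChain":
        return cls(steps=[], fixed_geometry=geometry)

    # -- serialization ---------------------------------------------------

    def to_json(self, path=None) -> str:
        payload = {
            "fixed_geometry": {
                "shape": list(self.fixed_geometry.shape),
                "voxel_size_um": list(self.fixed_geometry.voxel_size_um),
            },
            "steps": [s.to_dict() for s in self.steps],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "TransformChain":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            text = str(source)
            if text.lstrip().startswith("{"):
                payload = json.loads(text)
            else:
                with open(text) as fh:
                    payload = json.load(fh)
        geo = FixedGeometry(
            shape=tuple(payload["fixed_geometry"]["shape"]),
            voxel_size_um=tuple(payload["fixed_geometry"]["voxel_size_um"]),
        )
        return cls(steps=[TransformStep.from_dict(d) for d in payload["steps"]],
                   fixed_geometry=geo)


@dataclass
class RegistrationConfig:
    """Knobs for the multistep registration.

    pyramid_levels:
        Number of resolution levels (coarsest shrink factor is
        2**(levels-1), capped so the coarsest image keeps >= 4 voxels
        per axis).
    metric_bins:
        Histogram bins for Mattes mutual information.
    sampling_fraction:
        Fraction of voxels sampled per metric evaluation (random
        sampling, reseeded deterministically from ``seed``).
    iterations:
        Gradient-descent iteration cap per pyramid level.
    bspline_grid_mm:
        Final b-spline control-point spacing, millimetres per axis
        (x, y, z).
    """

    pyramid_levels: int = 6
    metric_bins: int = 32
    sampling_fraction: float = 0.10
    iterations: int = 100
    bspline_grid_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    bspline_iterations: int = 20
    bspline_levels: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.pyramid_levels < 1:
            raise ValueError("pyramid_levels must be >= 1")
        if not all(s > 0 for s in self.bspline_grid_mm):
            raise ValueError("bspline grid spacing must be positive")
        if not 0 < self.sampling_fraction <= 1:
            raise ValueError("sampling_fraction must be in (0, 1]")


@dataclass
class FiducialSet:
    """Paired corresponding points, voxel units, (z, y, x), 0-based."""

    sample_points: np.ndarray   # (N, 3)
    atlas_points: np.ndarray    # (N, 3)

    def __post_init__(self):
        self.sample_points = np.atleast_2d(np.asarray(self.sample_points, dtype=float))
        self.atlas_points = np.atleast_2d(np.asarray(self.atlas_points, dtype=float))
        if self.sample_points.shape != self.atlas_points.shape:
            raise ValueError("sample and atlas point lists must have equal shapes")
        if self.sample_points.shape[1] != 3:
            raise ValueError("points must be (N, 3) arrays of (z, y, x)")

    def __len__(self) -> int:
        return self.sample_points.shape[0]

    @classmethod
    def from_csv(cls, path) -> "FiducialSet":
        import pandas as pd

        df = pd.read_csv(path)
        need = {"point_index", "space", "z", "y", "x"}
        if not need.issubset(df.columns):
            raise ValueError(f"fiducial CSV must have columns {sorted(need)}")
        smp = df[df["space"] == "sample"].sort_values("point_index")[["z", "y", "x"]].to_numpy()
        atl = df[df["space"] == "atlas"].sort_values("point_index")[["z", "y", "x"]].to_numpy()
        return cls(smp, atl)

    def to_csv(self, path) -> None:
        import pandas as pd

        rows = []
        for i, (s, a) in enumerate(zip(self.sample_points, self.atlas_points)):
            rows.append({"point_index": i, "space": "sample", "z": s[0], "y": s[1], "x": s[2]})
            rows.append({"point_index": i, "space": "atlas", "z": a[0], "y": a[1], "x": a[2]})
        pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# metric helpers


def mutual_information(fixed: ImageVolume, moving: ImageVolume,
                       transform: sitk.Transform | None = None,
                       bins: int = 32) -> float:
    """Mattes mutual information of (fixed, transform(moving)).

    Returned on SimpleITK's scale where MORE NEGATIVE is better; the
    convenience wrapper negates it so larger = more information.
    """
    f = fixed.to_sitk()
    m = moving.to_sitk()
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=bins)
    reg.SetMetricSamplingStrategy(reg.NONE)
    reg.SetInterpolator(sitk.sitkLinear)
    if transform is None:
        transform = sitk.Transform(3, sitk.sitkIdentity)
    reg.SetInitialTransform(transform, inPlace=False)
    value = reg.MetricEvaluate(f, m)
    return -float(value)


def _pyramid_schedule(shape_xyz: Sequence[int], levels: int) -> tuple[list[int], list[float]]:
    """Shrink factors / smoothing sigmas, coarsest first, size-capped."""
    min_dim = min(shape_xyz)
    shrinks = []
    for lvl in range(levels - 1, -1, -1):
        s = 2 ** lvl
        while s > 1 and min_dim // s < 4:
            s //= 2
        shrinks.append(max(s, 1))
    sigmas = [max(s / 2.0, 0.0) if s > 1 else 0.0 for s in shrinks]
    return shrinks, sigmas


def _make_method(fixed_img, cfg: RegistrationConfig, learning_rate: float,
                 min_step: float) -> sitk.ImageRegistrationMethod:
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=cfg.metric_bins)
    reg.SetMetricSamplingStrategy(reg.RANDOM)
    reg.SetMetricSamplingPercentage(cfg.sampling_fraction, int(cfg.seed) % (2**31 - 1) + 1)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=learning_rate,
        minStep=min_step,
        numberOfIterations=cfg.iterations,
        relaxationFactor=0.6,
        gradientMagnitudeTolerance=1e-6,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    shrinks, sigmas = _pyramid_schedule(fixed_img.GetSize(), cfg.pyramid_levels)
    reg.SetShrinkFactorsPerLevel(shrinks)
    reg.SetSmoothingSigmasPerLevel(sigmas)
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOff()
    return reg


def _content_overlaps(fixed: ImageVolume, moving: ImageVolume) -> bool:
    return bool(np.any(fixed.data > 0) and np.any(moving.data > 0))


def register_multistep(moving: ImageVolume, fixed: ImageVolume,
                       cfg: RegistrationConfig,
                       stages: Sequence[str] = ("rigid", "affine", "bspline"),
                       ) -> TransformChain:
    """Fit the rigid -> affine -> b-spline chain aligning moving to fixed.

    Each stage is initialised with the composition of all previously
    fitted stages and optimises only its own parameters; the returned
    chain therefore applies stages right-to-left (b-spline innermost).

    Raises ValueError when either volume is empty (the intensity metric
    is undefined without overlapping content).
    """
    for s in stages:
        if s not in ("rigid", "affine", "bspline"):
            raise ValueError(f"unknown registration stage {s!r}")
    if not _content_overlaps(fixed, moving):
        raise ValueError(
            "registration metric undefined: fixed and/or moving volume has no "
            f"nonzero content (fixed max {np.max(fixed.data)}, moving max {np.max(moving.data)})")

    f_img = fixed.to_sitk()
    m_img = moving.to_sitk()
    geometry = FixedGeometry.from_volume(fixed)
    steps: list[TransformStep] = []
    prior: sitk.Transform | None = None

    for stage in stages:
        if stage == "rigid":
            init = sitk.CenteredTransformInitializer(
                f_img, m_img, sitk.Euler3DTransform(),
                sitk.CenteredTransformInitializerFilter.GEOMETRY)
            opt = sitk.Euler3DTransform(init)
            reg = _make_method(f_img, cfg, learning_rate=2.0, min_step=1e-3)
        elif stage == "affine":
            opt = sitk.AffineTransform(3)
            opt.SetCenter(_physical_center(f_img))
            reg = _make_method(f_img, cfg, learning_rate=1.0, min_step=1e-4)
        else:  # bspline
            gx, gy, gz = (g * MM_TO_UM for g in cfg.bspline_grid_mm)
            size = f_img.GetSize()
            spacing = f_img.GetSpacing()
            mesh = [max(1, int(round(size[d] * spacing[d] / g)))
                    for d, g in enumerate((gx, gy, gz))]
            opt = sitk.BSplineTransformInitializer(f_img, mesh)
            # the deformable stage has hundreds of parameters; a
            # quasi-Newton optimiser over a short 2-level schedule is
            # far cheaper than gradient descent at full depth
            reg = sitk.ImageRegistrationMethod()
            reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=cfg.metric_bins)
            reg.SetMetricSamplingStrategy(reg.RANDOM)
            reg.SetMetricSamplingPercentage(cfg.sampling_fraction,
                                            int(cfg.seed) % (2**31 - 1) + 1)
            reg.SetInterpolator(sitk.sitkLinear)
            reg.SetOptimizerAsLBFGSB(numberOfIterations=cfg.bspline_iterations)
            n_lv = max(1, int(cfg.bspline_levels))
            shrinks = [2 ** l for l in range(n_lv - 1, -1, -1)]
            reg.SetShrinkFactorsPerLevel(shrinks)
            reg.SetSmoothingSigmasPerLevel([s / 2.0 if s > 1 else 0.0 for s in shrinks])
            reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOff()
        if prior is not None:
            reg.SetMovingInitialTransform(prior)
        reg.SetInitialTransform(opt, inPlace=True)
        reg.Execute(f_img, m_img)
        steps.append(TransformStep(kind=stage if stage != "bspline" else "bspline",
                                   transform=opt))
        prior_comp = sitk.CompositeTransform(3)
        for st in steps:
            prior_comp.AddTransform(st.transform)
        prior = prior_comp

    return TransformChain(steps=steps, fixed_geometry=geometry)


def _physical_center(img: sitk.Image) -> tuple[float, float, float]:
    size = img.GetSize()
    center_index = [(s - 1) / 2.0 for s in size]
    return img.TransformContinuousIndexToPhysicalPoint(center_index)


def landmark_affine(points: FiducialSet,
                    voxel_size_um: tuple[float, float, float] = (1.0, 1.0, 1.0),
                    ) -> tuple[TransformStep, float]:
    """Closed-form least-squares affine from paired fiducials.

    Solves for the 3x4 affine A minimising
    sum_i || A [atlas_i; 1] - sample_i ||^2  in physical coordinates,
    i.e. the returned transform maps atlas (fixed) points to sample
    (moving) points and can be inserted directly into a resampling
    chain.  Returns (step, residual RMS in micrometres).

    Requires >= 4 pairs in general position (non-coplanar atlas
    points); degenerate configurations raise ValueError.
    """
    n = len(points)
    if n < 4:
        raise ValueError(f"landmark affine needs >= 4 point pairs, got {n}")
    vz, vy, vx = voxel_size_um
    scale = np.array([vz, vy, vx])
    # physical coordinates in (x, y, z) order for the ITK transform
    atl = (points.atlas_points * scale)[:, ::-1]
    smp = (points.sample_points * scale)[:, ::-1]
    design = np.hstack([atl, np.ones((n, 1))])
    if np.linalg.matrix_rank(design) < 4:
        raise ValueError("degenerate fiducial configuration: atlas points are coplanar")
    sol, *_ = np.linalg.lstsq(design, smp, rcond=None)   # (4, 3)
    matrix = sol[:3].T                                    # (3, 3), rows map to x,y,z out
    offset = sol[3]
    if np.linalg.det(matrix) <= 0:
        raise ValueError("landmark affine solution has non-positive determinant")
    residual = design @ sol - smp
    rms = float(np.sqrt(np.mean(np.sum(residual ** 2, axis=1))))
    t = sitk.AffineTransform(3)
    t.SetMatrix(tuple(matrix.ravel()))
    t.SetTranslation(tuple(offset))
    return TransformStep(kind="landmark_affine", transform=t), rms


def refine_with_landmarks(chain: TransformChain, points: FiducialSet,
                          moving: ImageVolume | None = None,
                          fixed: ImageVolume | None = None,
                          cfg: RegistrationConfig | None = None,
                          replace_chain: bool = False,
                          ) -> tuple[TransformChain, float]:
    """Add a fiducial-based affine stage to a fitted chain.

    By default the landmark affine is prepended (applied last, in
    sample space) and, when ``moving``/``fixed``/``cfg`` are given, the
    b-spline stage is re-run on top of the refined linear alignment.
    With ``replace_chain`` the landmark affine replaces the automated
    result entirely — for samples whose autofluorescence differs too
    much from the template for the intensity metric to work.

    Returns (refined chain, landmark residual RMS in micrometres).
    """
    voxel = chain.fixed_geometry.voxel_size_um if moving is None else moving.voxel_size_um
    step, rms = landmark_affine(points, voxel_size_um=voxel)
    if replace_chain:
        refined = TransformChain(steps=[step], fixed_geometry=chain.fixed_geometry)
    else:
        refined = TransformChain(
            steps=[step] + [s for s in chain.steps if s.kind != "bspline"],
            fixed_geometry=chain.fixed_geometry)
    if moving is not None and fixed is not None and cfg is not None:
        rerun = register_multistep(
            apply_transform(moving, refined, "linear"), fixed, cfg,
            stages=("bspline",))
        refined = refined.append(rerun.steps[0])
    return refined, rms


def apply_transform(volume: ImageVolume, chain: TransformChain,
                    interpolation: str = "linear") -> ImageVolume:
    """Resample a moving-space volume onto the chain's fixed grid.

    ``interpolation`` is "linear" for intensities/probability maps and
    "nearest" for label volumes.  Points mapping outside the source
    volume fill with 0.
    """
    interps = {"linear": sitk.sitkLinear, "nearest": sitk.sitkNearestNeighbor}
    if interpolation not in interps:
        raise ValueError(f"interpolation must be linear|nearest, got {interpolation!r}")
    is_label = np.issubdtype(volume.data.dtype, np.integer)
    pixel = sitk.sitkFloat32
    src = volume.to_sitk(dtype=np.float32)
    ref = chain.fixed_geometry.reference_image()
    out = sitk.Resample(src, ref, chain.as_composite(), interps[interpolation], 0.0, pixel)
    arr = sitk.GetArrayFromImage(out)
    if is_label and interpolation == "nearest":
        arr = np.rint(arr).astype(volume.data.dtype)
    elif np.issubdtype(volume.data.dtype, np.integer):
        info = np.iinfo(volume.data.dtype)
        arr = np.clip(np.rint(arr), info.min, info.max).astype(volume.data.dtype)
    return ImageVolume(arr, chain.fixed_geometry.voxel_size_um, channel=volume.channel)
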