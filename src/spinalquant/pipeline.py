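"""End-to-end orchestration: phantom cohort -> registration ->
classification -> warped, thresholded probability maps -> region
quantification -> group statistics.

This is the library-level composition of the individual stages, used
both for validation against phantom ground truth and as the reference
wiring for real cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .atlas import AnnotationVolume
from .classify import (
    SYNAPSE_SCHEME,
    ClassScheme,
    PixelClassifier,
    ProbabilityMapSet,
    SparseLabels,
    predict_probability_maps,
    threshold_probability,
    train_classifier,
)
from .phantom import TRUTH_CLASS_CODES, CohortSample
from .quantify import QuantMatrix, concat, quantify_regions
from .registration import (
    RegistrationConfig,
    TransformChain,
    apply_transform,
    register_multistep,
)
from .volume import ImageVolume

__all__ = ["PipelineConfig", "SampleResult", "sparse_labels_from_truth",
           "run_sample", "run_cohort"]

#: truth code -> index into the synapse scheme
_TRUTH_TO_SCHEME = {
    TRUTH_CLASS_CODES["synapse"]: 0,   # presynaptic_terminal
    TRUTH_CLASS_CODES["soma"]: 0,      # soma blobs count as terminal-like signal
    TRUTH_CLASS_CODES["axon"]: 1,
    TRUTH_CLASS_CODES["gray"]: 2,
    TRUTH_CLASS_CODES["white"]: 3,
    TRUTH_CLASS_CODES["background"]: 4,
}


@dataclass
class PipelineConfig:
    """Stage parameters for a cohort run."""

    registration: RegistrationConfig = field(
        default_factory=lambda: RegistrationConfig(pyramid_levels=4, iterations=60, seed=0))
    stages: tuple[str, ...] = ("rigid", "affine", "bspline")
    scheme: ClassScheme = SYNAPSE_SCHEME
    threshold: int = 86
    n_trees: int = 100
    n_label_sections: int = 5
    labels_per_class: int = 400
    feature_scales: tuple[float, ...] = (0.7, 1.0, 1.6, 3.5)
    use_autofluorescence_channel: bool = True


@dataclass
class SampleResult:
    sample: CohortSample
    chain: TransformChain
    maps_template_space: ProbabilityMapSet
    quant: QuantMatrix


def sparse_labels_from_truth(class_labels: np.ndarray, scheme_map: Mapping[int, int],
                             sections: Sequence[int], per_class: int,
                             rng: np.random.Generator) -> list[tuple[int, SparseLabels]]:
    """Draw brush-like sparse training labels from phantom truth labels.

    Emulates an annotator marking up to a handful of representative
    sections: for each scheme class, up to ``per_class`` pixels are
    sampled uniformly from that class's truth mask on the chosen
    sections.
    """
    out = []
    for z in sections:
        sec = class_labels[z]
        coords, classes = [], []
        for truth_code, scheme_idx in scheme_map.items():
            ys, xs = np.nonzero(sec == truth_code)
            if ys.size == 0:
                continue
            take = min(per_class, ys.size)
            idx = rng.choice(ys.size, size=take, replace=False)
            coords.append(np.column_stack([ys[idx], xs[idx]]))
            classes.append(np.full(take, scheme_idx))
        if coords:
            out.append((z, SparseLabels(z, np.concatenate(coords),
                                        np.concatenate(classes))))
    return out


def _training_sections(class_labels: np.ndarray, n: int) -> list[int]:
    """Pick up to n sections spanning the stack's tissue extent."""
    nz = class_labels.shape[0]
    tissue = np.nonzero((class_labels > 0).any(axis=(1, 2)))[0]
    if tissue.size == 0:
        raise ValueError("no tissue sections to label")
    picks = np.linspace(tissue.min(), tissue.max(), num=min(n, tissue.size))
    return sorted({int(round(p)) for p in picks})


def train_cohort_classifier(samples: Sequence[CohortSample], cfg: PipelineConfig,
                            seed: int) -> PixelClassifier:
    """One model per cohort, trained on sparse labels drawn from up to
    ``n_label_sections`` representative sections of each sample."""
    rng = np.random.default_rng(seed)
    training = []
    for s in samples:
        # truth labels live in template space; for training we use the
        # moved sample, so re-derive per-section labels by deforming the
        # truth class volume alongside (nearest-neighbour)
        labels_moved = s.truth.class_labels
        if s.true_chain is not None:
            lbl_vol = ImageVolume(labels_moved.astype(np.int16),
                                  s.signal.voxel_size_um)
            labels_moved = apply_transform(lbl_vol, s.true_chain, "nearest").data
        sections = _training_sections(labels_moved, cfg.n_label_sections)
        sparse = sparse_labels_from_truth(labels_moved, _TRUTH_TO_SCHEME, sections,
                                          cfg.labels_per_class, rng)
        for z, lab in sparse:
            training.append((_section_image(s, z, cfg), lab))
    return train_classifier(training, cfg.scheme, seed=int(seed),
                            scales=cfg.feature_scales, n_trees=cfg.n_trees)


def _section_image(sample: CohortSample, z: int, cfg: PipelineConfig) -> np.ndarray:
    if cfg.use_autofluorescence_channel:
        return np.stack([sample.signal.data[z], sample.autofluorescence.data[z]])
    return sample.signal.data[z]


def run_sample(sample: CohortSample, template: ImageVolume,
               annotation: AnnotationVolume, clf: PixelClassifier,
               cfg: PipelineConfig, seed: int) -> SampleResult:
    """Register one sample, classify it, warp maps, threshold, quantify."""
    from dataclasses import replace

    reg_cfg = replace(cfg.registration, seed=seed)
    chain = register_multistep(sample.autofluorescence, template, reg_cfg,
                               stages=cfg.stages)
    sections = [_section_image(sample, z, cfg)
                for z in range(sample.signal.n_sections)]
    maps = predict_probability_maps(clf, sections, sample.signal.voxel_size_um)
    warped = {name: apply_transform(vol, chain, "linear")
              for name, vol in maps.maps.items()}
    pset = ProbabilityMapSet(maps=warped, scheme=cfg.scheme)
    pset = threshold_probability(pset, cfg.threshold)
    quant = quantify_regions(pset, annotation, sample=sample.sample_id,
                             group=sample.group)
    return SampleResult(sample=sample, chain=chain, maps_template_space=pset,
                        quant=quant)


def run_cohort(samples: Sequence[CohortSample], template: ImageVolume,
               annotation: AnnotationVolume, cfg: PipelineConfig,
               seed: int) -> tuple[list[SampleResult], QuantMatrix]:
    """Classify and quantify a whole cohort with one shared model."""
    ss = np.random.SeedSequence(int(seed))
    train_seed, *reg_seeds = [int(s % (2**31 - 1))
                              for s in ss.generate_state(len(samples) + 1)]
    clf = train_cohort_classifier(samples, cfg, train_seed)
    results = [run_sample(s, template, annotation, clf, cfg, rs)
               for s, rs in zip(samples, reg_seeds)]
    return results, concat([r.quant for r in results])
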