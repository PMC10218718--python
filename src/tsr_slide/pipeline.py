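"""Workflow orchestration: classifier development and cohort TSR scoring.

Two headline workflows compose the pipeline stages into reproducible runs:

* :func:`run_dev_workflow` — tile annotated slides (overlapping, coverage
  filter), stain-normalize, train a classifier under the configured setup
  (cross-validation, early stopping, full retrain), and evaluate on patches
  tiled from held-out slides. The train/test split is at the slide level —
  patches from one slide never appear on both sides.
* :func:`run_scoring_workflow` — mask, tile (non-overlapping), normalize and
  classify every slide of a cohort, compute per-slide TSR, and, when visual
  truth values are supplied, the full evaluation table.

One global seed fans out to per-stage seeds through a fixed hash derivation,
so every artifact is reproducible from (config, seed) alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from tsr_slide.classifier import ClassifierModel, TrainConfig, run_setup
from tsr_slide.datatypes import (
    AnnotationMap,
    ClassReport,
    PatchSet,
    SlideImage,
    StainModel,
    TSRResult,
)
from tsr_slide.mask import build_tissue_mask
from tsr_slide.metrics import classification_report, tsr_eval_table
from tsr_slide.stain import DEFAULT_REFERENCE, normalize_patch
from tsr_slide.tiling import tile_training
from tsr_slide.tsr import NoTumorStromaError, estimate_slide_tsr
from tsr_slide.io import tsr_results_frame

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Numeric and structural configuration of a pipeline run.

    Defaults follow the standard protocol: 224 px patches, 64 px training
    overlap, inclusive 75% coverage filters for both tiling modes, and a 50%
    stroma-high cutoff.
    """

    patch_size: int = 224
    train_overlap: int = 64
    min_annotated: float = 0.75
    min_tissue: float = 0.75
    cutoff_percent: float = 50.0
    mask_channel: str = "saturation"
    normalize: bool = True
    stain_reference: StainModel = field(default_factory=lambda: DEFAULT_REFERENCE)
    train: TrainConfig = field(default_factory=TrainConfig)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(open(path)) or {}
        train_raw = raw.pop("train", {})
        ref_raw = raw.pop("stain_reference", None)
        cfg = cls(**raw)
        if train_raw:
            cfg.train = TrainConfig(**train_raw)
        if ref_raw:
            cfg.stain_reference = StainModel.from_dict(ref_raw)
        return cfg


def normalize_patchset(patches: PatchSet, reference: StainModel) -> PatchSet:
    normed = np.stack(
        [
            normalize_patch(p, reference=reference, fallback="passthrough")
            for p in patches.patches
        ]
    ) if len(patches) else patches.patches
    return PatchSet(
        patches=normed,
        windows=patches.windows,
        labels=patches.labels,
        params=patches.params,
    )


def tile_annotated_slides(
    slides: Sequence[tuple[SlideImage, AnnotationMap]],
    config: RunConfig,
) -> PatchSet:
    """Training-tile several annotated slides into one pooled labeled set."""
    sets = [
        tile_training(
            slide,
            annotation,
            size=config.patch_size,
            overlap=config.train_overlap,
            min_annotated=config.min_annotated,
        )
        for slide, annotation in slides
    ]
    sets = [s for s in sets if len(s)]
    if not sets:
        raise ValueError("no patches survived training tiling on any slide")
    return PatchSet(
        patches=np.concatenate([s.patches for s in sets]),
        windows=[w for s in sets for w in s.windows],
        labels=np.concatenate([s.labels for s in sets]),
        params=sets[0].params,
    )


def run_dev_workflow(
    train_slides: Sequence[tuple[SlideImage, AnnotationMap]],
    test_slides: Sequence[tuple[SlideImage, AnnotationMap]],
    config: Optional[RunConfig] = None,
    domain_set: Optional[PatchSet] = None,
) -> tuple[ClassifierModel, ClassReport]:
    """Train and evaluate a classifier with a slide-level train/test split.

    Raises if any slide id appears on both sides of the split: evaluation
    must be on slides the classifier never saw.
    """
    config = config or RunConfig()
    train_ids = {s.slide_id for s, _ in train_slides}
    test_ids = {s.slide_id for s, _ in test_slides}
    overlap = train_ids & test_ids
    if overlap:
        raise ValueError(f"slides in both train and test sets: {sorted(overlap)}")

    train_patches = tile_annotated_slides(train_slides, config)
    test_patches = tile_annotated_slides(test_slides, config)
    if config.normalize:
        train_patches = normalize_patchset(train_patches, config.stain_reference)
        test_patches = normalize_patchset(test_patches, config.stain_reference)
    logger.info(
        "dev workflow: %d train / %d test patches (%s)",
        len(train_patches), len(test_patches), config.train.setup,
    )
    model = run_setup(config.train.setup, domain_set, train_patches, config.train)
    _, pred = model.predict(test_patches)
    report = classification_report(test_patches.labels, pred)
    return model, report


def run_scoring_workflow(
    slides: Sequence[SlideImage],
    model: ClassifierModel,
    config: Optional[RunConfig] = None,
    true_tsr: Optional[dict[str, float]] = None,
) -> tuple[pd.DataFrame, Optional[dict]]:
    """Score a cohort of slides and (optionally) evaluate against truth.

    Per-slide failures (no tissue, unreadable image) are recorded in the
    result table's ``error`` column and the run continues. Evaluation is
    skipped with a notice when no truth values are given; truth maps slide
    id -> visual TSR percent on the {10, ..., 90} grid.
    """
    config = config or RunConfig()
    results: list[TSRResult] = []
    errors: list[dict] = []
    for slide in slides:
        try:
            mask = build_tissue_mask(slide, channel=config.mask_channel)
            results.append(
                estimate_slide_tsr(
                    slide,
                    model,
                    mask=mask,
                    reference=config.stain_reference,
                    size=config.patch_size,
                    min_tissue=config.min_tissue,
                    cutoff=config.cutoff_percent,
                    normalize=config.normalize,
                )
            )
        except (NoTumorStromaError, ValueError, OSError) as err:
            logger.error("slide %s failed: %s", slide.slide_id, err)
            errors.append({"slide_id": slide.slide_id, "error": str(err)})
    table = tsr_results_frame(results)
    if errors:
        table = pd.concat([table, pd.DataFrame(errors)], ignore_index=True)
    if not results:
        logger.warning("scoring workflow produced no successful slides")

    evaluation = None
    if true_tsr is not None and results:
        scored = [r for r in results if r.slide_id in true_tsr]
        missing = [r.slide_id for r in results if r.slide_id not in true_tsr]
        if missing:
            logger.warning("no truth for slides %s; excluded from evaluation", missing)
        if scored:
            evaluation = tsr_eval_table(
                [r.tsr_percent for r in scored],
                [true_tsr[r.slide_id] for r in scored],
                cutoff=config.cutoff_percent,
            )
    elif true_tsr is None:
        logger.info("no truth values supplied; evaluation skipped")
    return table, evaluation
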