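"""The tumor-stroma ratio statistic and the per-slide scoring composition.

The TSR of a slide is the patch-count ratio

    TSR = n_stroma / (n_tumor + n_stroma)

where the counts come from classifying every kept inference patch; *other*
patches influence neither numerator nor denominator. The ratio is stored as
a fraction in [0, 1] and rendered as a percent in reports. A slide with no
tumor or stroma patches has no defined TSR and raises — never a silent 0.

Dichotomization follows the prognostic convention: TSR strictly above the
cutoff (default 50%) is *stroma-high* (worse prognosis), at or below is
*stroma-low*.
"""

from __future__ import annotations

import logging
from typing import Optional, Protocol

import numpy as np

from tsr_slide.datatypes import (
    AnnotationMap,
    CLASS_NAMES,
    LABEL_CODES,
    PatchSet,
    SlideImage,
    StainModel,
    TissueMask,
    TSRResult,
)
from tsr_slide.mask import build_tissue_mask
from tsr_slide.stain import DEFAULT_REFERENCE, normalize_patch
from tsr_slide.tiling import tile_inference

logger = logging.getLogger(__name__)

STROMA_HIGH = "stroma-high"
STROMA_LOW = "stroma-low"


class NoTumorStromaError(ValueError):
    """Raised when a slide yields no tumor or stroma patches."""


class PatchClassifier(Protocol):
    """Anything that maps a PatchSet to (probabilities, class indices)."""

    def predict(self, patches: PatchSet) -> tuple[np.ndarray, np.ndarray]: ...


def compute_tsr(n_stroma: int, n_tumor: int) -> float:
    """``n_stroma / (n_tumor + n_stroma)``; *other* patches are excluded."""
    if n_stroma < 0 or n_tumor < 0:
        raise ValueError("patch counts must be non-negative")
    denom = n_stroma + n_tumor
    if denom == 0:
        raise NoTumorStromaError("no tumor or stroma patches; TSR undefined")
    return n_stroma / denom


def dichotomize(tsr_percent: float, cutoff: float = 50.0) -> str:
    """Stroma-high (strictly above cutoff) vs stroma-low (at or below)."""
    if not 0.0 <= tsr_percent <= 100.0:
        raise ValueError(f"TSR percent out of range: {tsr_percent}")
    return STROMA_HIGH if tsr_percent > cutoff else STROMA_LOW


class OracleClassifier:
    """Ground-truth-lookup classifier for synthetic slides.

    Labels each patch window by the majority tumor/stroma/other class of the
    underlying annotation map — the perfect classifier used to validate the
    scoring composition independently of any trained model.
    """

    def __init__(self, annotation: AnnotationMap):
        self.annotation = annotation

    def predict(self, patches: PatchSet) -> tuple[np.ndarray, np.ndarray]:
        codes = [LABEL_CODES[c] for c in CLASS_NAMES]
        labels = []
        for w in patches.windows:
            ys, xs = w.slice()
            win = self.annotation.labels[ys, xs]
            counts = [np.count_nonzero(win == c) for c in codes]
            labels.append(int(np.argmax(counts)))
        labels = np.array(labels, dtype=int)
        probs = np.zeros((len(labels), 3))
        if len(labels):
            probs[np.arange(len(labels)), labels] = 1.0
        return probs, labels


def estimate_slide_tsr(
    slide: SlideImage,
    model: PatchClassifier,
    mask: Optional[TissueMask] = None,
    reference: StainModel = DEFAULT_REFERENCE,
    size: int = 224,
    min_tissue: float = 0.75,
    cutoff: float = 50.0,
    normalize: bool = True,
) -> TSRResult:
    """Slide-level TSR: mask -> tile -> normalize -> classify -> count.

    Patches that fail stain normalization (near-blank) pass through
    unnormalized with a warning; they are still classified, and typically
    land in *other* where they cannot bias the ratio.

    Raises
    ------
    NoTumorStromaError
        If no patches survive tiling, or none classify as tumor or stroma.
    """
    if mask is None:
        mask = build_tissue_mask(slide)
    patches = tile_inference(slide, mask, size=size, min_tissue=min_tissue)
    if len(patches) == 0:
        raise NoTumorStromaError(
            f"slide {slide.slide_id}: no patches passed the tissue filter"
        )
    if normalize:
        normed = np.stack(
            [
                normalize_patch(p, reference=reference, fallback="passthrough")
                for p in patches.patches
            ]
        )
        patches = PatchSet(
            patches=normed, windows=patches.windows, params=patches.params
        )
    _, labels = model.predict(patches)
    n_tumor = int(np.count_nonzero(labels == 0))
    n_stroma = int(np.count_nonzero(labels == 1))
    n_other = int(np.count_nonzero(labels == 2))
    try:
        tsr = compute_tsr(n_stroma, n_tumor)
    except NoTumorStromaError as err:
        raise NoTumorStromaError(f"slide {slide.slide_id}: {err}") from None
    return TSRResult(
        n_tumor=n_tumor,
        n_stroma=n_stroma,
        n_other=n_other,
        tsr=tsr,
        stroma_class=dichotomize(100.0 * tsr, cutoff),
        cutoff_percent=cutoff,
        slide_id=slide.slide_id,
    )
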