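"""Sliding-window tiling of slides into fixed-size patches.

Two regimes are used:

* **training tiling** — overlapping windows (stride = size − overlap, default
  224 − 64 = 160 px) over an annotated slide; a window is kept iff at least
  75% of its area carries an annotation of any of the three tissue classes,
  and each kept patch is labeled by the majority annotated class;
* **inference tiling** — a non-overlapping grid (stride = size) filtered by a
  binary tissue mask: windows with less than 75% tissue are discarded and no
  labels are attached.

Both coverage thresholds are inclusive (a window at exactly 75% is kept).
Windows are half-open ``[x, x+S) × [y, y+S)``, 0-based, enumerated row-major;
partial windows at the right/bottom edges are dropped rather than padded.
"""

from __future__ import annotations

import logging

import numpy as np

from tsr_slide.datatypes import (
    AnnotationMap,
    LABEL_CODES,
    PatchSet,
    PatchWindow,
    SlideImage,
    TissueMask,
)

logger = logging.getLogger(__name__)

DEFAULT_PATCH_SIZE = 224
DEFAULT_TRAIN_OVERLAP = 64
DEFAULT_MIN_COVERAGE = 0.75

# class-index order for majority votes; earlier wins ties (tumor > stroma > other)
_TIE_ORDER_CODES = (LABEL_CODES["tumor"], LABEL_CODES["stroma"], LABEL_CODES["other"])


def enumerate_windows(
    width: int, height: int, size: int, stride: int, slide_id: str = "slide"
) -> list[PatchWindow]:
    """All fully-inside windows on the stride grid, row-major order.

    Offsets run over ``0, stride, 2*stride, …`` independently per axis; a
    window is included only if it fits entirely inside the image. An image
    smaller than one window yields an empty list (with a warning).
    """
    if size <= 0 or stride <= 0:
        raise ValueError("size and stride must be positive")
    if size > width or size > height:
        logger.warning(
            "image %dx%d smaller than window size %d: no windows", width, height, size
        )
        return []
    xs = range(0, width - size + 1, stride)
    ys = range(0, height - size + 1, stride)
    return [
        PatchWindow(x=x, y=y, size=size, slide_id=slide_id) for y in ys for x in xs
    ]


def _check_aligned(slide: SlideImage, raster: np.ndarray, what: str) -> None:
    if raster.shape[:2] != slide.pixels.shape[:2]:
        raise ValueError(
            f"{what} shape {raster.shape[:2]} does not match slide "
            f"{slide.pixels.shape[:2]}"
        )


def _majority_class_index(window_labels: np.ndarray) -> int:
    """Majority annotated class as an index into (tumor, stroma, other).

    Ties break by the fixed order tumor > stroma > other (np.argmax returns
    the first maximum over that ordering).
    """
    counts = [np.count_nonzero(window_labels == c) for c in _TIE_ORDER_CODES]
    return int(np.argmax(counts))


def tile_training(
    slide: SlideImage,
    annotation: AnnotationMap,
    size: int = DEFAULT_PATCH_SIZE,
    overlap: int = DEFAULT_TRAIN_OVERLAP,
    min_annotated: float = DEFAULT_MIN_COVERAGE,
) -> PatchSet:
    """Overlapping tiling of an annotated slide into labeled training patches.

    A window is kept iff the fraction of its pixels annotated with any of the
    three tissue classes is ``>= min_annotated``; the patch label is the
    majority annotated class within the window.
    """
    _check_aligned(slide, annotation.labels, "annotation map")
    if not 0 < overlap < size:
        raise ValueError("overlap must be in (0, size)")
    stride = size - overlap
    windows = enumerate_windows(
        slide.width, slide.height, size, stride, slide_id=slide.slide_id
    )
    annotated = np.isin(annotation.labels, _TIE_ORDER_CODES)

    kept, labels, patches = [], [], []
    area = float(size * size)
    for w in windows:
        ys, xs = w.slice()
        frac = np.count_nonzero(annotated[ys, xs]) / area
        if frac >= min_annotated:
            kept.append(w)
            labels.append(_majority_class_index(annotation.labels[ys, xs]))
            patches.append(slide.pixels[ys, xs])
    logger.info(
        "training tiling %s: %d/%d windows kept", slide.slide_id, len(kept), len(windows)
    )
    return PatchSet(
        patches=np.stack(patches) if patches else np.empty((0, size, size, 3)),
        windows=kept,
        labels=np.array(labels, dtype=int),
        params={
            "mode": "train",
            "size": size,
            "stride": stride,
            "overlap": overlap,
            "min_coverage": min_annotated,
        },
    )


def tile_inference(
    slide: SlideImage,
    mask: TissueMask,
    size: int = DEFAULT_PATCH_SIZE,
    min_tissue: float = DEFAULT_MIN_COVERAGE,
) -> PatchSet:
    """Non-overlapping tiling filtered by tissue-mask coverage (no labels)."""
    _check_aligned(slide, mask.mask, "tissue mask")
    windows = enumerate_windows(
        slide.width, slide.height, size, size, slide_id=slide.slide_id
    )
    kept, patches = [], []
    area = float(size * size)
    for w in windows:
        ys, xs = w.slice()
        if np.count_nonzero(mask.mask[ys, xs]) / area >= min_tissue:
            kept.append(w)
            patches.append(slide.pixels[ys, xs])
    logger.info(
        "inference tiling %s: %d/%d windows kept", slide.slide_id, len(kept), len(windows)
    )
    return PatchSet(
        patches=np.stack(patches) if patches else np.empty((0, size, size, 3)),
        windows=kept,
        labels=None,
        params={
            "mode": "infer",
            "size": size,
            "stride": size,
            "min_coverage": min_tissue,
        },
    )
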