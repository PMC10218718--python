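"""Tissue masking: Otsu thresholding of a slide-level channel histogram.

Classifiers in this pipeline are never shown image background or adipose
tissue, so inference tiling first removes both with a single binary mask.
Both appear near-white under H&E, which makes the HSV saturation channel a
natural separator: stained tissue is strongly saturated while background and
fat are not, giving the bimodal histogram Otsu's criterion expects. A
grayscale channel (tissue = dark) is available as an alternative.
"""

from __future__ import annotations

import logging

import numpy as np
from skimage.morphology import remove_small_objects

from tsr_slide.datatypes import SlideImage, TissueMask

logger = logging.getLogger(__name__)

N_BINS = 256


class DegenerateHistogramError(ValueError):
    """Raised when the histogram has fewer than two nonempty bins."""


def otsu_threshold(histogram: np.ndarray) -> int:
    """Otsu's optimal threshold from a 256-bin histogram.

    Returns the bin index ``t`` maximizing the between-class variance
    ``omega0 * omega1 * (mu0 - mu1)**2`` of the split into bins ``<= t`` and
    ``> t``. Ties are broken toward the lowest maximizing index, which makes
    the result deterministic.

    Raises
    ------
    DegenerateHistogramError
        If fewer than two bins are nonempty (no split separates anything).
    """
    hist = np.asarray(histogram, dtype=float)
    if hist.ndim != 1:
        raise ValueError("histogram must be 1-D")
    if np.count_nonzero(hist) < 2:
        raise DegenerateHistogramError("degenerate histogram: fewer than 2 nonempty bins")

    n_bins = hist.shape[0]
    bins = np.arange(n_bins, dtype=float)
    total = hist.sum()

    w0 = np.cumsum(hist)  # mass of class 0 for split after bin t
    w1 = total - w0
    m0 = np.cumsum(hist * bins)
    mu0 = np.divide(m0, w0, out=np.zeros(n_bins), where=w0 > 0)
    mu1 = np.divide(m0[-1] - m0, w1, out=np.zeros(n_bins), where=w1 > 0)

    sigma_b = (w0 / total) * (w1 / total) * (mu0 - mu1) ** 2
    sigma_b[w1 == 0] = -np.inf  # splits with an empty upper class are invalid
    return int(np.argmax(sigma_b))


def _channel_image(pixels: np.ndarray, channel: str) -> np.ndarray:
    """Extract the masking channel as floats in [0, 255]."""
    pixels = np.asarray(pixels, dtype=float)
    if channel == "saturation":
        mx = pixels.max(axis=2)
        mn = pixels.min(axis=2)
        sat = np.divide(mx - mn, mx, out=np.zeros_like(mx), where=mx > 0)
        return sat * 255.0
    if channel == "grayscale":
        return pixels @ np.array([0.2125, 0.7154, 0.0721])
    raise ValueError(f"unknown mask channel {channel!r}")


def build_tissue_mask(
    slide: SlideImage,
    channel: str = "saturation",
    min_object_px: int = 0,
) -> TissueMask:
    """Binary tissue mask for a slide via Otsu thresholding.

    Tissue lands on the stained side of the threshold: high saturation, or
    dark grayscale. Connected components smaller than ``min_object_px`` are
    removed (default 0: no cleanup). A blank slide (degenerate histogram)
    yields an all-false mask with a warning rather than an error, so bulk
    runs skip empty slides gracefully.
    """
    values = _channel_image(slide.pixels, channel)
    binned = np.clip(values, 0, 255).astype(np.uint8)
    hist = np.bincount(binned.ravel(), minlength=N_BINS)
    try:
        thr = otsu_threshold(hist)
    except DegenerateHistogramError:
        logger.warning("blank slide %s: degenerate histogram, empty mask", slide.slide_id)
        return TissueMask(
            mask=np.zeros(values.shape, dtype=bool),
            threshold=0.0,
            channel=channel,
            slide_id=slide.slide_id,
        )
    if channel == "saturation":
        mask = binned > thr
    else:
        mask = binned <= thr
    if min_object_px > 0:
        mask = remove_small_objects(mask, max_size=min_object_px - 1)
    return TissueMask(mask=mask, threshold=float(thr), channel=channel, slide_id=slide.slide_id)
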