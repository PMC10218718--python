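"""Macenko stain normalization for H&E images, implemented from first principles.

Under the Beer-Lambert law a transmitted intensity ``I`` relates to stain
concentrations ``c`` through the optical density ``OD = -log10(I / I0) = S c``,
where the columns of ``S`` (3x2) are the unit-norm absorption spectra of
hematoxylin and eosin. Macenko's method estimates ``S`` for an individual
image from the geometry of its OD point cloud:

1. drop near-transparent pixels (mean OD below ``beta``);
2. take the plane spanned by the two leading eigenvectors of the OD
   covariance;
3. project the surviving pixels into that plane and find the ``alpha`` and
   ``100 - alpha`` percentiles of the polar angle — the extreme directions of
   the two-stain mixture cone, which are the stain vectors themselves;
4. solve per-pixel concentrations against the estimated matrix and take the
   99th percentile per stain as a robust maximum.

Normalizing a patch then rescales its concentrations by the ratio of
reference to source maxima and re-renders them through the reference matrix,
which standardizes stain color and intensity across scanners and batches.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np

from tsr_slide.datatypes import StainModel

logger = logging.getLogger(__name__)

#: Default incident (white) intensity for 8-bit images.
DEFAULT_I0: float = 255.0
#: Percentile for the stain-cone extreme angles.
DEFAULT_ALPHA: float = 1.0
#: Mean-OD transparency threshold below which a pixel is ignored.
DEFAULT_BETA: float = 0.15
#: Minimum surviving pixels required for a stable plane estimate.
MIN_TISSUE_PIXELS: int = 50

# Widely used reference H&E absorption vectors (columns H, E), unit-normalized.
_REF = np.array(
    [
        [0.65, 0.07],
        [0.70, 0.99],
        [0.29, 0.11],
    ]
)
_REF = _REF / np.linalg.norm(_REF, axis=0, keepdims=True)

#: Global reference stain model used when no per-dataset reference is supplied.
DEFAULT_REFERENCE = StainModel(
    stain_matrix=_REF, max_concentrations=np.array([1.0, 1.0])
)


class InsufficientTissueError(ValueError):
    """Raised when too few pixels survive the transparency filter."""


def rgb_to_od(image: np.ndarray, i0: float = DEFAULT_I0) -> np.ndarray:
    """Convert RGB intensities to optical densities.

    ``OD = -log10(I / I0)`` elementwise; intensities are clipped to a floor of
    1 intensity unit so zero pixels map to a finite density.

    Parameters
    ----------
    image:
        Array whose last axis is the 3 RGB channels, values in ``(0, i0]``.
    i0:
        Incident intensity (255 for 8-bit images).
    """
    image = np.asarray(image, dtype=float)
    if image.shape[-1] != 3:
        raise ValueError(f"expected RGB input with last axis 3, got {image.shape}")
    clipped = np.clip(image, 1.0, i0)
    return -np.log10(clipped / i0)


def od_to_rgb(od: np.ndarray, i0: float = DEFAULT_I0) -> np.ndarray:
    """Invert :func:`rgb_to_od`: ``I = i0 * 10**(-OD)``, clipped to ``[0, i0]``."""
    od = np.asarray(od, dtype=float)
    return np.clip(i0 * np.power(10.0, -od), 0.0, i0)


def _order_h_first(vectors: np.ndarray) -> np.ndarray:
    """Order stain columns so hematoxylin (the more blue-heavy vector) is first.

    Hematoxylin absorbs strongly in the blue channel relative to eosin; ties
    fall back to the first principal angle (keep given order).
    """
    if vectors[2, 0] >= vectors[2, 1]:
        return vectors
    return vectors[:, ::-1]


def solve_concentrations(
    od_flat: np.ndarray, stain_matrix: np.ndarray, nonneg: bool = False
) -> np.ndarray:
    """Solve ``S c = od`` per pixel for the (N, 2) concentration matrix.

    The fast path is an unconstrained least-squares solve with negative
    concentrations clipped to zero; ``nonneg=True`` runs an exact
    non-negative solve per pixel (much slower, only needed when stains are
    strongly collinear).
    """
    od_flat = np.asarray(od_flat, dtype=float).reshape(-1, 3)
    if nonneg:
        from scipy.optimize import nnls

        out = np.empty((od_flat.shape[0], 2))
        for i, row in enumerate(od_flat):
            out[i], _ = nnls(stain_matrix, row)
        return out
    conc, *_ = np.linalg.lstsq(stain_matrix, od_flat.T, rcond=None)
    return np.clip(conc.T, 0.0, None)


def estimate_stain_matrix(
    od: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    beta: float = DEFAULT_BETA,
    min_pixels: int = MIN_TISSUE_PIXELS,
    beta_mode: str = "mean",
) -> StainModel:
    """Estimate an image's H&E stain model from its OD point cloud.

    Parameters
    ----------
    od:
        OD image ``(..., 3)`` (output of :func:`rgb_to_od`).
    alpha:
        Angle percentile; the stain directions are the ``alpha`` and
        ``100 - alpha`` percentiles of the projected polar angle.
    beta:
        Transparency threshold in OD units.
    min_pixels:
        Minimum number of surviving pixels; fewer raises
        :class:`InsufficientTissueError` (blank patch).
    beta_mode:
        ``"mean"`` keeps pixels whose channel-mean OD exceeds ``beta``
        (robust for strongly eosinophilic tissue); ``"any"`` keeps pixels
        with every channel above ``beta`` (the classic variant).

    Raises
    ------
    InsufficientTissueError
        If fewer than ``min_pixels`` pixels pass the ``beta`` filter, or the
        surviving cloud is effectively one-dimensional (single pure stain).
    """
    od_flat = np.asarray(od, dtype=float).reshape(-1, 3)
    if beta_mode == "mean":
        keep = od_flat.mean(axis=1) > beta
    elif beta_mode == "any":
        keep = np.all(od_flat > beta, axis=1)
    else:
        raise ValueError(f"unknown beta_mode {beta_mode!r}")
    od_hat = od_flat[keep]
    if od_hat.shape[0] < min_pixels:
        raise InsufficientTissueError(
            f"insufficient tissue: {od_hat.shape[0]} pixels above beta={beta} "
            f"(minimum {min_pixels})"
        )

    cov = np.cov(od_hat.T)
    eigvals, eigvecs = np.linalg.eigh(cov)
    if eigvals[-1] <= 0 or eigvals[-2] / eigvals[-1] < 1e-6:
        raise InsufficientTissueError(
            "degenerate OD cloud (single stain or constant image); "
            "cannot estimate a two-stain plane"
        )
    plane = eigvecs[:, [-1, -2]]  # two leading principal directions
    # orient the plane so projections land in a consistent half-space
    for j in range(2):
        if plane[:, j].sum() < 0:
            plane[:, j] = -plane[:, j]

    proj = od_hat @ plane
    phi = np.arctan2(proj[:, 1], proj[:, 0])
    phi_min, phi_max = np.percentile(phi, (alpha, 100.0 - alpha))
    v1 = plane @ np.array([np.cos(phi_min), np.sin(phi_min)])
    v2 = plane @ np.array([np.cos(phi_max), np.sin(phi_max)])

    vectors = np.stack([v1, v2], axis=1)
    # absorption vectors are non-negative; flip sign if needed, clip residue
    for j in range(2):
        if vectors[:, j].sum() < 0:
            vectors[:, j] = -vectors[:, j]
    vectors = np.clip(vectors, 0.0, None)
    norms = np.linalg.norm(vectors, axis=0)
    if np.any(norms < 1e-12):
        raise InsufficientTissueError("estimated stain vector collapsed to zero")
    vectors = vectors / norms
    vectors = _order_h_first(vectors)

    conc = solve_concentrations(od_hat, vectors)
    max_c = np.percentile(conc, 99.0, axis=0)
    max_c = np.maximum(max_c, 1e-8)
    return StainModel(stain_matrix=vectors, max_concentrations=max_c)


def angular_distance_deg(v1: np.ndarray, v2: np.ndarray) -> float:
    """Angle in degrees between two stain vectors (orientation-insensitive)."""
    v1 = np.asarray(v1, dtype=float).ravel()
    v2 = np.asarray(v2, dtype=float).ravel()
    cosang = abs(v1 @ v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def stain_model_angles_deg(a: StainModel, b: StainModel) -> tuple[float, float]:
    """Per-column (H, E) angular distances between two stain models."""
    return (
        angular_distance_deg(a.stain_matrix[:, 0], b.stain_matrix[:, 0]),
        angular_distance_deg(a.stain_matrix[:, 1], b.stain_matrix[:, 1]),
    )


def normalize_patch(
    patch: np.ndarray,
    reference: StainModel = DEFAULT_REFERENCE,
    alpha: float = DEFAULT_ALPHA,
    beta: float = DEFAULT_BETA,
    i0: float = DEFAULT_I0,
    nonneg: bool = False,
    fallback: str = "error",
    source: Optional[StainModel] = None,
) -> np.ndarray:
    """Map a patch's stain appearance onto a reference stain model.

    The patch's own stain matrix is estimated (unless ``source`` is given),
    per-pixel concentrations are solved against it, rescaled by the ratio of
    reference to source maximum concentrations, and re-rendered through the
    reference matrix.

    ``fallback="passthrough"`` returns the patch unchanged (with a warning)
    when the patch is too blank to estimate stains — the behaviour wanted in
    bulk inference, where an occasional near-empty patch should not abort a
    slide. ``fallback="error"`` propagates :class:`InsufficientTissueError`.
    """
    patch = np.asarray(patch)
    out_dtype = patch.dtype
    od = rgb_to_od(patch, i0=i0)
    if source is None:
        try:
            source = estimate_stain_matrix(od, alpha=alpha, beta=beta)
        except InsufficientTissueError:
            if fallback == "passthrough":
                logger.warning(
                    "normalize_patch: insufficient tissue, returning patch unchanged"
                )
                return patch
            raise
    conc = solve_concentrations(od, source.stain_matrix, nonneg=nonneg)
    scale = reference.max_concentrations / source.max_concentrations
    conc = conc * scale[None, :]
    od_norm = conc @ reference.stain_matrix.T
    rgb = od_to_rgb(od_norm.reshape(od.shape), i0=i0)
    if np.issubdtype(out_dtype, np.integer):
        return np.round(rgb).astype(out_dtype)
    return rgb.astype(out_dtype, copy=False)
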