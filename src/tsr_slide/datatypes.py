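"""Core containers shared across the pipeline.

Conventions used everywhere in the package:

* images are numpy arrays of shape ``(H, W, 3)``, RGB channel order, intensity
  range ``[0, 255]`` (``uint8`` on disk, float arrays allowed in memory for
  unquantized synthetic renderings);
* annotation / label maps are ``(H, W)`` integer arrays using the codes in
  :data:`LABEL_CODES` (0 = unannotated/background, 1 = tumor, 2 = stroma,
  3 = other, 4 = adipose);
* the classifier class order is fixed as ``("tumor", "stroma", "other")``
  (:data:`CLASS_NAMES`) and class indices 0/1/2 follow it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

#: Fixed classifier class order: index 0 = tumor, 1 = stroma, 2 = other.
CLASS_NAMES: tuple[str, str, str] = ("tumor", "stroma", "other")

#: Integer codes used in annotation maps / synthetic ground-truth label maps.
LABEL_CODES: dict[str, int] = {
    "background": 0,
    "tumor": 1,
    "stroma": 2,
    "other": 3,
    "adipose": 4,
}

#: Reverse lookup of :data:`LABEL_CODES`.
CODE_TO_NAME: dict[int, str] = {v: k for k, v in LABEL_CODES.items()}

#: Label-map codes that count as tissue the classifier sees.
TISSUE_CODES: tuple[int, int, int] = (
    LABEL_CODES["tumor"],
    LABEL_CODES["stroma"],
    LABEL_CODES["other"],
)


@dataclass
class SlideImage:
    """An RGB slide raster plus scan metadata.

    Parameters
    ----------
    pixels:
        ``(H, W, 3)`` array, intensities in ``[0, 255]``.
    mpp:
        Microns per pixel of the scan (0.5 for the scanners emulated here).
    slide_id:
        Identifier used in manifests and per-slide result tables.
    """

    pixels: np.ndarray
    mpp: float = 0.5
    slide_id: str = "slide"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(
                f"slide pixels must be (H, W, 3) RGB, got shape {self.pixels.shape}"
            )

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class AnnotationMap:
    """Integer label raster aligned to a slide (codes per :data:`LABEL_CODES`)."""

    labels: np.ndarray
    slide_id: str = "slide"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("annotation map must be a 2-D integer raster")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def class_areas(self) -> dict[str, int]:
        """Pixel count per class name, including zero-count classes."""
        return {
            name: int(np.count_nonzero(self.labels == code))
            for name, code in LABEL_CODES.items()
        }


@dataclass
class StainModel:
    """Two H&E stain vectors in optical-density space.

    ``stain_matrix`` is a 3x2 matrix whose columns are the unit-norm OD
    absorption vectors of hematoxylin (column 0) and eosin (column 1);
    ``max_concentrations`` holds the robust (99th percentile) maximum
    concentration of each stain, used to match stain intensity between a
    source image and a reference.
    """

    stain_matrix: np.ndarray
    max_concentrations: np.ndarray

    def __post_init__(self) -> None:
        self.stain_matrix = np.asarray(self.stain_matrix, dtype=float)
        self.max_concentrations = np.asarray(self.max_concentrations, dtype=float)
        if self.stain_matrix.shape != (3, 2):
            raise ValueError("stain_matrix must be 3x2 (columns = H, E)")
        if self.max_concentrations.shape != (2,):
            raise ValueError("max_concentrations must be a 2-vector")
        if np.any(self.stain_matrix < -1e-9):
            raise ValueError("stain vectors must be non-negative in OD space")
        norms = np.linalg.norm(self.stain_matrix, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("stain matrix columns must be unit norm")

    def to_dict(self) -> dict:
        return {
            "stain_matrix": self.stain_matrix.tolist(),
            "max_concentrations": self.max_concentrations.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StainModel":
        return cls(
            stain_matrix=np.array(d["stain_matrix"], dtype=float),
            max_concentrations=np.array(d["max_concentrations"], dtype=float),
        )


@dataclass
class TissueMask:
    """Boolean tissue raster (``True`` = tissue) plus the threshold that made it."""

    mask: np.ndarray
    threshold: float
    channel: str = "saturation"
    slide_id: str = "slide"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("tissue mask must be 2-D")

    @property
    def tissue_fraction(self) -> float:
        return float(self.mask.mean()) if self.mask.size else 0.0


@dataclass(frozen=True)
class PatchWindow:
    """A half-open square window ``[x, x+size) x [y, y+size)``, 0-based."""

    x: int
    y: int
    size: int = 224
    slide_id: str = "slide"

    def slice(self) -> tuple[slice, slice]:
        return slice(self.y, self.y + self.size), slice(self.x, self.x + self.size)


@dataclass
class PatchSet:
    """A collection of fixed-size patches with provenance.

    ``patches`` is a ``(N, S, S, 3)`` array; ``windows`` the matching
    window list; ``labels`` an optional ``(N,)`` integer array of class
    indices into :data:`CLASS_NAMES` (present for training tilings and
    synthetic labeled sets, absent for inference tilings).
    """

    patches: np.ndarray
    windows: list[PatchWindow] = field(default_factory=list)
    labels: Optional[np.ndarray] = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.patches = np.asarray(self.patches)
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != len(self.patches):
                raise ValueError("labels length must match patch count")

    def __len__(self) -> int:
        return len(self.patches)

    def class_counts(self) -> dict[str, int]:
        if self.labels is None:
            raise ValueError("patch set has no labels")
        return {
            name: int(np.count_nonzero(self.labels == i))
            for i, name in enumerate(CLASS_NAMES)
        }

    def subset(self, idx: Sequence[int] | np.ndarray) -> "PatchSet":
        idx = np.asarray(idx)
        return PatchSet(
            patches=self.patches[idx],
            windows=[self.windows[i] for i in idx] if self.windows else [],
            labels=None if self.labels is None else self.labels[idx],
            params=dict(self.params),
        )


@dataclass
class GroundTruth:
    """Exact ground truth emitted with every synthetic slide.

    ``expected_tsr`` is the patch-count TSR obtained by tiling the label map
    with the inference tiler parameters recorded in ``tiling_params`` (each
    kept window labeled by its majority tumor/stroma/other class);
    ``pixel_tsr`` is the pixel-area ratio ``stroma_px / (stroma_px + tumor_px)``.
    The two differ at region boundaries, so both are reported.
    """

    annotation: AnnotationMap
    region_areas: dict[str, int]
    stains: StainModel
    expected_tsr: Optional[float]
    pixel_tsr: Optional[float]
    tiling_params: dict
    class_mean_concentrations: dict[str, tuple[float, float]] = field(
        default_factory=dict
    )


@dataclass
class TSRResult:
    """Per-slide TSR estimate: patch counts, the ratio, and its dichotomization."""

    n_tumor: int
    n_stroma: int
    n_other: int
    tsr: float
    stroma_class: str
    cutoff_percent: float = 50.0
    slide_id: str = "slide"

    @property
    def tsr_percent(self) -> float:
        return 100.0 * self.tsr


@dataclass
class ClassReport:
    """3-class classification report (class order tumor/stroma/other).

    ``confusion`` rows are true classes, columns predicted. ``flags`` lists
    classes whose precision or recall was a 0/0 division (reported as 0).
    """

    confusion: np.ndarray
    accuracy: float
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    flags: list[str] = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "precision": self.precision,
                "recall": self.recall,
                "f1": self.f1,
            },
            index=list(CLASS_NAMES),
        )
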