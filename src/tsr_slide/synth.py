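"""Synthetic H&E slide and patch generation with exact ground truth.

Slides are rendered with a forward Beer-Lambert model: each pixel carries a
hematoxylin/eosin concentration pair ``c``; transmitted intensity is
``I = I0 * 10**(-S c)`` for a known 3x2 stain matrix ``S``. Tissue classes
are told apart by their stain chemistry and texture, mimicking colorectal
H&E sections:

* **tumor** — hematoxylin-dominant (dense basophilic nuclei on a light
  eosin background), speckled nuclear texture;
* **stroma** — eosin-dominant (collagen fibres, few nuclei), gentle
  fibrous intensity modulation;
* **other** — intermediate, coarse-grained mixture (debris, mucus, normal
  epithelium, smooth muscle — the grab-bag class);
* **adipose** and **background** — near-white (almost zero stain uptake),
  which is what lets one Otsu mask remove both.

Every generated slide comes with an exact pixel-level label map, per-class
areas, the generating stain model, and the expected patch-count tumor-stroma
ratio under the inference tiling parameters (computed here by a direct
brute-force window scan, independent of the production tiler).

Nothing here aims at photorealism: the goal is a forward model whose ground
truth is known exactly, so the downstream estimators can be validated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter

from tsr_slide.datatypes import (
    AnnotationMap,
    CLASS_NAMES,
    GroundTruth,
    LABEL_CODES,
    PatchSet,
    PatchWindow,
    SlideImage,
    StainModel,
    TISSUE_CODES,
)
from tsr_slide.stain import DEFAULT_I0, DEFAULT_REFERENCE

logger = logging.getLogger(__name__)

DEFAULT_PATCH_SIZE = 224


@dataclass(frozen=True)
class ClassTexture:
    """Rendering parameters for one tissue class.

    Concentration units are optical densities of the pure stain at unit
    concentration (so an ``h_range`` of (0.50, 0.90) spans deeply basophilic
    tissue). ``nuclear_density`` (nuclei per pixel^2) controls near-pure
    hematoxylin speckles — nuclei in tumor, fibroblast nuclei in stroma —
    and ``eosin_speck_density`` near-pure eosin speckles (dense cytoplasm /
    collagen clumps). Both matter beyond appearance: the pure-stain pixel
    populations anchor the extreme angles of the optical-density cloud, as
    counterstained real tissue does, and give every class a comparable
    robust concentration maximum so per-patch normalization stays gentle.
    """

    h_range: tuple[float, float]
    e_range: tuple[float, float]
    nuclear_density: float = 0.0
    nucleus_radius: tuple[float, float] = (3.0, 0.8)
    nucleus_amp: float = 0.88
    eosin_speck_density: float = 0.0
    eosin_speck_radius: tuple[float, float] = (2.5, 0.6)
    eosin_speck_amp: float = 0.85
    fiber_contrast: float = 0.0
    blob_scale: float = 8.0
    #: optional two-phase mottle: ((h_range, e_range), (h_range, e_range)) of
    #: alternating basophilic / eosinophilic phases at ``phase_scale`` px —
    #: used for the heterogeneous grab-bag class (debris, mucus, epithelium,
    #: smooth muscle), which mixes strongly and weakly nucleated components
    phases: Optional[tuple] = None
    phase_scale: float = 0.0

    def __post_init__(self) -> None:
        for lo, hi in (self.h_range, self.e_range):
            if lo < 0 or hi < lo:
                raise ValueError("concentration ranges must be non-negative and ordered")


def _default_class_textures() -> dict[str, ClassTexture]:
    return {
        "tumor": ClassTexture(
            h_range=(0.50, 0.90),
            e_range=(0.02, 0.18),
            nuclear_density=1.2e-3,
            nucleus_radius=(3.0, 0.8),
            eosin_speck_density=8e-4,
            blob_scale=6.0,
        ),
        "stroma": ClassTexture(
            h_range=(0.01, 0.12),
            e_range=(0.45, 0.85),
            nuclear_density=1.2e-3,
            nucleus_radius=(2.0, 0.5),
            fiber_contrast=0.35,
            blob_scale=10.0,
        ),
        "other": ClassTexture(
            h_range=(0.24, 0.46),
            e_range=(0.24, 0.46),
            nuclear_density=1.2e-3,
            nucleus_radius=(2.5, 0.6),
            eosin_speck_density=8e-4,
            blob_scale=18.0,
            phases=(((0.45, 0.80), (0.05, 0.25)), ((0.03, 0.15), (0.40, 0.75))),
            phase_scale=45.0,
        ),
        "adipose": ClassTexture(h_range=(0.0, 0.012), e_range=(0.0, 0.035), blob_scale=12.0),
        "background": ClassTexture(h_range=(0.0, 0.0), e_range=(0.0, 0.0)),
    }


@dataclass
class TextureParams:
    """Per-class textures plus global rendering noise.

    ``other_heterogeneity`` (0..1) widens the concentration ranges of the
    *other* class about their midpoints — that class is a mixture of several
    real tissue types and its within-class variability is a free parameter of
    the simulation.
    """

    classes: dict[str, ClassTexture] = field(default_factory=_default_class_textures)
    rgb_noise_sd: float = 1.5
    other_heterogeneity: float = 0.5

    def resolved(self) -> dict[str, ClassTexture]:
        out = dict(self.classes)
        if "other" in out and self.other_heterogeneity != 0.5:
            t = out["other"]
            w = 0.4 + 1.2 * self.other_heterogeneity  # range-width multiplier
            out["other"] = replace(
                t,
                h_range=_widen(t.h_range, w),
                e_range=_widen(t.e_range, w),
            )
        return out


def _widen(rng_pair: tuple[float, float], w: float) -> tuple[float, float]:
    lo, hi = rng_pair
    mid, half = (lo + hi) / 2.0, (hi - lo) / 2.0
    return (max(0.0, mid - half * w), mid + half * w)


# ---------------------------------------------------------------------------
# layouts


@dataclass
class SyntheticLayout:
    """Geometric layout of a synthetic slide.

    ``regions`` is an ordered list of paint operations; pixels not covered by
    any region are background. Use the class-method constructors for the
    common cases.
    """

    width: int
    height: int
    regions: list[dict] = field(default_factory=list)
    mpp: float = 0.5
    seed: int = 0

    @classmethod
    def uniform(cls, class_name: str, width: int, height: int, seed: int = 0) -> "SyntheticLayout":
        return cls(
            width=width,
            height=height,
            regions=[{"kind": "rect", "x0": 0, "y0": 0, "x1": width, "y1": height,
                      "class": class_name}],
            seed=seed,
        )

    @classmethod
    def vertical_bands(
        cls, bands: list[tuple[str, float]], width: int, height: int, seed: int = 0
    ) -> "SyntheticLayout":
        """Left-to-right bands of (class, width-fraction); fractions sum to 1."""
        total = sum(f for _, f in bands)
        if not np.isclose(total, 1.0):
            raise ValueError("band fractions must sum to 1")
        regions, x0 = [], 0
        for i, (name, frac) in enumerate(bands):
            x1 = width if i == len(bands) - 1 else x0 + int(round(frac * width))
            regions.append({"kind": "rect", "x0": x0, "y0": 0, "x1": x1, "y1": height,
                            "class": name})
            x0 = x1
        return cls(width=width, height=height, regions=regions, seed=seed)

    @classmethod
    def blobs(
        cls,
        fractions: dict[str, float],
        width: int,
        height: int,
        seed: int = 0,
        scale: float = 120.0,
    ) -> "SyntheticLayout":
        """Organic blob layout hitting the given area fractions exactly.

        A smoothed Gaussian random field is split at its empirical quantiles,
        so each class receives (to the pixel) the requested share of the
        canvas in contiguous blobs of characteristic size ``scale``.
        """
        total = sum(fractions.values())
        if not np.isclose(total, 1.0):
            raise ValueError("class fractions must sum to 1")
        return cls(
            width=width,
            height=height,
            regions=[{"kind": "blobs", "fractions": dict(fractions), "scale": scale}],
            seed=seed,
        )

    def label_map(self) -> np.ndarray:
        """Resolve the layout to a (H, W) integer label map (deterministic)."""
        labels = np.full((self.height, self.width), LABEL_CODES["background"], dtype=np.uint8)
        rng = np.random.default_rng(np.random.SeedSequence([int(self.seed), 0xA11]))
        for region in self.regions:
            if region["kind"] == "rect":
                code = LABEL_CODES[region["class"]]
                labels[region["y0"]:region["y1"], region["x0"]:region["x1"]] = code
            elif region["kind"] == "blobs":
                field_ = rng.standard_normal((self.height, self.width))
                field_ = gaussian_filter(field_, sigma=region["scale"] / 6.0)
                order = np.argsort(field_, axis=None, kind="stable")
                flat = np.empty(self.width * self.height, dtype=np.uint8)
                start = 0
                items = sorted(region["fractions"].items())
                for i, (name, frac) in enumerate(items):
                    n = (self.width * self.height - start
                         if i == len(items) - 1
                         else int(round(frac * self.width * self.height)))
                    flat[order[start:start + n]] = LABEL_CODES[name]
                    start += n
                labels = flat.reshape(self.height, self.width)
            else:
                raise ValueError(f"unknown region kind {region['kind']!r}")
        return labels


# ---------------------------------------------------------------------------
# concentration fields and rendering


def _concentration_fields(
    shape: tuple[int, int],
    texture: ClassTexture,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Hematoxylin and eosin concentration fields for one class region."""
    h_lo, h_hi = texture.h_range
    e_lo, e_hi = texture.e_range

    def smooth_field(lo: float, hi: float) -> np.ndarray:
        if hi <= 0:
            return np.zeros(shape)
        base = rng.random(shape)
        if texture.blob_scale > 0:
            base = gaussian_filter(base, sigma=texture.blob_scale / 3.0)
            lo_v, hi_v = base.min(), base.max()
            if hi_v > lo_v:
                base = (base - lo_v) / (hi_v - lo_v)
        return lo + (hi - lo) * base

    if texture.phases is not None and texture.phase_scale > 0:
        # two-phase mottle: alternating basophilic/eosinophilic components
        phase = gaussian_filter(rng.standard_normal(shape), sigma=texture.phase_scale / 3.0)
        in_a = phase > 0
        (h1, e1), (h2, e2) = texture.phases
        h = np.where(in_a, smooth_field(*h1), smooth_field(*h2))
        e = np.where(in_a, smooth_field(*e1), smooth_field(*e2))
    else:
        h = smooth_field(h_lo, h_hi)
        e = smooth_field(e_lo, e_hi)

    if texture.fiber_contrast > 0:
        theta = rng.uniform(0, np.pi)
        wavelength = rng.uniform(18.0, 36.0)
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        phase = gaussian_filter(rng.standard_normal(shape), sigma=20.0) * 6.0
        stripes = np.sin(2 * np.pi * (xx * np.cos(theta) + yy * np.sin(theta)) / wavelength + phase)
        e = np.clip(e * (1.0 + texture.fiber_contrast * stripes), 0.0, None)

    # speckles of near-pure stain: nuclei (hematoxylin) and cytoplasm/collagen
    # clumps (eosin); the other stain is suppressed inside the speckle
    _add_speckles(
        h, e, texture.nuclear_density, texture.nucleus_radius, texture.nucleus_amp, rng
    )
    _add_speckles(
        e, h, texture.eosin_speck_density, texture.eosin_speck_radius,
        texture.eosin_speck_amp, rng,
    )
    return h, e


def _add_speckles(
    boost: np.ndarray,
    suppress: np.ndarray,
    density: float,
    radius: tuple[float, float],
    amp: float,
    rng: np.random.Generator,
) -> None:
    """Stamp random disks raising ``boost`` to ``amp`` and damping ``suppress``."""
    if density <= 0:
        return
    shape = boost.shape
    n = rng.poisson(density * shape[0] * shape[1])
    if n == 0:
        return
    cy = rng.integers(0, shape[0], n)
    cx = rng.integers(0, shape[1], n)
    radii = np.clip(rng.normal(radius[0], radius[1], n), 1.0, None)
    for y0, x0, r in zip(cy, cx, radii):
        ir = int(np.ceil(r))
        ys = slice(max(0, int(y0) - ir), min(shape[0], int(y0) + ir + 1))
        xs = slice(max(0, int(x0) - ir), min(shape[1], int(x0) + ir + 1))
        yy, xx = np.mgrid[ys, xs]
        disk = (yy - y0) ** 2 + (xx - x0) ** 2 <= r * r
        boost[ys, xs][disk] = np.maximum(boost[ys, xs][disk], amp)
        suppress[ys, xs][disk] *= 0.05


def _expected_patch_tsr(
    labels: np.ndarray, size: int, min_tissue: float
) -> tuple[Optional[float], dict[str, int]]:
    """Brute-force patch-count TSR of a label map under inference tiling.

    Scans the non-overlapping grid directly (independent of the tiler
    module): a window whose tissue fraction is >= min_tissue is counted for
    its majority tumor/stroma/other class.
    """
    h, w = labels.shape
    counts = {"tumor": 0, "stroma": 0, "other": 0}
    names = ("tumor", "stroma", "other")
    for y in range(0, h - size + 1, size):
        for x in range(0, w - size + 1, size):
            win = labels[y : y + size, x : x + size]
            class_counts = [np.count_nonzero(win == LABEL_CODES[n]) for n in names]
            if sum(class_counts) / (size * size) >= min_tissue:
                counts[names[int(np.argmax(class_counts))]] += 1
    denom = counts["tumor"] + counts["stroma"]
    tsr = counts["stroma"] / denom if denom > 0 else None
    return tsr, counts


def render_concentrations(
    labels: np.ndarray, textures: TextureParams, rng: np.random.Generator
) -> np.ndarray:
    """(H, W, 2) hematoxylin/eosin concentration maps for a label map."""
    conc = np.zeros(labels.shape + (2,), dtype=float)
    resolved = textures.resolved()
    for name, code in LABEL_CODES.items():
        sel = labels == code
        if not sel.any():
            continue
        tex = resolved.get(name)
        if tex is None:
            continue
        h, e = _concentration_fields(labels.shape, tex, rng)
        conc[sel, 0] = h[sel]
        conc[sel, 1] = e[sel]
    return conc


def render_rgb(
    conc: np.ndarray,
    stains: StainModel,
    i0: float = DEFAULT_I0,
    rgb_noise_sd: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    quantize: bool = True,
) -> np.ndarray:
    """Beer-Lambert rendering ``I = I0 * 10**(-S c)`` of a concentration map."""
    od = conc @ stains.stain_matrix.T
    rgb = i0 * np.power(10.0, -od)
    if rgb_noise_sd > 0 and rng is not None:
        rgb = rgb + rng.normal(0.0, rgb_noise_sd, rgb.shape)
    rgb = np.clip(rgb, 0.0, i0)
    if quantize:
        return np.round(rgb).astype(np.uint8)
    return rgb


def make_slide(
    layout: SyntheticLayout,
    textures: Optional[TextureParams] = None,
    stains: StainModel = DEFAULT_REFERENCE,
    patch_size: int = DEFAULT_PATCH_SIZE,
    min_tissue: float = 0.75,
    quantize: bool = True,
    slide_id: Optional[str] = None,
) -> tuple[SlideImage, GroundTruth]:
    """Render a synthetic slide and its exact ground truth.

    With ``quantize=True`` (default) the output is a realistic uint8 image
    with small sensor noise; ``quantize=False`` returns the exact float
    forward model (no noise, no rounding), which downstream optical-density
    computations invert to machine precision.

    Raises
    ------
    ValueError
        If the canvas is smaller than one patch in either dimension.
    """
    if layout.width < patch_size or layout.height < patch_size:
        raise ValueError(
            f"canvas {layout.width}x{layout.height} smaller than one "
            f"{patch_size}px patch"
        )
    textures = textures or TextureParams()
    labels = layout.label_map()
    rng = np.random.default_rng(np.random.SeedSequence([int(layout.seed), 0x51]))
    conc = render_concentrations(labels, textures, rng)
    pixels = render_rgb(
        conc,
        stains,
        rgb_noise_sd=textures.rgb_noise_sd if quantize else 0.0,
        rng=rng,
        quantize=quantize,
    )
    sid = slide_id or f"synth-{layout.seed}"
    slide = SlideImage(pixels=pixels, mpp=layout.mpp, slide_id=sid)

    annotation = AnnotationMap(labels=labels, slide_id=sid)
    areas = annotation.class_areas()
    tsr, patch_counts = _expected_patch_tsr(labels, patch_size, min_tissue)
    s_px, t_px = areas["stroma"], areas["tumor"]
    pixel_tsr = s_px / (s_px + t_px) if (s_px + t_px) > 0 else None

    mean_conc: dict[str, tuple[float, float]] = {}
    for name, code in LABEL_CODES.items():
        sel = labels == code
        if sel.any():
            mean_conc[name] = (float(conc[sel, 0].mean()), float(conc[sel, 1].mean()))

    truth = GroundTruth(
        annotation=annotation,
        region_areas=areas,
        stains=stains,
        expected_tsr=tsr,
        pixel_tsr=pixel_tsr,
        tiling_params={
            "size": patch_size,
            "min_tissue": min_tissue,
            "patch_counts": patch_counts,
        },
        class_mean_concentrations=mean_conc,
    )
    return slide, truth


# ---------------------------------------------------------------------------
# labeled patch datasets


def make_patch_dataset(
    n_per_class: int,
    textures: Optional[TextureParams] = None,
    stains: StainModel = DEFAULT_REFERENCE,
    seed: int = 0,
    size: int = DEFAULT_PATCH_SIZE,
) -> PatchSet:
    """Class-balanced labeled patch set (tumor/stroma/other), ``size``-square.

    Deterministic in ``seed``; the per-patch concentration fields depend only
    on the seed and textures, never on the stain model, so re-rendering the
    same seed under a different stain model changes color but not the
    underlying concentrations.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    textures = textures or TextureParams()
    resolved = textures.resolved()
    patches, labels, windows = [], [], []
    for ci, name in enumerate(CLASS_NAMES):
        tex = resolved[name]
        for i in range(n_per_class):
            rng = np.random.default_rng(np.random.SeedSequence([int(seed), ci, i]))
            h, e = _concentration_fields((size, size), tex, rng)
            conc = np.stack([h, e], axis=-1)
            rgb = render_rgb(
                conc, stains, rgb_noise_sd=textures.rgb_noise_sd, rng=rng, quantize=True
            )
            patches.append(rgb)
            labels.append(ci)
            windows.append(PatchWindow(x=0, y=0, size=size, slide_id=f"synthpatch-{name}-{i}"))
    return PatchSet(
        patches=np.stack(patches),
        windows=windows,
        labels=np.array(labels, dtype=int),
        params={"source": "synthetic", "seed": seed, "n_per_class": n_per_class},
    )


def make_tsr_cohort(
    n_slides: int = 30,
    seed: int = 0,
    size: int = 1568,
    scale: float = 1000.0,
    stroma_range: tuple[float, float] = (0.22, 0.88),
    textures: Optional[TextureParams] = None,
    stains: StainModel = DEFAULT_REFERENCE,
):
    """Generator of ``(slide, truth)`` pairs emulating a TSR scoring cohort.

    Slides carry contiguous tumor and stroma fields large relative to the
    224-px window (as real colorectal resections do at 0.5 MPP), with the
    stroma share of tissue swept across ``stroma_range`` so ground-truth
    patch-count TSR spans roughly 10-90%. Tissue occupies 88% of the canvas;
    the rest is the grab-bag class, adipose and background.
    """
    if n_slides < 1:
        raise ValueError("n_slides must be >= 1")
    lo, hi = stroma_range
    shares = np.linspace(lo, hi, n_slides)
    for i, share in enumerate(shares):
        slide_seed = int(
            np.random.SeedSequence([int(seed), 0xC0, i]).generate_state(1)[0] % (2**31)
        )
        layout = SyntheticLayout.blobs(
            {
                "tumor": 0.88 * (1.0 - share),
                "stroma": 0.88 * share,
                "other": 0.05,
                "adipose": 0.03,
                "background": 0.04,
            },
            width=size,
            height=size,
            seed=slide_seed,
            scale=scale,
        )
        yield make_slide(layout, textures=textures, stains=stains,
                         slide_id=f"cohort-{i:03d}")


def sparse_annotation(annotation: AnnotationMap, margin: int = 56) -> AnnotationMap:
    """Annotate only class interiors, leaving a ``margin``-px boundary blank.

    Expert annotations cover homogeneous regions and avoid ambiguous class
    boundaries; this helper emulates that by un-annotating every tissue pixel
    within ``margin`` pixels of a different class. Windows straddling a
    boundary then fail the annotated-coverage filter of training tiling,
    exactly as they would on an expert-annotated slide.
    """
    from scipy.ndimage import distance_transform_edt

    labels = annotation.labels
    out = np.zeros_like(labels)
    for code in TISSUE_CODES:
        sel = labels == code
        if not sel.any():
            continue
        interior = distance_transform_edt(sel) > margin
        out[interior] = code
    return AnnotationMap(labels=out, slide_id=annotation.slide_id)


def rotate_stain_model(stains: StainModel, angle_deg: float) -> StainModel:
    """Rotate both stain vectors by ``angle_deg`` about the plane normal.

    Used to emulate scanner/batch color shifts; small angles keep the vectors
    non-negative (entries are clipped and renormalized).
    """
    h, e = stains.stain_matrix[:, 0], stains.stain_matrix[:, 1]
    axis = np.cross(h, e)
    axis = axis / np.linalg.norm(axis)
    theta = np.radians(angle_deg)
    k = axis
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    R = np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * (K @ K)
    rotated = R @ stains.stain_matrix
    rotated = np.clip(rotated, 0.0, None)
    rotated = rotated / np.linalg.norm(rotated, axis=0, keepdims=True)
    return StainModel(stain_matrix=rotated, max_concentrations=stains.max_concentrations.copy())


def shifted_domain_textures(textures: Optional[TextureParams] = None) -> TextureParams:
    """A mildly shifted texture family standing in for an external dataset.

    Concentration ranges are scaled and the grab-bag class made more
    heterogeneous, emulating a public patch collection from different labs
    and scanners than the target cohort.
    """
    textures = textures or TextureParams()
    base = textures.resolved()
    shifted = {}
    for name, tex in base.items():
        shifted[name] = replace(
            tex,
            h_range=(tex.h_range[0] * 0.85, tex.h_range[1] * 1.1),
            e_range=(tex.e_range[0] * 0.85, tex.e_range[1] * 1.1),
        )
    return TextureParams(
        classes=shifted,
        rgb_noise_sd=textures.rgb_noise_sd * 1.3,
        other_heterogeneity=min(1.0, textures.other_heterogeneity + 0.3),
    )


def make_domain_pair(
    textures_a: Optional[TextureParams] = None,
    textures_b: Optional[TextureParams] = None,
    stains_a: StainModel = DEFAULT_REFERENCE,
    stains_b: Optional[StainModel] = None,
    n_per_class: int = 100,
    seed: int = 0,
) -> tuple[PatchSet, PatchSet]:
    """Two class-balanced patch sets with a controlled domain shift.

    Defaults: dataset B uses a stain model rotated 10 degrees from A and a
    shifted texture family, giving a measurable color/appearance gap of the
    kind seen between a local cohort and an external public dataset. If both
    parameter sets are identical a warning is logged but the pair is still
    returned.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    textures_a = textures_a or TextureParams()
    if textures_b is None and stains_b is None:
        textures_b = shifted_domain_textures(textures_a)
        stains_b = rotate_stain_model(stains_a, 10.0)
    textures_b = textures_b or textures_a
    stains_b = stains_b or stains_a

    same_stains = np.allclose(stains_a.stain_matrix, stains_b.stain_matrix)
    same_textures = textures_a.resolved() == textures_b.resolved()
    if same_stains and same_textures:
        logger.warning("make_domain_pair: parameter sets are identical; no domain shift")

    ss = np.random.SeedSequence(int(seed))
    seed_a, seed_b = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
    set_a = make_patch_dataset(n_per_class, textures_a, stains_a, seed=seed_a)
    set_b = make_patch_dataset(n_per_class, textures_b, stains_b, seed=seed_b)
    set_a.params["domain"] = "target"
    set_b.params["domain"] = "source"
    return set_a, set_b
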