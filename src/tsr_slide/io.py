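"""Reading and writing pipeline artifacts.

Slides are PNG or TIFF RGB images; annotation maps and tissue masks are
single-channel PNGs (annotation codes 0-4, masks 0/255); stain models and
ground-truth sidecars are JSON; patch sets are a directory of PNGs plus a
CSV manifest (slide id, x, y, size, label).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np
import pandas as pd

from tsr_slide.datatypes import (
    AnnotationMap,
    CLASS_NAMES,
    GroundTruth,
    PatchSet,
    PatchWindow,
    SlideImage,
    StainModel,
    TissueMask,
    TSRResult,
)


def save_slide(slide: SlideImage, path: str | Path) -> None:
    path = Path(path)
    pixels = slide.pixels
    if pixels.dtype != np.uint8:
        pixels = np.clip(np.round(pixels), 0, 255).astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, pixels, tile=(256, 256))
    else:
        iio.imwrite(path, pixels)
    meta = {"slide_id": slide.slide_id, "mpp": slide.mpp}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))


def load_slide(path: str | Path, mpp: Optional[float] = None) -> SlideImage:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        pixels = tifffile.imread(path)
    else:
        pixels = iio.imread(path)
    if pixels.ndim == 3 and pixels.shape[2] == 4:
        pixels = pixels[:, :, :3]
    meta_path = path.with_suffix(path.suffix + ".json")
    slide_id, meta_mpp = path.stem, 0.5
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        slide_id = meta.get("slide_id", slide_id)
        meta_mpp = meta.get("mpp", meta_mpp)
    return SlideImage(pixels=pixels, mpp=mpp if mpp is not None else meta_mpp, slide_id=slide_id)


def save_annotation(annotation: AnnotationMap, path: str | Path) -> None:
    iio.imwrite(Path(path), annotation.labels.astype(np.uint8))


def load_annotation(path: str | Path) -> AnnotationMap:
    path = Path(path)
    return AnnotationMap(labels=iio.imread(path).astype(np.uint8), slide_id=path.stem)


def save_mask(mask: TissueMask, path: str | Path) -> None:
    iio.imwrite(Path(path), (mask.mask.astype(np.uint8)) * 255)


def load_mask(path: str | Path, threshold: float = 0.0, channel: str = "saturation") -> TissueMask:
    path = Path(path)
    raster = iio.imread(path)
    return TissueMask(mask=raster > 127, threshold=threshold, channel=channel, slide_id=path.stem)


def save_stain_model(model: StainModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model.to_dict(), indent=2))


def load_stain_model(path: str | Path) -> StainModel:
    return StainModel.from_dict(json.loads(Path(path).read_text()))


def save_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    """JSON sidecar of everything except the raster (saved separately)."""
    payload = {
        "region_areas": truth.region_areas,
        "expected_tsr": truth.expected_tsr,
        "pixel_tsr": truth.pixel_tsr,
        "tiling_params": truth.tiling_params,
        "stains": truth.stains.to_dict(),
        "class_mean_concentrations": truth.class_mean_concentrations,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def save_patchset(patchset: PatchSet, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (patch, window) in enumerate(zip(patchset.patches, patchset.windows)):
        name = f"patch_{i:06d}.png"
        arr = patch
        if arr.dtype != np.uint8:
            arr = np.clip(np.round(arr), 0, 255).astype(np.uint8)
        iio.imwrite(out_dir / name, arr)
        rows.append(
            {
                "file": name,
                "slide_id": window.slide_id,
                "x": window.x,
                "y": window.y,
                "size": window.size,
                "label": (
                    CLASS_NAMES[patchset.labels[i]] if patchset.labels is not None else ""
                ),
            }
        )
    pd.DataFrame(rows).to_csv(out_dir / "manifest.csv", index=False)


def load_patchset(in_dir: str | Path) -> PatchSet:
    in_dir = Path(in_dir)
    manifest = pd.read_csv(in_dir / "manifest.csv", keep_default_na=False)
    patches, windows, labels = [], [], []
    has_labels = bool((manifest["label"] != "").all()) and len(manifest) > 0
    for _, row in manifest.iterrows():
        patches.append(iio.imread(in_dir / row["file"]))
        windows.append(
            PatchWindow(x=int(row["x"]), y=int(row["y"]), size=int(row["size"]),
                        slide_id=str(row["slide_id"]))
        )
        if has_labels:
            labels.append(CLASS_NAMES.index(row["label"]))
    return PatchSet(
        patches=np.stack(patches) if patches else np.empty((0, 224, 224, 3), dtype=np.uint8),
        windows=windows,
        labels=np.array(labels, dtype=int) if has_labels else None,
    )


def tsr_results_frame(results: list[TSRResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "slide_id": r.slide_id,
                "n_tumor": r.n_tumor,
                "n_stroma": r.n_stroma,
                "n_other": r.n_other,
                "tsr_percent": r.tsr_percent,
                "stroma_class": r.stroma_class,
            }
            for r in results
        ]
    )
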