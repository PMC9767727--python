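"""Moving-window patch extraction and per-class gray-level statistics.

A window of size ``w`` slides over the rectangular ROI of each labeled image
with a fixed stride; every fully contained window becomes one training patch.
Per-class mean/min/max gray statistics over the extracted patches summarise
the echogenicity structure of the four steatosis grades (the two low grades
dark and close, the two high grades bright and close).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .errors import DataError, EmptyExtractionError, ParameterError
from .synth import CLASS_LABELS, UltrasoundImage


@dataclass(frozen=True)
class PatchConfig:
    """Moving-window geometry.

    ``window`` is the patch side ``w`` in pixels (default 28); ``stride``
    defaults to ``w // 2`` (half-overlapping windows) when not given.
    """

    window: int = 28
    stride: int | None = None
    classes: tuple[str, ...] = CLASS_LABELS

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ParameterError(f"window must be >= 1, got {self.window}")
        if self.stride is not None and self.stride < 1:
            raise ParameterError(f"stride must be >= 1, got {self.stride}")

    @property
    def effective_stride(self) -> int:
        return self.stride if self.stride is not None else max(1, self.window // 2)


@dataclass(frozen=True)
class Patch:
    """A ``w x w`` sub-image cut from an image ROI.

    ``origin`` is the (row, col) of the window's top-left corner, 0-based in
    source-image coordinates; the window spans ``[origin, origin + w)`` per
    axis.  ``pixels`` keeps the raw 8-bit gray values; any normalisation is
    deferred to training.
    """

    pixels: np.ndarray
    class_label: str
    image_id: str
    origin: tuple[int, int]

    @property
    def patch_id(self) -> str:
        return f"{self.image_id}_r{self.origin[0]}_c{self.origin[1]}"


def window_count(extent: int, window: int, stride: int) -> int:
    """Number of window origins along one axis: floor((extent - w)/stride) + 1."""
    if extent < window:
        return 0
    return (extent - window) // stride + 1


def extract_patches(
    image: UltrasoundImage,
    config: PatchConfig,
    max_patches: int | None = None,
    seed: int | None = None,
) -> list[Patch]:
    """Cut all fully contained windows from the image ROI, in raster order.

    Origins are ``(roi_row0 + a*stride, roi_col0 + b*stride)`` for all ``a, b``
    keeping the window inside the ROI.  If ``max_patches`` is given and fewer
    windows exist nothing is dropped; otherwise a seeded uniform subsample of
    exactly ``max_patches`` windows is kept (raster order preserved).
    """
    w = config.window
    stride = config.effective_stride
    r0, c0, roi_h, roi_w = image.roi
    if roi_h < w or roi_w < w:
        raise EmptyExtractionError(
            f"ROI {roi_h}x{roi_w} of image {image.image_id!r} is smaller than window {w}"
        )

    n_rows = window_count(roi_h, w, stride)
    n_cols = window_count(roi_w, w, stride)
    origins = [
        (r0 + a * stride, c0 + b * stride)
        for a in range(n_rows)
        for b in range(n_cols)
    ]
    if max_patches is not None and len(origins) > max_patches:
        rng = np.random.default_rng(seed)
        keep = np.sort(rng.choice(len(origins), size=max_patches, replace=False))
        origins = [origins[i] for i in keep]

    return [
        Patch(
            pixels=image.pixels[r : r + w, c : c + w].copy(),
            class_label=image.class_label,
            image_id=image.image_id,
            origin=(r, c),
        )
        for r, c in origins
    ]


def extract_dataset_patches(
    images: Sequence[UltrasoundImage],
    config: PatchConfig,
    per_class_cap: int | None = None,
    seed: int = 0,
) -> list[Patch]:
    """Extract patches from every image; optionally cap each class's total.

    The cap is applied per class by a seeded uniform subsample over all of the
    class's patches, emulating the sparse sampling needed to obtain a target
    patch count per grade from a handful of images.
    """
    by_class: dict[str, list[Patch]] = {c: [] for c in config.classes}
    for img in images:
        for p in extract_patches(img, config):
            by_class.setdefault(p.class_label, []).append(p)

    if per_class_cap is None:
        return [p for c in by_class for p in by_class[c]]

    rng = np.random.default_rng(seed)
    capped: list[Patch] = []
    for c in by_class:
        pool = by_class[c]
        if len(pool) > per_class_cap:
            keep = np.sort(rng.choice(len(pool), size=per_class_cap, replace=False))
            pool = [pool[i] for i in keep]
        capped.extend(pool)
    return capped


def class_gray_stats(
    patches: Sequence[Patch], classes: Sequence[str] = CLASS_LABELS
) -> pd.DataFrame:
    """Per-class gray statistics over all pixels of all patches of the class.

    Returns a DataFrame indexed by class with columns ``count`` (number of
    patches), ``mean``, ``min``, ``max``.  A class with zero patches is
    reported with count 0 and NaN statistics rather than silently omitted.
    """
    if len(patches) == 0:
        raise DataError("class_gray_stats requires a non-empty patch list")
    rows = {}
    for c in classes:
        pix = [p.pixels for p in patches if p.class_label == c]
        if pix:
            flat = np.concatenate([np.asarray(a, dtype=np.float64).ravel() for a in pix])
            rows[c] = {
                "count": len(pix),
                "mean": float(flat.mean()),
                "min": float(flat.min()),
                "max": float(flat.max()),
            }
        else:
            rows[c] = {"count": 0, "mean": math.nan, "min": math.nan, "max": math.nan}
    return pd.DataFrame.from_dict(rows, orient="index")


def write_patches(patches: Sequence[Patch], out_dir: str | Path) -> Path:
    """Write patches as PNGs plus ``patches.csv``; return the CSV path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    csv_path = out / "patches.csv"
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patch_id", "class", "source", "row", "col", "path"])
        for p in patches:
            fname = f"{p.patch_id}.png"
            Image.fromarray(p.pixels.astype(np.uint8), mode="L").save(out / fname)
            writer.writerow([p.patch_id, p.class_label, p.image_id, p.origin[0], p.origin[1], fname])
    return csv_path


def read_patches(csv_path: str | Path) -> list[Patch]:
    """Load patches written by :func:`write_patches`."""
    csv_path = Path(csv_path)
    base = csv_path.parent
    out = []
    with open(csv_path, newline="") as fh:
        for row in csv.DictReader(fh):
            pixels = np.asarray(Image.open(base / row["path"]).convert("L"))
            out.append(
                Patch(
                    pixels=pixels,
                    class_label=row["class"],
                    image_id=row["source"],
                    origin=(int(row["row"]), int(row["col"])),
                )
            )
    return out
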