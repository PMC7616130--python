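"""Quantitative fluorescence densitometry.

Per-compartment signal density is total background-subtracted intensity
normalised to the signal area: the whole growth cone for F-actin, the
central domain only for tubulin.  Background is the median intensity
outside a dilated copy of the mask (border pixels excluded); masks come
from Otsu thresholding (actin), or are supplied (manual outlines or the
generator's ground truth).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from skimage.filters import threshold_otsu
from skimage.measure import label
from skimage.morphology import dilation, disk

__all__ = [
    "ImageRecord",
    "Mask",
    "DensityRecord",
    "estimate_background",
    "make_mask",
    "normalized_density",
    "growth_cone_area",
    "quantify",
    "analyze_image_dir",
]


@dataclass
class ImageRecord:
    pixels: np.ndarray
    pixel_size_um: float
    channel: str = ""          # actin | tubulin
    compartment: str = ""      # growth_cone | axon_shaft

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, float)
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if np.any(self.pixels < 0):
            raise ValueError("negative intensities")


@dataclass
class Mask:
    pixels: np.ndarray
    provenance: str = "threshold"   # threshold | manual | ground_truth

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, bool)

    @property
    def n_px(self) -> int:
        return int(self.pixels.sum())


@dataclass
class DensityRecord:
    total_intensity: float
    area_um2: float
    density: float
    background_level: float


def estimate_background(image: np.ndarray, mask: np.ndarray,
                        dilate_px: int = 5, border_px: int = 2) -> float:
    """Median intensity of pixels outside the dilated mask.

    The mask is dilated by ``dilate_px`` so the halo of out-of-focus signal
    around the object does not bias the estimate, and a ``border_px`` frame
    is excluded.
    """
    image = np.asarray(image, float)
    mask = np.asarray(mask, bool)
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    bg_region = ~dilation(mask, disk(dilate_px))
    if border_px > 0:
        bg_region[:border_px, :] = False
        bg_region[-border_px:, :] = False
        bg_region[:, :border_px] = False
        bg_region[:, -border_px:] = False
    if not bg_region.any():
        raise ValueError("no background pixels outside the dilated mask")
    return float(np.median(image[bg_region]))


def make_mask(image: np.ndarray, method: str = "threshold",
              min_object_px: int = 20,
              supplied: np.ndarray | None = None) -> Mask:
    """Segmentation mask for quantification.

    ``threshold``: Otsu threshold, keep the largest connected component if
    it has at least ``min_object_px`` pixels.  ``manual`` / ``ground_truth``:
    use the supplied boolean mask unchanged.
    """
    if method in ("manual", "ground_truth"):
        if supplied is None:
            raise ValueError(f"method={method!r} requires a supplied mask")
        m = Mask(np.asarray(supplied, bool), provenance=method)
        if m.n_px == 0:
            raise ValueError("supplied mask is empty")
        return m
    if method != "threshold":
        raise ValueError(f"unknown mask method {method!r}")
    image = np.asarray(image, float)
    if np.ptp(image) == 0:
        raise ValueError("degenerate (constant) image; cannot threshold")
    binary = image > threshold_otsu(image)
    labels = label(binary)
    if labels.max() == 0:
        raise ValueError("no foreground after thresholding")
    sizes = np.bincount(labels.ravel())[1:]
    biggest = int(np.argmax(sizes)) + 1
    if sizes[biggest - 1] < min_object_px:
        raise ValueError(f"largest component {sizes[biggest - 1]} px "
                         f"< min_object_px={min_object_px}")
    return Mask(labels == biggest, provenance="threshold")


def normalized_density(image: np.ndarray, mask: Mask | np.ndarray,
                       background_level: float, pixel_size_um: float,
                       clip_negative: bool = True) -> DensityRecord:
    """Background-subtracted total intensity normalised to the mask area.

    Negative post-subtraction pixels are clipped to zero by default so
    that noise in sparse masks cannot cancel real signal.
    """
    image = np.asarray(image, float)
    m = mask.pixels if isinstance(mask, Mask) else np.asarray(mask, bool)
    if not m.any():
        raise ValueError("empty mask")
    if background_level < 0:
        raise ValueError("background must be nonnegative")
    vals = image[m] - background_level
    if clip_negative:
        vals = np.clip(vals, 0.0, None)
    total = float(vals.sum())
    area = float(m.sum()) * pixel_size_um ** 2
    return DensityRecord(total_intensity=total, area_um2=area,
                         density=total / area, background_level=float(background_level))


def growth_cone_area(mask: Mask | np.ndarray, pixel_size_um: float) -> float:
    """Mask area in µm² (pixel count times pixel area)."""
    m = mask.pixels if isinstance(mask, Mask) else np.asarray(mask, bool)
    if not m.any():
        raise ValueError("empty mask")
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    return float(m.sum()) * pixel_size_um ** 2


def quantify(record: ImageRecord, mask: Mask) -> dict:
    """Background + density + area for one image/mask pair."""
    bg = estimate_background(record.pixels, mask.pixels)
    dens = normalized_density(record.pixels, mask, bg, record.pixel_size_um)
    return {
        "channel": record.channel,
        "compartment": record.compartment,
        "area_um2": dens.area_um2,
        "background": bg,
        "total_intensity": dens.total_intensity,
        "density": dens.density,
    }


def analyze_image_dir(image_dir: str | Path, method: str = "threshold") -> pd.DataFrame:
    """Quantify every ``*_<channel>.tif`` under ``image_dir``.

    Expects the cohort layout: ``<id>_<channel>.tif`` with a sidecar
    ``<id>_meta.json`` carrying the pixel size and, for ``method='mask'``,
    ground-truth masks ``<id>_<channel>_mask.tif``.
    """
    rows = []
    for f in sorted(Path(image_dir).glob("**/*.tif")):
        if f.stem.endswith("_mask"):
            continue
        stem, _, channel = f.stem.rpartition("_")
        meta_path = f.with_name(f"{stem}_meta.json")
        if not stem or not meta_path.exists():
            continue   # not an image written with a pixel-size sidecar
        px = json.loads(meta_path.read_text()).get("pixel_size_um", 0.1)
        img = tifffile.imread(f).astype(float)
        if method == "mask":
            mask_path = f.with_name(f"{stem}_{channel}_mask.tif")
            supplied = tifffile.imread(mask_path).astype(bool)
            mask = make_mask(img, "ground_truth", supplied=supplied)
        else:
            mask = make_mask(img, "threshold")
        rec = ImageRecord(img, px, channel=channel, compartment="growth_cone")
        row = quantify(rec, mask)
        row["cell_id"] = stem
        row["condition"] = f.parent.parent.name
        rows.append(row)
    if not rows:
        raise FileNotFoundError(f"no channel TIFFs under {image_dir}")
    df = pd.DataFrame(rows)
    return df[["cell_id", "condition", "channel", "compartment", "area_um2",
               "background", "total_intensity", "density"]]
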