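"""Image-processing protocol for pore segmentation in demineralized bone sections.

The protocol mirrors a standard quantitative-histology workflow for
confocal images of stained, demineralized cortical bone:

1. 5x5 median filtering to suppress salt-and-pepper noise,
2. brightness equalization by dividing the image by a strongly
   Gaussian-blurred copy of itself (flat-field correction without a
   reference image),
3. fixed-threshold segmentation of the dark, non-collagenous spaces
   ("objects": pores, canals, lacunae, fissures),
4. removal of objects touching the raster border (visible only in part),
   followed by sequential connected-component labeling.

All steps are deterministic; there is no random state anywhere in the
protocol.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "CalibratedImage",
    "LabeledMask",
    "SegmentationConfig",
    "median_denoise",
    "equalize_brightness",
    "threshold_segment",
    "run_protocol",
]

#: Gray value that a locally-average pixel maps to after equalization.
#: Ratio 1.0 (pixel == local background estimate) -> 128, so the fixed
#: segmentation threshold of 50 selects pixels darker than ~39% of their
#: local background.
EQUALIZED_MIDGRAY = 128.0


@dataclass(frozen=True)
class CalibratedImage:
    """A 2D 8-bit grayscale raster with a physical pixel-area calibration.

    Parameters
    ----------
    intensities
        2D array of integers in [0, 255] (stored as uint8).
    pixel_area_um2
        Area of one pixel in square micrometres. The default 2.971
        corresponds to a 4x confocal objective over a 2048 px field of
        3.53 mm.
    """

    intensities: np.ndarray
    pixel_area_um2: float = 2.971

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities)
        if arr.ndim != 2 or arr.size == 0:
            raise ValueError(
                f"expected a non-empty 2D grayscale raster, got shape {arr.shape}"
            )
        if arr.dtype != np.uint8:
            if arr.min() < 0 or arr.max() > 255:
                raise ValueError("intensities must lie in [0, 255]")
            arr = arr.astype(np.uint8)
        if not self.pixel_area_um2 > 0:
            raise ValueError("pixel_area_um2 must be positive")
        object.__setattr__(self, "intensities", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape

    @property
    def pixel_side_um(self) -> float:
        """Side length of one (square) pixel in micrometres."""
        return math.sqrt(self.pixel_area_um2)

    @property
    def field_size_mm(self) -> tuple[float, float]:
        """Physical (height, width) of the imaged field in millimetres."""
        h, w = self.intensities.shape
        return (h * self.pixel_side_um / 1000.0, w * self.pixel_side_um / 1000.0)

    @classmethod
    def from_file(cls, path: str | Path, pixel_area_um2: float = 2.971) -> "CalibratedImage":
        """Read an 8-bit single-channel TIFF or PNG.

        Multi-channel or non-8-bit inputs are rejected rather than
        silently converted.
        """
        path = Path(path)
        if path.suffix.lower() in {".tif", ".tiff"}:
            import tifffile

            arr = tifffile.imread(path)
        else:
            from PIL import Image

            arr = np.asarray(Image.open(path))
        if arr.ndim != 2:
            raise ValueError(
                f"{path} has {arr.ndim} dimensions; expected a single-channel "
                "grayscale image (convert multi-channel inputs explicitly)"
            )
        if arr.dtype != np.uint8:
            raise ValueError(f"{path} is {arr.dtype}; expected 8-bit grayscale")
        return cls(arr, pixel_area_um2)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix.lower() in {".tif", ".tiff"}:
            import tifffile

            tifffile.imwrite(path, self.intensities)
        else:
            from PIL import Image

            Image.fromarray(self.intensities, mode="L").save(path)


@dataclass(frozen=True)
class LabeledMask:
    """Sequentially labeled connected components with border bookkeeping.

    ``labels`` is 0 for background and 1..n_objects for retained objects;
    components that touched the raster border have been removed and are
    counted in ``border_excluded_count``.
    """

    labels: np.ndarray
    n_objects: int
    border_excluded_count: int
    pixel_area_um2: float = 2.971

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise ValueError("labels must be a 2D raster")
        object.__setattr__(self, "labels", lab.astype(np.int32, copy=False))

    def binary(self, label: int) -> np.ndarray:
        return self.labels == label


@dataclass(frozen=True)
class SegmentationConfig:
    """Parameters of the full segmentation protocol (defaults follow the
    acquisition protocol this package targets)."""

    median_size: int = 5
    blur_sigma_px: float = 50.0
    threshold: int = 50
    polarity: str = "dark_objects"  # or "bright_objects"
    connectivity: int = 8  # 8 or 4
    min_object_px: int = 1  # no size filter by default

    def __post_init__(self) -> None:
        if self.polarity not in ("dark_objects", "bright_objects"):
            raise ValueError(f"unknown polarity {self.polarity!r}")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if not 0 <= self.threshold <= 255:
            raise ValueError("threshold must be in [0, 255]")
        if not self.blur_sigma_px > 0:
            raise ValueError("blur_sigma_px must be positive")


def median_denoise(img: CalibratedImage, size: int = 5) -> CalibratedImage:
    """Median-filter the image with a ``size`` x ``size`` window.

    Reflect padding at the border avoids artificial dark rims that would
    later segment as spurious border objects. Calibration is unchanged.
    """
    out = ndimage.median_filter(img.intensities, size=size, mode="reflect")
    return CalibratedImage(out, img.pixel_area_um2)


def equalize_brightness(img: CalibratedImage, blur_sigma_px: float = 50.0) -> CalibratedImage:
    """Flat-field correction by division with a Gaussian-blurred copy.

    Each pixel is divided by the corresponding pixel of the blurred image
    (blurred values floored at 1 to guard against division by zero on
    pure-black regions) and the ratio is mapped so that ratio 1.0 ->
    gray 128, then rounded and clipped to [0, 255]. A blur sigma much
    larger than the pore scale removes small details so the ratio image
    carries only local contrast, making a fixed global threshold
    meaningful under uneven illumination.
    """
    if not blur_sigma_px > 0:
        raise ValueError("blur_sigma_px must be positive")
    orig = img.intensities.astype(np.float64)
    blurred = ndimage.gaussian_filter(orig, sigma=blur_sigma_px, mode="reflect")
    blurred = np.maximum(blurred, 1.0)
    out = np.clip(np.rint(EQUALIZED_MIDGRAY * orig / blurred), 0, 255).astype(np.uint8)
    return CalibratedImage(out, img.pixel_area_um2)


def _structure(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(2, 2 if connectivity == 8 else 1)


def threshold_segment(
    img: CalibratedImage,
    threshold: int = 50,
    polarity: str = "dark_objects",
    connectivity: int = 8,
    min_object_px: int = 1,
) -> LabeledMask:
    """Fixed-threshold segmentation with border-object exclusion.

    With ``dark_objects`` the foreground is ``intensity < threshold``
    (pores are non-fluorescent voids, darker than stained tissue); with
    ``bright_objects`` it is ``intensity > threshold``. Connected
    components (8-connectivity by default) touching any raster border are
    removed and counted; the remainder are relabeled 1..n with no gaps.
    """
    if polarity == "dark_objects":
        fg = img.intensities < threshold
    elif polarity == "bright_objects":
        fg = img.intensities > threshold
    else:
        raise ValueError(f"unknown polarity {polarity!r}")

    labels, n = ndimage.label(fg, structure=_structure(connectivity))
    if n == 0:
        return LabeledMask(labels, 0, 0, img.pixel_area_um2)

    border = np.zeros(n + 1, dtype=bool)
    for edge in (labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]):
        border[np.unique(edge)] = True
    border[0] = False
    border_excluded = int(border.sum())

    keep = ~border
    keep[0] = False
    if min_object_px > 1:
        sizes = np.bincount(labels.ravel(), minlength=n + 1)
        keep &= sizes >= min_object_px

    # relabel retained components sequentially
    remap = np.zeros(n + 1, dtype=np.int32)
    kept_ids = np.flatnonzero(keep)
    remap[kept_ids] = np.arange(1, len(kept_ids) + 1, dtype=np.int32)
    return LabeledMask(remap[labels], len(kept_ids), border_excluded, img.pixel_area_um2)


def run_protocol(img: CalibratedImage, config: SegmentationConfig | None = None) -> LabeledMask:
    """Full protocol: median denoise -> equalize brightness -> threshold.

    Deterministic composition of the three stages; returns the final
    labeled mask carrying the image's calibration.
    """
    cfg = config or SegmentationConfig()
    denoised = median_denoise(img, size=cfg.median_size)
    equalized = equalize_brightness(denoised, blur_sigma_px=cfg.blur_sigma_px)
    return threshold_segment(
        equalized,
        threshold=cfg.threshold,
        polarity=cfg.polarity,
        connectivity=cfg.connectivity,
        min_object_px=cfg.min_object_px,
    )


def write_mask(mask: LabeledMask, path: str | Path, config: SegmentationConfig | None = None) -> None:
    """Write a label raster as 16-bit TIFF plus a JSON sidecar."""
    import json

    import tifffile

    path = Path(path)
    if mask.labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("too many labels for a 16-bit label image")
    tifffile.imwrite(path, mask.labels.astype(np.uint16))
    sidecar = {
        "n_objects": mask.n_objects,
        "border_excluded_count": mask.border_excluded_count,
        "pixel_area_um2": mask.pixel_area_um2,
    }
    if config is not None:
        sidecar["config"] = dataclasses.asdict(config)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
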