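"""Deposit detection on scanned plate images.

Flies fed dye-laced food leave dark faecal deposits on a clear plastic
surface, imaged with a transparency scanner on a light background.  The
detection pipeline binarises the greyscale image with an *adaptive* (local
mean) threshold — robust to the slow background gradients a scanner
produces — labels 8-connected foreground regions as candidate deposits,
fills internal holes, and discards regions outside a user-set size range.

All coordinates are 0-based with ``x`` rightward and ``y`` downward from
the top-left corner.  Binary maps are plain 2-D ``uint8`` arrays with
values in {0, 1}.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

REFERENCE_DPI = 1200.0

__all__ = [
    "RgbImage",
    "Component",
    "DetectionParams",
    "to_greyscale",
    "adaptive_threshold",
    "label_components",
    "fill_holes",
    "filter_by_size",
    "detect_spots",
]


@dataclass
class RgbImage:
    """An RGB plate scan with channel values in [0, 1].

    ``pixels`` has shape (height, width, 3), float, origin top-left.
    ``dpi`` is the scan resolution tag; size filters are calibrated at
    1200 dpi and rescaled when this differs.
    """

    pixels: np.ndarray
    dpi: float = REFERENCE_DPI

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must have shape (height, width, 3)")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("image must be at least 1x1")
        if self.pixels.min() < 0.0 or self.pixels.max() > 1.0:
            raise ValueError("channel values must lie in [0, 1]")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class Component:
    """A connected foreground region (candidate deposit).

    ``pixel_set`` is an (n, 2) integer array of (x, y) coordinates;
    ``bounding_box`` is (x_min, y_min, x_max, y_max), inclusive.
    """

    label: int
    pixel_set: np.ndarray
    bounding_box: tuple[int, int, int, int] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.pixel_set = np.asarray(self.pixel_set, dtype=np.intp).reshape(-1, 2)
        if len(self.pixel_set) == 0:
            raise ValueError("component pixel_set must be non-empty")
        if self.bounding_box is None:
            xs, ys = self.pixel_set[:, 0], self.pixel_set[:, 1]
            self.bounding_box = (int(xs.min()), int(ys.min()), int(xs.max()), int(ys.max()))

    @property
    def area(self) -> int:
        return len(self.pixel_set)

    def local_mask(self, pad: int = 0) -> tuple[np.ndarray, tuple[int, int]]:
        """Boolean mask over the (padded) bounding box and its (x0, y0) origin."""
        x0, y0, x1, y1 = self.bounding_box
        h, w = y1 - y0 + 1 + 2 * pad, x1 - x0 + 1 + 2 * pad
        mask = np.zeros((h, w), dtype=bool)
        mask[self.pixel_set[:, 1] - y0 + pad, self.pixel_set[:, 0] - x0 + pad] = True
        return mask, (x0 - pad, y0 - pad)


@dataclass
class DetectionParams:
    """Detection parameters, calibrated for 1200 dpi scans.

    window
        Odd side (pixels) of the square neighbourhood whose mean forms the
        local threshold; should exceed the typical deposit diameter.
    offset
        Intensity subtracted from the local mean; a pixel is foreground
        iff its greyscale value falls strictly below mean − offset.
    min_area, max_area
        Inclusive pixel-count bounds for accepted deposits (artefact and
        smear rejection).
    greyscale_weights
        RGB → grey weights (must sum to 1); default is the standard luma.
    opening
        Optional single-pass morphological opening (disc radius 1) before
        labelling, to separate weakly confluent deposits.  Off by default;
        no further splitting of confluent spots is attempted.
    """

    window: int = 51
    offset: float = 0.06
    min_area: int = 40
    max_area: int = 50_000
    greyscale_weights: tuple[float, float, float] = (0.299, 0.587, 0.114)
    connectivity: int = 8
    opening: bool = False

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be an odd integer >= 3")
        if not (0 <= self.min_area < self.max_area):
            raise ValueError("need 0 <= min_area < max_area")
        if self.offset < 0:
            raise ValueError("offset must be >= 0")
        if self.connectivity != 8:
            raise ValueError("only 8-connectivity is supported")

    def scaled_to_dpi(self, dpi: float) -> "DetectionParams":
        """Rescale the area bounds by (dpi / 1200)**2.

        Deposit areas scale with the square of resolution; shape features
        remain resolution-sensitive, so comparisons should only be drawn
        between identically processed scans.
        """
        if dpi == REFERENCE_DPI:
            return self
        factor = (dpi / REFERENCE_DPI) ** 2
        logger.warning(
            "image dpi %.0f differs from the 1200 dpi calibration; "
            "rescaling size filters by %.4g", dpi, factor,
        )
        return replace(
            self,
            min_area=int(round(self.min_area * factor)),
            max_area=int(round(self.max_area * factor)),
        )


def to_greyscale(image: RgbImage, weights: tuple[float, float, float] | None = None) -> np.ndarray:
    """Weighted-sum greyscale conversion; weights must be >= 0 and sum to 1."""
    if weights is None:
        weights = DetectionParams().greyscale_weights
    w = np.asarray(weights, dtype=float)
    if w.shape != (3,) or (w < 0).any():
        raise ValueError("weights must be three non-negative numbers")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("greyscale weights must sum to 1")
    return image.pixels @ w


def adaptive_threshold(grey: np.ndarray, window: int = 51, offset: float = 0.06) -> np.ndarray:
    """Binarise against the local mean: foreground iff grey < mean − offset.

    The neighbourhood is a window×window square centred on each pixel,
    with reflected padding at the borders.  Being relative to the local
    mean, the map is invariant to adding a constant to the whole image.
    """
    grey = np.asarray(grey, dtype=float)
    if grey.ndim != 2:
        raise ValueError("grey must be a 2-D intensity grid")
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    if offset < 0:
        raise ValueError("offset must be >= 0")
    if window > grey.shape[0] and window > grey.shape[1]:
        raise ValueError("window larger than both image dimensions")
    local_mean = ndimage.uniform_filter(grey, size=window, mode="reflect")
    return (grey < local_mean - offset).astype(np.uint8)


_STRUCTURE_8 = np.ones((3, 3), dtype=bool)


def label_components(binary_map: np.ndarray, connectivity: int = 8) -> list[Component]:
    """Label 8-connected foreground regions.

    Labels run 1..n in raster order of each component's first pixel.
    An empty map yields an empty list.
    """
    if connectivity != 8:
        raise ValueError("only 8-connectivity is supported")
    mask = np.asarray(binary_map).astype(bool)
    labelled, n = ndimage.label(mask, structure=_STRUCTURE_8)
    if n == 0:
        return []
    # enforce raster order of first occurrence regardless of the labelling pass
    flat = labelled.ravel()
    first = np.full(n + 1, flat.size, dtype=np.intp)
    idx = np.nonzero(flat)[0]
    # reversed so earlier raster indices overwrite later ones
    first[flat[idx[::-1]]] = idx[::-1]
    order = np.argsort(first[1:], kind="stable")  # old labels in raster order
    slices = ndimage.find_objects(labelled)
    components = []
    for new_label, old_idx in enumerate(order, start=1):
        sl = slices[old_idx]
        ys, xs = np.nonzero(labelled[sl] == old_idx + 1)
        ys = ys + sl[0].start
        xs = xs + sl[1].start
        components.append(
            Component(
                label=new_label,
                pixel_set=np.column_stack([xs, ys]),
                bounding_box=(int(xs.min()), int(ys.min()), int(xs.max()), int(ys.max())),
            )
        )
    return components


def fill_holes(component: Component, binary_map: np.ndarray | None = None) -> Component:
    """Add enclosed background regions (holes) to the component.

    A hole is background not reachable from the image border through
    background (4-connected, the dual of 8-connected foreground).
    Idempotent; never removes pixels.  ``binary_map`` is accepted for
    signature compatibility but the fill is purely local to the component.
    """
    mask, (x0, y0) = component.local_mask(pad=1)
    filled = ndimage.binary_fill_holes(mask)
    if filled.sum() == mask.sum():
        return component
    ys, xs = np.nonzero(filled)
    return Component(
        label=component.label,
        pixel_set=np.column_stack([xs + x0, ys + y0]),
    )


def filter_by_size(components: list[Component], min_area: int, max_area: int) -> list[Component]:
    """Keep components with min_area <= area <= max_area (inclusive), preserving order."""
    if not min_area < max_area:
        raise ValueError("min_area must be < max_area")
    return [c for c in components if min_area <= c.area <= max_area]


def detect_spots(image: RgbImage, params: DetectionParams | None = None) -> list[Component]:
    """Full detection pipeline: greyscale → adaptive threshold →
    (optional opening) → label → fill holes → size filter.

    Deterministic for fixed inputs.  Size bounds are rescaled when the
    image dpi differs from the 1200 dpi calibration.
    """
    if params is None:
        params = DetectionParams()
    params = params.scaled_to_dpi(image.dpi)
    grey = to_greyscale(image, params.greyscale_weights)
    binary = adaptive_threshold(grey, params.window, params.offset)
    if params.opening:
        disc = ndimage.generate_binary_structure(2, 1)  # radius-1 disc (cross)
        binary = ndimage.binary_opening(binary, structure=disc).astype(np.uint8)
    components = label_components(binary, params.connectivity)
    components = [fill_holes(c) for c in components]
    return filter_by_size(components, params.min_area, params.max_area)
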