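"""Per-deposit graphical variables.

Each detected deposit is summarised by position, size, shape and colour:

* ``area`` — pixel count of the (hole-filled) region.
* ``perimeter`` — closed polygon length of the outer border traced
  through pixel centres: 1 per axial step, √2 per diagonal step.
* ``circularity`` — 4π·area / perimeter², clamped to [0, 1]; 1 for a
  perfect circle, → 0 for elongated shapes.
* ``is_rod`` — reproductive oblong deposit flag; RODs are the long,
  concentrated deposits typical of mated females, identified by a
  circularity *below* a user-set cutoff (default 0.5).
* ``iod`` — integrated optical density, area·(1 − mean lightness): a
  proxy for the total dye (hence food) excreted in the deposit, valid
  when the scan is calibrated so lightness is linear in dye concentration.
* mean RGB and its HSL transform — with a pH-sensitive dye (bromophenol
  blue) the hue reads out acid–base balance (blue ≈ 240° neutral/basic,
  < 60° acidic) and lightness reads out dye concentration / water content.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .detect import Component, RgbImage

__all__ = [
    "Deposit",
    "trace_perimeter",
    "circularity",
    "classify_rod",
    "mean_rgb",
    "rgb_to_hsl",
    "hsl_to_rgb",
    "iod",
    "build_deposit",
    "DEFAULT_ROD_CUTOFF",
]

DEFAULT_ROD_CUTOFF = 0.5


@dataclass
class Deposit:
    """One detected faecal deposit with all its graphical variables.

    ``x``/``y`` are the centroid in pixels from the top-left corner;
    ``mean_h`` is an integer hue in degrees [0, 359]; ``include`` marks
    the deposit for inclusion in plate-level summaries (manual curation
    flips it to False for artefacts).  ``pixel_set`` is None for
    deposits re-loaded from exported tables.
    """

    plate_id: str
    deposit_id: int
    x: float
    y: float
    area: int
    perimeter: float
    circularity: float
    is_rod: bool
    iod: float
    mean_r: float
    mean_g: float
    mean_b: float
    mean_h: int
    mean_s: float
    mean_l: float
    include: bool = True
    pixel_set: np.ndarray | None = field(default=None, repr=False)


# Moore neighbourhood, clockwise starting west, as (dy, dx).
_MOORE = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]
_MOORE_INDEX = {d: i for i, d in enumerate(_MOORE)}


def _trace_boundary(mask: np.ndarray) -> list[tuple[int, int]]:
    """Moore border following on a padded boolean mask.

    Returns the closed cycle of boundary pixels (y, x).  The walk over
    states (pixel, backtrack direction) is deterministic on a finite set,
    so it eventually revisits a state; the boundary cycle is the portion
    from the first occurrence of that state onward.  Thin necks and
    one-pixel-wide arms are visited once per side, as the closed polygon
    through pixel centres requires.
    """
    ys, xs = np.nonzero(mask)
    start = (int(ys[0]), int(xs[0]))  # np.nonzero is raster-ordered
    c, b = start, 0  # backtrack west of the raster-first pixel is background
    seen: dict[tuple[tuple[int, int], int], int] = {}
    trail: list[tuple[int, int]] = []
    while (c, b) not in seen:
        seen[(c, b)] = len(trail)
        trail.append(c)
        nxt = None
        for k in range(1, 9):
            i = (b + k) % 8
            dy, dx = _MOORE[i]
            if mask[c[0] + dy, c[1] + dx]:
                nxt = (c[0] + dy, c[1] + dx)
                pdy, pdx = _MOORE[(b + k - 1) % 8]
                prev_bg = (c[0] + pdy, c[1] + pdx)
                break
        if nxt is None:  # isolated pixel
            return trail
        b = _MOORE_INDEX[(prev_bg[0] - nxt[0], prev_bg[1] - nxt[1])]
        c = nxt
    return trail[seen[(c, b)]:]


def trace_perimeter(component: Component) -> float:
    """Outer-border polygon length of the component.

    The border is followed 8-connectedly through pixel centres; each
    axial step contributes 1 and each diagonal step √2, and the polygon
    is closed.  Components with fewer than 3 border points (1–2 pixels,
    or degenerate traces) return 0 by convention; the size filter
    normally removes such objects anyway.
    """
    if component.area == 0:
        raise ValueError("empty component")
    mask, _ = component.local_mask(pad=1)
    contour = _trace_boundary(mask)
    if len(contour) < 3:
        return 0.0
    pts = np.asarray(contour, dtype=float)
    closed = np.vstack([pts, pts[:1]])
    steps = np.diff(closed, axis=0)
    return float(np.hypot(steps[:, 0], steps[:, 1]).sum())


def circularity(area: float, perimeter: float) -> float:
    """4π·area / perimeter², clamped to [0, 1].

    Exactly 1 for an ideal circle (area πr², perimeter 2πr).  Discretised
    contours can overshoot 1 slightly for small compact regions, hence
    the clamp; a degenerate perimeter of 0 maps to 1 by the compactness
    convention.
    """
    if area <= 0:
        raise ValueError("area must be positive")
    if perimeter < 0:
        raise ValueError("perimeter must be non-negative")
    if perimeter == 0:
        return 1.0
    return min(1.0, 4.0 * math.pi * area / perimeter**2)


def classify_rod(circ: float, cutoff: float = DEFAULT_ROD_CUTOFF) -> bool:
    """ROD iff circularity < cutoff (strict: a value at the cutoff is non-ROD)."""
    if not (0 <= circ <= 1 and 0 <= cutoff <= 1):
        raise ValueError("circularity and cutoff must lie in [0, 1]")
    return circ < cutoff


def mean_rgb(component: Component, image: RgbImage) -> tuple[float, float, float]:
    """Channel-wise mean colour over the component's pixels."""
    px = component.pixel_set
    vals = image.pixels[px[:, 1], px[:, 0], :]
    r, g, b = vals.mean(axis=0)
    return float(r), float(g), float(b)


def rgb_to_hsl(r: float, g: float, b: float) -> tuple[float, float, float]:
    """Standard hexagonal RGB → HSL.

    Returns (H, S, L) with H in degrees [0, 360) as a float, S and L in
    [0, 1].  Achromatic colours (max = min) take H = 0 and S = 0.
    """
    for v in (r, g, b):
        if not 0.0 <= v <= 1.0:
            raise ValueError("RGB channels must lie in [0, 1]")
    cmax, cmin = max(r, g, b), min(r, g, b)
    ell = (cmax + cmin) / 2.0
    if cmax == cmin:
        return 0.0, 0.0, ell
    delta = cmax - cmin
    # equivalent to delta / (1 - |2L - 1|) but immune to underflow near L = 0, 1
    s = delta / ((cmax + cmin) if ell <= 0.5 else (2.0 - cmax - cmin))
    if cmax == r:
        h = ((g - b) / delta) % 6.0
    elif cmax == g:
        h = (b - r) / delta + 2.0
    else:
        h = (r - g) / delta + 4.0
    return (60.0 * h) % 360.0, s, ell


def hsl_to_rgb(h: float, s: float, ell: float) -> tuple[float, float, float]:
    """Inverse HSL → RGB (used by the synthetic generator and round-trip checks)."""
    if not (0 <= s <= 1 and 0 <= ell <= 1):
        raise ValueError("S and L must lie in [0, 1]")
    h = h % 360.0
    c = (1.0 - abs(2.0 * ell - 1.0)) * s
    x = c * (1.0 - abs((h / 60.0) % 2.0 - 1.0))
    m = ell - c / 2.0
    sector = int(h // 60) % 6
    rgb = [(c, x, 0), (x, c, 0), (0, c, x), (0, x, c), (x, 0, c), (c, 0, x)][sector]
    return tuple(v + m for v in rgb)  # type: ignore[return-value]


def iod(area: float, mean_l: float) -> float:
    """Integrated optical density: area · (1 − mean lightness)."""
    if area < 0:
        raise ValueError("area must be >= 0")
    if not 0.0 <= mean_l <= 1.0:
        raise ValueError("mean lightness must lie in [0, 1]")
    return area * (1.0 - mean_l)


def build_deposit(
    component: Component,
    image: RgbImage,
    plate_id: str,
    deposit_id: int,
    rod_cutoff: float = DEFAULT_ROD_CUTOFF,
) -> Deposit:
    """Assemble every per-deposit variable from a detected component.

    The colour pathway is mean RGB first, then the HSL of that mean
    colour (not a circular mean of per-pixel hues).  The centroid is the
    arithmetic mean of pixel coordinates.
    """
    px = component.pixel_set
    cx, cy = px[:, 0].mean(), px[:, 1].mean()
    area = component.area
    perim = trace_perimeter(component)
    circ = circularity(area, perim)
    r, g, b = mean_rgb(component, image)
    h, s, ell = rgb_to_hsl(r, g, b)
    return Deposit(
        plate_id=plate_id,
        deposit_id=deposit_id,
        x=float(cx),
        y=float(cy),
        area=area,
        perimeter=perim,
        circularity=circ,
        is_rod=classify_rod(circ, rod_cutoff),
        iod=iod(area, ell),
        mean_r=r,
        mean_g=g,
        mean_b=b,
        mean_h=int(round(h)) % 360,
        mean_s=s,
        mean_l=ell,
        include=True,
        pixel_set=px,
    )
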