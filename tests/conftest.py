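import math

import numpy as np
import pytest

from flyspot.detect import Component, RgbImage
from flyspot.synth import SynthSpec, generate_plate


def rasterise_disc(radius: float, centre: tuple[float, float] | None = None) -> Component:
    """Disc component: pixel centres within ``radius`` of the centre."""
    if centre is None:
        c = radius + 2.0
        centre = (c, c)
    n = int(math.ceil(2 * radius + 5))
    yy, xx = np.mgrid[0:n, 0:n]
    inside = (xx - centre[0]) ** 2 + (yy - centre[1]) ** 2 <= radius**2
    return Component(label=1, pixel_set=np.column_stack([xx[inside], yy[inside]]))


def rasterise_ellipse(a: float, b: float) -> Component:
    """Axis-aligned ellipse with half-axes a (x) and b (y)."""
    cx, cy = a + 2.0, b + 2.0
    yy, xx = np.mgrid[0 : int(2 * b + 5), 0 : int(2 * a + 5)]
    inside = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0
    return Component(label=1, pixel_set=np.column_stack([xx[inside], yy[inside]]))


def rasterise_capsule(length: float, width: float, theta: float = 0.3) -> Component:
    half = (length - width) / 2.0
    ux, uy = math.cos(theta), math.sin(theta)
    c = length / 2.0 + 2.0
    n = int(length + 5)
    yy, xx = np.mgrid[0:n, 0:n]
    px, py = xx - c, yy - c
    t = np.clip(px * ux + py * uy, -half, half)
    inside = (px - t * ux) ** 2 + (py - t * uy) ** 2 <= (width / 2.0) ** 2
    return Component(label=1, pixel_set=np.column_stack([xx[inside], yy[inside]]))


def grey_image(grey: np.ndarray, dpi: float = 1200.0) -> RgbImage:
    """Promote a 2-D intensity grid to an achromatic RgbImage."""
    return RgbImage(np.repeat(np.asarray(grey, float)[:, :, None], 3, axis=2), dpi=dpi)


@pytest.fixture(scope="session")
def default_plate():
    """One default synthetic plate (30 round + 30 oblong deposits), with truth."""
    return generate_plate(SynthSpec(seed=7))


@pytest.fixture(scope="session")
def sparse_plate():
    """A small, quick plate with a handful of well-separated spots."""
    spec = SynthSpec(
        width=300, height=300, n_round=4, n_oblong=2, n_artefacts=3, seed=11
    )
    return generate_plate(spec)
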