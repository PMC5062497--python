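import numpy as np
import pytest

from carrionball.shape_scoring import RasterImage

FLESH = (95, 55, 45)
WHITE = (255, 255, 255)


def disk_image(radius: int, frame: int, view: str = "top",
               color=FLESH, px_per_mm: float | None = None) -> RasterImage:
    """A filled dark disk centred in a white frame."""
    yy, xx = np.mgrid[0:frame, 0:frame]
    c = (frame - 1) / 2.0
    img = np.full((frame, frame, 3), 255, dtype=np.uint8)
    img[(yy - c) ** 2 + (xx - c) ** 2 <= radius**2] = color
    return RasterImage(img, view=view, px_per_mm=px_per_mm)


def ellipse_image(a: float, b: float, frame: int, view: str = "top") -> RasterImage:
    """A filled dark axis-aligned ellipse (semi-axes a, b) in a white frame."""
    yy, xx = np.mgrid[0:frame, 0:frame].astype(float)
    c = (frame - 1) / 2.0
    img = np.full((frame, frame, 3), 255, dtype=np.uint8)
    img[((xx - c) / a) ** 2 + ((yy - c) / b) ** 2 <= 1.0] = FLESH
    return RasterImage(img, view=view)


def ramanujan_perimeter(a: float, b: float) -> float:
    """Ramanujan's closed-form approximation of an ellipse perimeter."""
    return np.pi * (3.0 * (a + b) - np.sqrt((3.0 * a + b) * (a + 3.0 * b)))


@pytest.fixture
def rng():
    return np.random.default_rng(186282)
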