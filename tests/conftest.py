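import numpy as np
import pytest

from mpvol import ParticleMask


def disk_image(radius, center=None, size=None, value=True):
    """Binary image of a rasterized disk (pixel centers strictly inside)."""
    size = size or 2 * radius + 21
    img = np.zeros((size, size), dtype=bool)
    cy, cx = center or (size // 2, size // 2)
    yy, xx = np.mgrid[:size, :size]
    img[(yy - cy) ** 2 + (xx - cx) ** 2 < radius ** 2] = value
    return img


def ellipse_image(a_px, b_px, angle_deg=0.0, size=None):
    """Rasterized ellipse with semi-axes a_px >= b_px, rotated by angle_deg."""
    size = size or 2 * a_px + 21
    c = size / 2.0 - 0.5
    yy, xx = np.mgrid[:size, :size]
    x, y = xx - c, yy - c
    t = np.deg2rad(angle_deg)
    u = x * np.cos(t) + y * np.sin(t)
    v = -x * np.sin(t) + y * np.cos(t)
    return (u / a_px) ** 2 + (v / b_px) ** 2 < 1.0


def square_image(side_px, pad=10):
    img = np.zeros((side_px + 2 * pad, side_px + 2 * pad), dtype=bool)
    img[pad:pad + side_px, pad:pad + side_px] = True
    return img


def band_image(length_px, width_px, pad=10):
    img = np.zeros((width_px + 2 * pad, length_px + 2 * pad), dtype=bool)
    img[pad:pad + width_px, pad:pad + length_px] = True
    return img


def arc_band_image(radius_px, width_px, pad=10):
    """Quarter-circle band of the given centerline radius and thickness."""
    size = radius_px + width_px + 2 * pad
    yy, xx = np.mgrid[:size, :size]
    r = np.hypot(xx - pad, yy - pad)
    quarter = (xx >= pad) & (yy >= pad)
    return quarter & (np.abs(r - radius_px) <= width_px / 2.0)


def as_mask(img, scale=1.0, image_id="fixture"):
    return ParticleMask(np.pad(img, 2), scale=scale, image_id=image_id)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
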