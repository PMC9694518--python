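"""Contrast enhancement, smoothing, and RGB→HSV decomposition.

Slide-scanner acquisitions of FASGA-stained sections are dim and carry
shot noise. The first pipeline step doubles every RGB intensity (clipped
at 255) to spread the histogram, then applies three passes of a radius-2
circular mean filter to suppress acquisition noise. The enhanced image is
decomposed into hue / saturation / value planes on a [0, 1] scale; every
downstream threshold is expressed on that scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import color

from .io import RgbImage

# Radius-2 circular neighborhood: the 21 offsets of a 5x5 square whose
# squared distance to the center is <= 5 (square minus its four corners).
_MEAN_RADIUS = 2
_MEAN_ITERATIONS = 3


def _mean_kernel(radius: int = _MEAN_RADIUS) -> np.ndarray:
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    mask = (yy**2 + xx**2) <= radius**2 + 1
    return mask / mask.sum()


@dataclass
class HsvImage:
    """Hue, saturation and value planes of an image, each in [0, 1].

    Hue is the fraction of the color circle (degrees / 360). Achromatic
    pixels (s == 0) carry h == 0 by convention.
    """

    h: np.ndarray
    s: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        if not (self.h.shape == self.s.shape == self.v.shape):
            raise ValueError("H, S and V planes must share one grid shape")
        for name in ("h", "s", "v"):
            plane = getattr(self, name)
            if plane.min() < 0 or plane.max() > 1:
                raise ValueError(f"{name} plane exceeds [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.h.shape


def enhance(
    image: RgbImage,
    iterations: int = _MEAN_ITERATIONS,
    use_gaussian: bool = False,
) -> RgbImage:
    """Double intensities (clipped) then smooth each channel.

    The default smoother is ``iterations`` passes of the radius-2 circular
    mean filter with replicate-edge padding; three iterated box passes
    closely approximate a Gaussian. Set ``use_gaussian`` to use a single
    Gaussian of matched variance instead (var of one mean pass = mean
    squared radius of the footprint; total var scales with iterations).
    """
    doubled = np.minimum(image.pixels.astype(np.float64) * 2.0, 255.0)
    if use_gaussian:
        kernel = _mean_kernel()
        yy, xx = np.mgrid[-_MEAN_RADIUS : _MEAN_RADIUS + 1, -_MEAN_RADIUS : _MEAN_RADIUS + 1]
        var_one = float(np.sum(kernel * (yy**2)))  # isotropic: per-axis variance
        sigma = np.sqrt(iterations * var_one)
        smoothed = np.stack(
            [
                ndimage.gaussian_filter(doubled[:, :, c], sigma=sigma, mode="nearest")
                for c in range(3)
            ],
            axis=2,
        )
    else:
        kernel = _mean_kernel()
        smoothed = doubled
        for _ in range(iterations):
            smoothed = np.stack(
                [
                    ndimage.correlate(smoothed[:, :, c], kernel, mode="nearest")
                    for c in range(3)
                ],
                axis=2,
            )
    out = np.clip(np.rint(smoothed), 0, 255).astype(np.uint8)
    return RgbImage(out, pixel_size_um=image.pixel_size_um)


def to_hsv(image: RgbImage) -> HsvImage:
    """Hexcone HSV decomposition: S = (max-min)/max, V = max/255, H in [0,1]."""
    hsv = color.rgb2hsv(image.pixels)
    h, s, v = hsv[:, :, 0], hsv[:, :, 1], hsv[:, :, 2]
    h = np.where(s == 0, 0.0, h)
    return HsvImage(
        h=np.clip(h, 0.0, 1.0), s=np.clip(s, 0.0, 1.0), v=np.clip(v, 0.0, 1.0)
    )


def hsv_planes_to_rgb(h: np.ndarray, s: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Inverse transform: HSV planes in [0,1] to float RGB in [0, 255]."""
    from matplotlib.colors import hsv_to_rgb

    hsv = np.stack([h, s, v], axis=-1)
    return hsv_to_rgb(hsv) * 255.0
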