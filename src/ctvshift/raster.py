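"""Rasterization of sagittal anatomies to grayscale images.

Images stand in for the sagittal slice of planning CT / pretreatment CBCT
after bone registration: each organ is filled with a distinct constant
intensity over a soft-tissue background, gas with the lowest intensity.
Pixel values are assigned by point-in-polygon tests at pixel centers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib.path import Path

from .anatomy import SagittalAnatomy
from .geometry import Contour, Point2D

# grey levels, arbitrary HU-like units
INTENSITY = {
    "background": 100.0,
    "bladder": 30.0,
    "rectum": 60.0,
    "ctv": 105.0,
    "prostate": 110.0,
    "bone": 200.0,
    "gas_region": 0.0,
}
_FILL_ORDER = ("bladder", "rectum", "ctv", "prostate", "bone", "gas_region")


@dataclass
class Image2D:
    """Rectangular pixel grid; ``pixels[i, j]`` has center (origin.a + j*px, origin.s + i*px)."""

    pixels: np.ndarray
    pixel_size_mm: float
    origin: Point2D

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("pixel grid must be 2-D")
        if self.pixel_size_mm <= 0:
            raise ValueError("pixel size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(A, S) meshgrids of pixel-center coordinates in mm."""
        n_s, n_a = self.pixels.shape
        a = self.origin.a + np.arange(n_a) * self.pixel_size_mm
        s = self.origin.s + np.arange(n_s) * self.pixel_size_mm
        return np.meshgrid(a, s)


def grid_for(anatomies: list[SagittalAnatomy], pixel_size_mm: float,
             padding_mm: float = 20.0) -> tuple[Point2D, tuple[int, int]]:
    """Common (origin, shape) covering all anatomies with a margin.

    Using one grid for a planning/pretreatment pair keeps their pixels
    aligned, which the grey-value comparator requires.
    """
    lo = np.array([np.inf, np.inf])
    hi = -lo.copy()
    for anat in anatomies:
        for c in anat.organs().values():
            mn_a, mn_s, mx_a, mx_s = c.bounds()
            lo = np.minimum(lo, [mn_a, mn_s])
            hi = np.maximum(hi, [mx_a, mx_s])
    lo -= padding_mm
    hi += padding_mm
    n_a = int(np.ceil((hi[0] - lo[0]) / pixel_size_mm)) + 1
    n_s = int(np.ceil((hi[1] - lo[1]) / pixel_size_mm)) + 1
    return Point2D(lo[0], lo[1]), (n_s, n_a)


def fill_mask(contour: Contour, image: Image2D) -> np.ndarray:
    """Boolean mask of pixels whose centers fall inside the contour."""
    A, S = image.pixel_centers()
    pts = np.column_stack([A.ravel(), S.ravel()])
    inside = Path(contour.vertices, closed=True).contains_points(pts)
    return inside.reshape(image.shape)


def rasterize(anatomy: SagittalAnatomy, pixel_size_mm: float = 1.0,
              include_gas: bool = True, origin: Point2D | None = None,
              shape: tuple[int, int] | None = None,
              padding_mm: float = 20.0) -> Image2D:
    """Rasterize one anatomy; pass a shared (origin, shape) to align image pairs."""
    if pixel_size_mm <= 0:
        raise ValueError("pixel size must be positive")
    if origin is None or shape is None:
        origin, shape = grid_for([anatomy], pixel_size_mm, padding_mm)
    img = Image2D(np.full(shape, INTENSITY["background"]), pixel_size_mm, origin)
    organs = anatomy.organs()
    for name in _FILL_ORDER:
        if name not in organs:
            continue
        if name == "gas_region" and not include_gas:
            continue
        img.pixels[fill_mask(organs[name], img)] = INTENSITY[name]
    return img
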