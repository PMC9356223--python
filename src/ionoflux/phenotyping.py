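"""Image- and gas-exchange-derived phenotyping indices.

Plants under water deficit are monitored non-destructively with side-view RGB
cameras: the projected area and convex-hull area of the segmented plant track
growth and turgor loss, and the Excess Green index (ExG) tracks chlorosis.
Gas-exchange measurements give the photosynthetic water-use efficiency
WUE = A/E (CO2 assimilation over transpiration).

Conventions
-----------
* ExG is computed on the *mean* channel intensities over the plant mask,

      ExG = (2*Gbar - (Rbar + Bbar)) / (Rbar + Gbar + Bbar),

  which is bounded in [-1, 2]. A per-pixel variant (mean of pixelwise ExG)
  is available via ``per_pixel=True``.
* Channel scale is auto-detected: arrays with a maximum above 1 are treated
  as 0-255 integer images and divided by 255 (ExG is scale-invariant, so
  this only matters for mixed-type inputs).
* The convex hull is built on foreground *pixel centers* with Andrew's
  monotone chain and measured with the shoelace formula. Under this
  convention four single pixels at the corners of a 10x10-pixel square span
  a (10-1) x (10-1) = 81-px^2 hull, and a filled mask's hull can be up to
  ~0.5 px smaller per edge than the pixel-counted projected area.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np


class DegenerateImageError(ValueError):
    """Raised when an index is undefined for the masked region."""


@dataclass
class ImageRecord:
    """An RGB image with a binary foreground (plant) mask.

    Parameters
    ----------
    rgb : (H, W, 3) array, integer 0-255 or float 0-1.
    mask : (H, W) boolean array, True on plant pixels.
    pixel_scale : side length of one pixel in cm.
    """

    rgb: np.ndarray
    mask: np.ndarray
    pixel_scale: float = 1.0

    def __post_init__(self) -> None:
        self.rgb = np.asarray(self.rgb)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.rgb.ndim != 3 or self.rgb.shape[2] != 3:
            raise ValueError(f"rgb must be (H, W, 3), got shape {self.rgb.shape}")
        if self.mask.shape != self.rgb.shape[:2]:
            raise ValueError(
                f"mask shape {self.mask.shape} does not match image {self.rgb.shape[:2]}"
            )
        if self.pixel_scale <= 0:
            raise ValueError("pixel_scale must be > 0")


@dataclass
class PhenotypeRecord:
    """One plant's gas-exchange and hormone measurements.

    Units: A in umol CO2 m-2 s-1, E in mmol H2O m-2 s-1, gs in
    mol H2O m-2 s-1, ABA and SA in pg mg-1 FW, delta13C in permil.
    delta13C, ABA and SA are carried as data (measured upstream).
    """

    A: Optional[float] = None
    E: Optional[float] = None
    gs: Optional[float] = None
    delta13C: Optional[float] = None
    ABA: Optional[float] = None
    SA: Optional[float] = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("A", "E", "gs"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")

    @property
    def wue(self) -> Optional[float]:
        if self.A is None or self.E is None:
            return None
        return wue(self.A, self.E)


def _normalized_channels(rgb: np.ndarray) -> np.ndarray:
    rgb = np.asarray(rgb, dtype=float)
    if rgb.max() > 1.0:
        rgb = rgb / 255.0
    return rgb


def excess_green(image: ImageRecord, per_pixel: bool = False) -> float:
    """Excess Green index of the masked plant region.

    With mean channel intensities Rbar, Gbar, Bbar over the mask,
    ExG = (2*Gbar - (Rbar + Bbar)) / (Rbar + Gbar + Bbar) in [-1, 2].

    ``per_pixel=True`` instead averages the pixelwise index (pixels whose
    channel sum is zero are excluded from that average).
    """
    if not image.mask.any():
        raise DegenerateImageError("mask has no foreground pixels")
    rgb = _normalized_channels(image.rgb)[image.mask]  # (n, 3)
    if per_pixel:
        sums = rgb.sum(axis=1)
        ok = sums > 0
        if not ok.any():
            raise DegenerateImageError("all masked pixels are black; ExG undefined")
        r, g, b = rgb[ok, 0], rgb[ok, 1], rgb[ok, 2]
        return float(np.mean((2 * g - (r + b)) / sums[ok]))
    rbar, gbar, bbar = rgb.mean(axis=0)
    total = rbar + gbar + bbar
    if total == 0:
        raise DegenerateImageError("masked region is entirely black; ExG undefined")
    return float((2 * gbar - (rbar + bbar)) / total)


def projected_area(mask: np.ndarray, pixel_scale: float = 1.0) -> float:
    """Projected plant area in cm^2: foreground pixel count x pixel_scale^2."""
    mask = np.asarray(mask, dtype=bool)
    if pixel_scale <= 0:
        raise ValueError("pixel_scale must be > 0")
    if not mask.any():
        raise DegenerateImageError("mask has no foreground pixels")
    return float(mask.sum()) * pixel_scale**2


def _monotone_chain(points: np.ndarray) -> np.ndarray:
    """Convex hull vertices (CCW) of 2-D points by Andrew's monotone chain."""
    pts = np.unique(points, axis=0)  # lexicographic sort + dedup
    if len(pts) <= 2:
        return pts

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    lower: list = []
    for p in pts:
        while len(lower) >= 2 and cross(lower[-2], lower[-1], p) <= 0:
            lower.pop()
        lower.append(p)
    upper: list = []
    for p in pts[::-1]:
        while len(upper) >= 2 and cross(upper[-2], upper[-1], p) <= 0:
            upper.pop()
        upper.append(p)
    return np.array(lower[:-1] + upper[:-1])


def shoelace_area(vertices: np.ndarray) -> float:
    """Polygon area from an ordered vertex list (shoelace formula)."""
    v = np.asarray(vertices, dtype=float)
    if len(v) < 3:
        return 0.0
    x, y = v[:, 0], v[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


def convex_hull_area(mask: np.ndarray, pixel_scale: float = 1.0) -> float:
    """Convex-hull area (cm^2) of the foreground pixel centers.

    Fewer than 3 non-collinear foreground pixels is a degenerate hull: the
    function warns and returns 0.0.
    """
    mask = np.asarray(mask, dtype=bool)
    if pixel_scale <= 0:
        raise ValueError("pixel_scale must be > 0")
    if not mask.any():
        raise DegenerateImageError("mask has no foreground pixels")
    rows, cols = np.nonzero(mask)
    pts = np.column_stack([cols, rows]).astype(float)  # pixel centers (x, y)
    hull = _monotone_chain(pts)
    area = shoelace_area(hull)
    if area == 0.0:
        warnings.warn(
            "degenerate hull: fewer than 3 non-collinear foreground pixels",
            RuntimeWarning,
            stacklevel=2,
        )
    return area * pixel_scale**2


def convex_hull_vertices(mask: np.ndarray) -> np.ndarray:
    """Hull vertices (x, y pixel-center coordinates, CCW order) of a mask."""
    mask = np.asarray(mask, dtype=bool)
    rows, cols = np.nonzero(mask)
    return _monotone_chain(np.column_stack([cols, rows]).astype(float))


def wue(A: float, E: float) -> float:
    """Photosynthetic water-use efficiency A/E (umol CO2 per mmol H2O)."""
    if E <= 0:
        raise ValueError(f"transpiration rate E must be > 0, got {E}")
    return A / E
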