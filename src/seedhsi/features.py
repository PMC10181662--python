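"""Spatial-spectral phenotype descriptors for segmented seeds.

Seeds are modelled as ellipses.  The boundary diameter (maximum pairwise
distance between boundary points) defines the major axis; the half-extent
perpendicular to it defines the minor axis.  From the half-axes ``a >= b``
the ellipse descriptors follow:

    eccentricity = sqrt(1 - (b/a)^2)
    area         = pi * a * b
    perimeter    = pi * (a + b)        (crude approximation, kept by design)
    compactness  = p^2 / A
    roundness    = 4 * pi * A / p^2

so roundness * compactness == 4*pi identically.  The perimeter is the
coarse first-order approximation rather than Ramanujan's; pass
``perimeter_method="ramanujan"`` to compare.  Mean intensity averages each
pixel's spectrum over bands first, then over masked pixels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import binary_erosion
from scipy.spatial.distance import cdist

from .segmentation import SeedCube, SeedRegion

__all__ = [
    "ShapeFeatures",
    "boundary_diameter",
    "boundary_points",
    "axes_from_region",
    "ellipse_features",
    "mean_intensity",
    "mean_spectrum",
    "feature_table",
]

FEATURE_COLUMNS = [
    "source", "class", "exposure", "diameter", "a", "b", "eccentricity",
    "area", "perimeter", "compactness", "roundness", "mean_intensity",
]


@dataclass(frozen=True)
class ShapeFeatures:
    diameter: float
    a: float
    b: float
    eccentricity: float
    area: float
    perimeter: float
    compactness: float
    roundness: float
    mean_intensity: float
    degenerate: bool = False  # collinear region: b == 0


def boundary_diameter(points: np.ndarray) -> tuple[float, tuple[int, int]]:
    """Maximum pairwise Euclidean distance over boundary points.

    Returns the diameter and the achieving index pair; ties resolve to the
    lexicographically smallest ``(i, j)`` with ``i < j``.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.size == 0:
        raise ValueError("need at least one boundary point")
    pts = pts.reshape(len(pts), -1)
    if len(pts) == 1:
        return 0.0, (0, 0)
    d = cdist(pts, pts)
    best = d.max()
    # Smallest (i, j), i < j, within float tolerance of the max.
    close = np.argwhere(d >= best * (1 - 1e-12))
    pairs = close[close[:, 0] < close[:, 1]]
    if len(pairs) == 0:  # all points coincide
        return 0.0, (0, 1)
    i, j = min(map(tuple, pairs))
    return float(d[i, j]), (int(i), int(j))


def boundary_points(mask: np.ndarray) -> np.ndarray:
    """Outer-contour pixel centers (pixels with an 8-neighbour outside)."""
    mask = np.asarray(mask, dtype=bool)
    inner = binary_erosion(mask, structure=np.ones((3, 3)), border_value=0)
    return np.argwhere(mask & ~inner).astype(np.float64)


def axes_from_region(region: SeedRegion | np.ndarray) -> tuple[float, float, float]:
    """Half-axes ``(a, b)`` and the major-axis orientation (radians).

    ``a`` is half the boundary diameter along the diameter's endpoint
    direction; ``b`` is half the mask's extent projected on the
    perpendicular direction.  A collinear region returns ``b = 0``.
    """
    mask = region.mask if isinstance(region, SeedRegion) else np.asarray(region, dtype=bool)
    if mask.sum() < 3:
        raise ValueError("region must contain at least 3 pixels")
    pts = boundary_points(mask)
    diam, (i, j) = boundary_diameter(pts)
    if diam == 0:
        return 0.0, 0.0, 0.0
    direction = pts[j] - pts[i]
    direction /= np.linalg.norm(direction)
    orientation = float(math.atan2(direction[0], direction[1]))
    perp = np.array([-direction[1], direction[0]])
    all_pts = np.argwhere(mask).astype(np.float64)
    proj = all_pts @ perp
    a = diam / 2.0
    b = float(np.ptp(proj)) / 2.0
    if b > a:
        a, b = b, a
    return a, b, orientation


def ellipse_features(
    a: float, b: float, perimeter_method: str = "crude"
) -> tuple[float, float, float, float, float]:
    """Eccentricity, area, perimeter, compactness, roundness from half-axes.

    ``perimeter_method="crude"`` uses p = pi*(a+b); ``"ramanujan"`` uses
    Ramanujan's closer approximation for comparison.
    """
    if a <= 0:
        raise ValueError("major half-axis a must be > 0")
    if b > a:
        raise ValueError(f"require a >= b, got a={a}, b={b}")
    if b < 0:
        raise ValueError("minor half-axis b must be >= 0")
    ecc = math.sqrt(1.0 - (b / a) ** 2)
    area = math.pi * a * b
    if perimeter_method == "crude":
        p = math.pi * (a + b)
    elif perimeter_method == "ramanujan":
        h = ((a - b) / (a + b)) ** 2
        p = math.pi * (a + b) * (1 + 3 * h / (10 + math.sqrt(4 - 3 * h)))
    else:
        raise ValueError(f"unknown perimeter_method {perimeter_method!r}")
    if area == 0:
        raise ValueError("degenerate ellipse (b = 0) has undefined compactness")
    compactness = p**2 / area
    roundness = 4 * math.pi * area / p**2
    return ecc, area, p, compactness, roundness


def mean_intensity(seed: SeedCube) -> float:
    """Mean over masked pixels of each pixel's band-averaged reflectance."""
    if not seed.mask.any():
        raise ValueError("seed mask is empty")
    per_pixel = seed.data.mean(axis=2)
    return float(per_pixel[seed.mask].mean())


def mean_spectrum(seed: SeedCube) -> np.ndarray:
    """Per-band mean reflectance over masked pixels."""
    if not seed.mask.any():
        raise ValueError("seed mask is empty")
    return seed.data[seed.mask].mean(axis=0)


def shape_features(seed: SeedCube) -> ShapeFeatures:
    """All descriptors for one seed cube (mask defines the region)."""
    a, b, _ = axes_from_region(seed.mask)
    degenerate = b == 0
    if degenerate:
        ecc, area, p, compactness, roundness = 1.0, 0.0, math.pi * a, float("nan"), float("nan")
    else:
        ecc, area, p, compactness, roundness = ellipse_features(a, b)
    return ShapeFeatures(
        diameter=2 * a,
        a=a,
        b=b,
        eccentricity=ecc,
        area=area,
        perimeter=p,
        compactness=compactness,
        roundness=roundness,
        mean_intensity=mean_intensity(seed),
        degenerate=degenerate,
    )


def feature_table(seeds: list[SeedCube]) -> pd.DataFrame:
    """One row of descriptors + labels per seed, stable column order."""
    rows = []
    for seed in seeds:
        f = shape_features(seed)
        rows.append(
            {
                "source": seed.source,
                "class": seed.class_label,
                "exposure": seed.exposure_label,
                "diameter": f.diameter,
                "a": f.a,
                "b": f.b,
                "eccentricity": f.eccentricity,
                "area": f.area,
                "perimeter": f.perimeter,
                "compactness": f.compactness,
                "roundness": f.roundness,
                "mean_intensity": f.mean_intensity,
            }
        )
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)
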