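"""Seed segmentation and per-seed sub-cube extraction.

A calibrated panel cube holding many seeds on a dark background is reduced
to a scalar score image (mean reflectance over a band window), thresholded
with Otsu's method, cleaned by binary closing, and labelled by
8-connectivity.  Each retained connected component becomes a
:class:`SeedRegion`; :func:`extract_seed_cubes` then cuts one fixed-size,
background-zeroed sub-cube per region for the seed-level classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label, regionprops
from skimage.morphology import disk
from skimage.transform import resize

from .io_hypercube import Hypercube

__all__ = ["SeedRegion", "SeedCube", "SegmentationParams", "segment_panel", "extract_seed_cubes"]


@dataclass
class SeedRegion:
    """One segmented seed in the panel frame.

    ``bbox`` is 0-based half-open ``(row_min, col_min, row_max, col_max)``.
    """

    label_id: int
    mask: np.ndarray
    bbox: tuple[int, int, int, int]
    centroid: tuple[float, float]
    area_px: int

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.area_px != int(self.mask.sum()):
            raise ValueError("area_px does not match mask pixel count")


@dataclass
class SeedCube:
    """Fixed-size masked sub-cube for one seed, plus its labels."""

    data: np.ndarray
    mask: np.ndarray
    class_label: str | None = None
    exposure_label: float | None = None
    source: str = ""
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.shape[:2] != self.mask.shape:
            raise ValueError("seed cube and mask spatial dims differ")


@dataclass
class SegmentationParams:
    """Knobs for :func:`segment_panel`.

    band_window
        ``(lo, hi)`` band-index window (half-open) averaged into the score
        image; ``None`` averages all bands.
    threshold_method
        Only ``"otsu"`` is implemented.
    min_area
        Components below this pixel count are dropped.
    closing_radius
        Disk radius for binary closing; 0 disables.
    border_policy
        ``"discard"`` drops regions touching the panel edge; ``"keep"``
        retains them.
    """

    band_window: tuple[int, int] | None = None
    threshold_method: str = "otsu"
    min_area: int = 50
    closing_radius: int = 2
    border_policy: str = "discard"

    def validate(self) -> None:
        if self.threshold_method != "otsu":
            raise ValueError(f"unknown threshold_method {self.threshold_method!r}")
        if self.min_area < 1:
            raise ValueError("min_area must be >= 1")
        if self.closing_radius < 0:
            raise ValueError("closing_radius must be >= 0")
        if self.border_policy not in ("discard", "keep"):
            raise ValueError(f"unknown border_policy {self.border_policy!r}")


def segment_panel(
    panel: Hypercube, params: SegmentationParams | None = None
) -> list[SeedRegion]:
    """Find seed regions in a calibrated panel.

    Returns regions sorted by ``(row_min, col_min)``, re-labelled 1..n in
    that order.  A constant or empty panel yields an empty list.
    """
    params = params or SegmentationParams()
    params.validate()
    if not panel.calibrated:
        raise ValueError("panel must be calibrated before segmentation")

    if params.band_window is None:
        score = panel.data.mean(axis=2)
    else:
        lo, hi = params.band_window
        if not (0 <= lo < hi <= panel.bands):
            raise ValueError(f"band_window {params.band_window} invalid for {panel.bands} bands")
        score = panel.data[:, :, lo:hi].mean(axis=2)

    if np.ptp(score) == 0:
        return []
    fg = score > threshold_otsu(score)
    if params.closing_radius > 0:
        fg = ndimage.binary_closing(fg, structure=disk(params.closing_radius))
    labels = cc_label(fg, connectivity=2)  # 8-connectivity

    regions: list[SeedRegion] = []
    for prop in regionprops(labels):
        if prop.area < params.min_area:
            continue
        r0, c0, r1, c1 = prop.bbox
        if params.border_policy == "discard" and (
            r0 == 0 or c0 == 0 or r1 == panel.rows or c1 == panel.cols
        ):
            continue
        mask = labels == prop.label
        regions.append(
            SeedRegion(
                label_id=prop.label,
                mask=mask,
                bbox=(r0, c0, r1, c1),
                centroid=(float(prop.centroid[0]), float(prop.centroid[1])),
                area_px=int(prop.area),
            )
        )
    regions.sort(key=lambda r: (r.bbox[0], r.bbox[1]))
    for new_id, region in enumerate(regions, start=1):
        region.label_id = new_id
    return regions


def _center_pad(crop: np.ndarray, mask: np.ndarray, h: int, w: int) -> tuple[np.ndarray, np.ndarray]:
    ch, cw = mask.shape
    out = np.zeros((h, w) + crop.shape[2:], dtype=crop.dtype)
    out_mask = np.zeros((h, w), dtype=bool)
    r0 = (h - ch) // 2
    c0 = (w - cw) // 2
    out[r0 : r0 + ch, c0 : c0 + cw] = crop
    out_mask[r0 : r0 + ch, c0 : c0 + cw] = mask
    return out, out_mask


def extract_seed_cubes(
    panel: Hypercube,
    regions: Sequence[SeedRegion],
    canonical_hw: tuple[int, int] = (64, 32),
    class_label: str | None = None,
    exposure_label: float | None = None,
    panel_id: str = "panel",
    allow_resize: bool = True,
) -> list[SeedCube]:
    """Cut one canonical-size sub-cube per region.

    Pixels outside the region mask are zeroed.  Bounding-box content is
    centred and zero-padded into ``canonical_hw``; a bbox exceeding the
    canonical size is band-wise bilinearly resized when ``allow_resize``,
    and a size error otherwise.  The band axis is never resampled.
    """
    h, w = canonical_hw
    out: list[SeedCube] = []
    for region in regions:
        r0, c0, r1, c1 = region.bbox
        crop = panel.data[r0:r1, c0:c1].copy()
        mask = region.mask[r0:r1, c0:c1]
        crop[~mask] = 0.0
        ch, cw = mask.shape
        if ch > h or cw > w:
            if not allow_resize:
                raise ValueError(
                    f"region {region.label_id} bbox {ch}x{cw} exceeds canonical {h}x{w}"
                )
            scale = min(h / ch, w / cw)
            nh, nw = max(1, int(np.floor(ch * scale))), max(1, int(np.floor(cw * scale)))
            crop = resize(crop, (nh, nw, crop.shape[2]), order=1, preserve_range=True,
                          anti_aliasing=False).astype(np.float32)
            mask = resize(mask.astype(np.float32), (nh, nw), order=1,
                          preserve_range=True, anti_aliasing=False) > 0.5
            crop[~mask] = 0.0
        data, m = _center_pad(crop, mask, h, w)
        out.append(
            SeedCube(
                data=data,
                mask=m,
                class_label=class_label,
                exposure_label=exposure_label,
                source=f"{panel_id}:{region.label_id}",
            )
        )
    return out
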