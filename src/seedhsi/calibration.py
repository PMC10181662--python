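"""Reflectance calibration of raw intensity cubes.

Raw line-scan intensities are converted to fractional reflectance with the
standard white/dark two-point (Shafer) model::

    I_c = (I - I_d) / (I_w - I_d)

where ``I_w`` is a white-reference frame (a Teflon tile, nominally 100%
reflectance) and ``I_d`` a dark frame (shutter closed, 0% reflectance).
References may be full-frame cubes or reduced profiles (a per-band spectrum,
or a per-column x per-band profile as line-scan systems produce); anything
NumPy-broadcastable onto the raw cube with a matching band axis is accepted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_hypercube import Hypercube

__all__ = ["CalibrationRefs", "DegenerateReferenceError", "calibrate", "average_reference"]

logger = logging.getLogger(__name__)


class DegenerateReferenceError(ValueError):
    """White and dark references coincide somewhere (zero denominator)."""


@dataclass
class CalibrationRefs:
    """White (100%) and dark (0%) reference cubes or profiles."""

    white: Hypercube
    dark: Hypercube

    def __post_init__(self) -> None:
        if self.white.data.shape != self.dark.data.shape:
            raise ValueError(
                f"white {self.white.data.shape} and dark {self.dark.data.shape} dims differ"
            )
        if self.white.grid != self.dark.grid:
            raise ValueError("white and dark wavelength grids differ")


def _broadcast_ref(ref: np.ndarray, target_shape: tuple[int, ...]) -> np.ndarray:
    """Broadcast a reference (full frame or profile) to the raw cube shape."""
    try:
        return np.broadcast_to(ref, target_shape)
    except ValueError as exc:
        raise ValueError(
            f"reference shape {ref.shape} not broadcastable to cube shape {target_shape}"
        ) from exc


def calibrate(
    raw: Hypercube,
    refs: CalibrationRefs,
    clip: bool = True,
    epsilon_guard: bool = False,
    epsilon_frac: float = 1e-6,
) -> Hypercube:
    """Convert a raw cube to reflectance: ``(I - I_d) / (I_w - I_d)``.

    Parameters
    ----------
    raw
        Uncalibrated intensity cube.  Calibrating twice is an error.
    refs
        White and dark references, broadcastable to ``raw``.
    clip
        Clamp the result to [0, 1.2].  Specular glints can slightly exceed
        the Teflon reference; unbounded values destabilise training.
    epsilon_guard
        When on, pixels whose denominator magnitude falls below
        ``epsilon_frac`` of the white dynamic range are masked to 0 (with a
        logged count) instead of raising.
    """
    if raw.calibrated:
        raise ValueError("cube is already calibrated; refusing to calibrate twice")
    if refs.white.bands != raw.bands:
        raise ValueError(
            f"reference has {refs.white.bands} bands but raw cube has {raw.bands}"
        )
    white = _broadcast_ref(refs.white.data.astype(np.float64), raw.data.shape)
    dark = _broadcast_ref(refs.dark.data.astype(np.float64), raw.data.shape)
    denom = white - dark

    eps = epsilon_frac * float(np.ptp(white)) if np.ptp(white) > 0 else epsilon_frac
    degenerate = np.abs(denom) < max(eps, np.finfo(np.float64).tiny)
    n_bad = int(degenerate.sum())
    if n_bad and not epsilon_guard:
        bad_bands = np.unique(np.nonzero(degenerate)[2])
        raise DegenerateReferenceError(
            f"white == dark at {n_bad} element(s) across band(s) {bad_bands.tolist()}"
        )

    with np.errstate(divide="ignore", invalid="ignore"):
        refl = (raw.data.astype(np.float64) - dark) / denom
    if n_bad:
        logger.warning("epsilon guard masked %d degenerate reference element(s)", n_bad)
        refl[degenerate] = 0.0
    if clip:
        refl = np.clip(refl, 0.0, 1.2)

    meta = dict(raw.meta)
    meta["calibrated"] = True
    return Hypercube(data=refl.astype(np.float32), grid=raw.grid, meta=meta)


def average_reference(frames: list[Hypercube]) -> Hypercube:
    """Elementwise mean of repeated reference frames."""
    if not frames:
        raise ValueError("need at least one reference frame")
    shape = frames[0].data.shape
    grid = frames[0].grid
    for f in frames[1:]:
        if f.data.shape != shape:
            raise ValueError(f"frame shape {f.data.shape} differs from first frame {shape}")
        if f.grid != grid:
            raise ValueError("reference frames have differing wavelength grids")
    mean = np.mean([f.data.astype(np.float64) for f in frames], axis=0)
    return Hypercube(data=mean.astype(np.float32), grid=grid, meta=dict(frames[0].meta))
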