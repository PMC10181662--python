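"""Synthetic labelled hyperspectral seed panels.

Real acquisitions of this kind are line-scan cubes of seed panels: bright
ellipsoidal seeds on a dark tray, five temperature-treatment classes, six
exposure durations, and a white/dark reference pair per session.  No such
dataset ships with the package, so this module generates panels with the
same statistical structure, giving every pipeline stage a ground truth:

* each class has a smooth mean reflectance spectrum — a shared baseline
  plus class-specific Gaussian bumps whose amplitudes scale with a
  ``separation`` knob, so pairwise class distances are proportional to it;
* exposure duration acts as a smaller within-class amplitude modulation;
* pixel noise is i.i.d. Gaussian per pixel-band (no spatial correlation —
  a documented simplification);
* the raw cube is synthesised as ``dark + reflectance * (white - dark)``
  with a smooth non-flat lamp spectrum, so reflectance calibration is a
  non-trivial inversion that recovers the generated scene exactly at zero
  noise.

The default wavelength grid is the emulated instrument's
597.21-1703.93 nm at 4.14 nm (268 bands); ``reduced_grid`` spans the same
range with fewer bands for fast tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_dilation

from .calibration import CalibrationRefs
from .cnn3d import LabeledSeedSet
from .dnn_pixel import PixelDataset, build_pixel_dataset
from .io_hypercube import Hypercube, WavelengthGrid
from .segmentation import SeedCube, SeedRegion

__all__ = [
    "SpectralClassModel",
    "SeedSpec",
    "PanelSpec",
    "INSTRUMENT_GRID",
    "DEFAULT_EXPOSURES_H",
    "DEFAULT_CLASS_NAMES",
    "reduced_grid",
    "make_class_models",
    "make_panel_spec",
    "generate_panel",
    "generate_dataset",
]

INSTRUMENT_GRID = WavelengthGrid(start_nm=597.21, step_nm=4.14, count=268)
DEFAULT_EXPOSURES_H = (168, 180, 204, 216, 228, 240)
DEFAULT_CLASS_NAMES = ("Control", "HDNT1", "HNT", "HDT", "HDNT2")

_BACKGROUND_REFLECTANCE = 0.03


def reduced_grid(count: int) -> WavelengthGrid:
    """Grid spanning the instrument's full range with ``count`` bands."""
    if count < 2:
        raise ValueError("need at least 2 bands")
    step = (INSTRUMENT_GRID.stop_nm - INSTRUMENT_GRID.start_nm) / (count - 1)
    return WavelengthGrid(start_nm=INSTRUMENT_GRID.start_nm, step_nm=step, count=count)


@dataclass
class SpectralClassModel:
    """Mean-spectrum model for one treatment class.

    ``bumps`` are ``(center_nm, width_nm, amplitude)`` Gaussians added to a
    shared sloped baseline; ``noise_sigma`` is the i.i.d. pixel-band noise
    in reflectance units; ``exposure_sensitivity`` scales the within-class
    amplitude shift across exposure durations.
    """

    name: str
    bumps: list[tuple[float, float, float]]
    slope: float = 0.0
    base_level: float = 0.30
    noise_sigma: float = 0.02
    exposure_sensitivity: float = 0.03

    def __post_init__(self) -> None:
        if any(amp < 0 for _, _, amp in self.bumps):
            raise ValueError("bump amplitudes must be >= 0")

    def mean_spectrum(self, grid: WavelengthGrid, exposure_h: float | None = None) -> np.ndarray:
        wl = grid.wavelengths()
        span = INSTRUMENT_GRID.stop_nm - INSTRUMENT_GRID.start_nm
        spec = self.base_level + self.slope * (wl - wl.mean()) / span
        bump_sum = np.zeros_like(wl)
        for center, width, amp in self.bumps:
            bump_sum += amp * np.exp(-0.5 * ((wl - center) / width) ** 2)
        gain = 1.0
        if exposure_h is not None:
            mid = np.mean(DEFAULT_EXPOSURES_H)
            half_range = (max(DEFAULT_EXPOSURES_H) - min(DEFAULT_EXPOSURES_H)) / 2
            gain = 1.0 + self.exposure_sensitivity * (exposure_h - mid) / half_range
        spec = spec + gain * bump_sum
        if spec.min() < 0 or spec.max() > 1:
            raise ValueError(f"class {self.name!r} mean reflectance leaves [0, 1]")
        return spec


@dataclass
class SeedSpec:
    """Placement of one elliptical seed in a panel."""

    class_name: str
    exposure_h: float
    a: float                      # major half-axis, px
    b: float                      # minor half-axis, px
    center: tuple[float, float]   # (row, col)
    orientation: float = 0.0      # radians, 0 = major axis along columns


@dataclass
class PanelSpec:
    rows: int
    cols: int
    grid: WavelengthGrid = field(default_factory=lambda: INSTRUMENT_GRID)
    seeds: list[SeedSpec] = field(default_factory=list)
    white_level: float = 0.9
    white_peak_nm: float = 1100.0
    white_width_nm: float = 700.0
    dark_level: float = 0.05
    background_sigma: float = 0.005
    rng_seed: int = 0


def make_class_models(
    n_classes: int,
    separation: float = 1.0,
    rng_seed: int = 0,
    noise_sigma: float = 0.02,
    class_names: tuple[str, ...] | None = None,
) -> list[SpectralClassModel]:
    """Class models whose pairwise mean-spectrum distances scale with
    ``separation``.

    Each class gets three Gaussian bumps at class-specific random centers;
    amplitudes are proportional to ``separation`` (so ``separation=0``
    collapses all means onto the shared baseline).
    """
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    if separation < 0:
        raise ValueError("separation must be >= 0")
    rng = np.random.default_rng(rng_seed)
    if class_names is None:
        if n_classes <= len(DEFAULT_CLASS_NAMES):
            class_names = DEFAULT_CLASS_NAMES[:n_classes]
        else:
            class_names = tuple(f"class{i}" for i in range(n_classes))
    models = []
    for name in class_names:
        centers = rng.uniform(INSTRUMENT_GRID.start_nm + 50, INSTRUMENT_GRID.stop_nm - 50, size=3)
        widths = rng.uniform(40.0, 90.0, size=3)
        amps = separation * rng.uniform(0.05, 0.12, size=3)
        slope = separation * rng.uniform(-0.05, 0.05)
        models.append(
            SpectralClassModel(
                name=name,
                bumps=[(float(c), float(w), float(a)) for c, w, a in zip(centers, widths, amps)],
                slope=float(slope),
                noise_sigma=noise_sigma,
            )
        )
    return models


def _ellipse_mask(
    shape: tuple[int, int], center: tuple[float, float], a: float, b: float, theta: float
) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dr = rr - center[0]
    dc = cc - center[1]
    # Major axis along columns when theta == 0.
    u = dc * np.cos(theta) + dr * np.sin(theta)
    v = -dc * np.sin(theta) + dr * np.cos(theta)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def make_panel_spec(
    models: list[SpectralClassModel],
    seeds_per_class: int = 2,
    rows: int = 160,
    cols: int = 160,
    grid: WavelengthGrid | None = None,
    rng_seed: int = 0,
    a_range: tuple[float, float] = (9.0, 12.0),
    b_range: tuple[float, float] = (5.0, 7.0),
    margin: int = 16,
) -> PanelSpec:
    """Lay seeds out on a jittered grid so placements never overlap."""
    rng = np.random.default_rng(rng_seed)
    n_seeds = seeds_per_class * len(models)
    pitch = 2 * max(a_range[1], b_range[1]) + 6
    per_row = max(1, int((cols - 2 * margin) // pitch))
    n_rows_needed = -(-n_seeds // per_row)
    if margin + n_rows_needed * pitch > rows:
        raise ValueError(
            f"panel {rows}x{cols} too small for {n_seeds} seeds at pitch {pitch:.0f}"
        )
    specs: list[SeedSpec] = []
    order = rng.permutation(n_seeds)
    classes = [m.name for m in models for _ in range(seeds_per_class)]
    for slot, k in enumerate(order):
        gr, gc = divmod(slot, per_row)
        jitter = rng.uniform(-2, 2, size=2)
        center = (
            margin + gr * pitch + pitch / 2 + jitter[0],
            margin + gc * pitch + pitch / 2 + jitter[1],
        )
        specs.append(
            SeedSpec(
                class_name=classes[k],
                exposure_h=float(rng.choice(DEFAULT_EXPOSURES_H)),
                a=float(rng.uniform(*a_range)),
                b=float(rng.uniform(*b_range)),
                center=center,
                orientation=float(rng.uniform(0, np.pi)),
            )
        )
    return PanelSpec(
        rows=rows, cols=cols, grid=grid or reduced_grid(32), seeds=specs, rng_seed=rng_seed
    )


def generate_panel(
    spec: PanelSpec, models: list[SpectralClassModel]
) -> tuple[Hypercube, CalibrationRefs, dict]:
    """Synthesise one raw panel cube plus its references and ground truth.

    Returns ``(raw, refs, truth)`` where ``truth`` holds the reflectance
    scene, a per-pixel class-index raster (background -1), and the list of
    true :class:`SeedRegion` masks.  The raw cube is
    ``dark + reflectance * (white - dark)``, with Gaussian noise applied in
    the reflectance domain, so calibration inverts it exactly at zero noise.
    """
    rng = np.random.default_rng(spec.rng_seed)
    model_by_name = {m.name: m for m in models}
    class_names = [m.name for m in models]
    wl = spec.grid.wavelengths()

    refl = np.full(
        (spec.rows, spec.cols, spec.grid.count), _BACKGROUND_REFLECTANCE, dtype=np.float64
    )
    if spec.background_sigma > 0:
        refl += rng.normal(0, spec.background_sigma, size=refl.shape)
    raster = np.full((spec.rows, spec.cols), -1, dtype=np.int64)
    regions: list[SeedRegion] = []
    occupied = np.zeros((spec.rows, spec.cols), dtype=bool)
    for i, seed in enumerate(spec.seeds):
        if seed.class_name not in model_by_name:
            raise ValueError(f"seed {i} references unknown class {seed.class_name!r}")
        mask = _ellipse_mask((spec.rows, spec.cols), seed.center, seed.a, seed.b,
                             seed.orientation)
        if not mask.any():
            raise ValueError(f"seed {i} ellipse rasterises to zero pixels")
        rr, cc = np.nonzero(mask)
        if rr.min() == 0 or cc.min() == 0 or rr.max() == spec.rows - 1 or cc.max() == spec.cols - 1:
            raise ValueError(f"seed {i} ellipse touches or leaves the panel frame")
        grown = binary_dilation(mask, np.ones((3, 3)))
        if (grown & occupied).any():
            raise ValueError(f"seed {i} ellipse within 2 px of another seed")
        occupied |= grown
        model = model_by_name[seed.class_name]
        spectrum = model.mean_spectrum(spec.grid, seed.exposure_h)
        pix = np.broadcast_to(spectrum, (rr.size, spec.grid.count)).copy()
        if model.noise_sigma > 0:
            pix += rng.normal(0, model.noise_sigma, size=pix.shape)
        refl[rr, cc] = pix
        raster[mask] = class_names.index(seed.class_name)
        regions.append(
            SeedRegion(
                label_id=i + 1,
                mask=mask,
                bbox=(int(rr.min()), int(cc.min()), int(rr.max()) + 1, int(cc.max()) + 1),
                centroid=(float(rr.mean()), float(cc.mean())),
                area_px=int(mask.sum()),
            )
        )
    refl = np.clip(refl, 0.0, 1.2)

    lamp = spec.white_level * np.exp(
        -0.5 * ((wl - spec.white_peak_nm) / spec.white_width_nm) ** 2
    )
    white = np.broadcast_to(lamp, refl.shape).astype(np.float32)
    dark = np.full(refl.shape, spec.dark_level, dtype=np.float32)
    raw_data = dark + refl * (white - dark)

    raw = Hypercube(
        data=raw_data.astype(np.float32), grid=spec.grid,
        meta={"calibrated": False, "panel_seed": spec.rng_seed},
    )
    refs = CalibrationRefs(
        white=Hypercube(data=white, grid=spec.grid, meta={"role": "white"}),
        dark=Hypercube(data=dark, grid=spec.grid, meta={"role": "dark"}),
    )
    truth = {
        "reflectance": refl.astype(np.float32),
        "raster": raster,
        "regions": regions,
        "class_names": class_names,
        "seeds": spec.seeds,
    }
    return raw, refs, truth


def generate_dataset(
    n_per_class: int,
    models: list[SpectralClassModel],
    chip_hw: tuple[int, int] = (16, 16),
    grid: WavelengthGrid | None = None,
    rng_seed: int = 0,
) -> tuple[LabeledSeedSet, PixelDataset, dict]:
    """Per-seed chips generated directly from truth masks (no segmentation).

    Each chip holds one centred ellipse whose pixels carry the class mean
    spectrum (exposure-modulated) plus noise; background stays zero.
    Deterministic for a fixed ``rng_seed``.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    grid = grid or reduced_grid(32)
    rng = np.random.default_rng(rng_seed)
    h, w = chip_hw
    max_b = min(h, w) / 2 - 1.5
    max_a = max(h, w) / 2 - 1.5
    cubes: list[SeedCube] = []
    labels: list[str] = []
    truth_shapes = []
    for model in models:
        for k in range(n_per_class):
            a = float(rng.uniform(0.7 * max_a, max_a))
            b = float(rng.uniform(0.6 * max_b, max_b))
            if b > a:
                a, b = b, a
            theta = float(rng.uniform(0, np.pi)) if h == w else 0.0
            exposure = float(rng.choice(DEFAULT_EXPOSURES_H))
            mask = _ellipse_mask((h, w), ((h - 1) / 2, (w - 1) / 2), a, b, theta)
            data = np.zeros((h, w, grid.count), dtype=np.float64)
            spectrum = model.mean_spectrum(grid, exposure)
            rr, cc = np.nonzero(mask)
            pix = np.broadcast_to(spectrum, (rr.size, grid.count)).copy()
            if model.noise_sigma > 0:
                pix += rng.normal(0, model.noise_sigma, size=pix.shape)
            data[rr, cc] = np.clip(pix, 0.0, 1.2)
            cubes.append(
                SeedCube(
                    data=data.astype(np.float32), mask=mask,
                    class_label=model.name, exposure_label=exposure,
                    source=f"sim:{model.name}:{k}",
                )
            )
            labels.append(model.name)
            truth_shapes.append({"class": model.name, "a": a, "b": b,
                                 "orientation": theta, "exposure_h": exposure})
    seed_set = LabeledSeedSet(cubes=cubes, labels=labels)
    pixels = build_pixel_dataset(cubes)
    truth = {"shapes": truth_shapes, "grid": grid,
             "class_names": [m.name for m in models]}
    return seed_set, pixels, truth
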