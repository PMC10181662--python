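"""Hyperspectral cube container and on-disk I/O.

A hypercube is a 3-D array of shape ``(rows, cols, bands)`` in which every
spatial pixel carries a full spectrum.  The wavelength axis is a uniform
grid (line-scan spectrographs sample at a fixed interval; the instrument
emulated here spans 597.21-1703.93 nm at 4.14 nm, i.e. 268 bands).

Two on-disk dialects are supported:

* ENVI — a plain-text ``.hdr`` companion to a flat binary cube, with the
  three standard interleaves (BIL, BIP, BSQ).  All interleaves are
  normalised to ``(rows, cols, bands)`` on read.
* HDF5 — datasets ``/data`` and ``/wavelengths_nm``; free-form metadata as
  root attributes.

Storage dtype is float32 throughout; raw sensor cubes stored as uint16 are
converted on read.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Any

import h5py
import numpy as np

__all__ = [
    "WavelengthGrid",
    "Hypercube",
    "read_cube",
    "write_cube",
    "band_index_for_wavelength",
    "rgb_composite",
    "FormatError",
]


class FormatError(ValueError):
    """Raised when an on-disk cube violates its format contract."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform wavelength sampling: ``wavelength(i) = start_nm + i * step_nm``."""

    start_nm: float
    step_nm: float
    count: int

    def __post_init__(self) -> None:
        if self.step_nm <= 0:
            raise ValueError(f"step_nm must be > 0, got {self.step_nm}")
        if self.count < 1:
            raise ValueError(f"count must be >= 1, got {self.count}")

    def wavelength(self, i: int) -> float:
        if not 0 <= i < self.count:
            raise IndexError(f"band index {i} outside [0, {self.count})")
        return self.start_nm + i * self.step_nm

    @property
    def stop_nm(self) -> float:
        """Wavelength of the last band."""
        return self.start_nm + (self.count - 1) * self.step_nm

    def wavelengths(self) -> np.ndarray:
        return self.start_nm + self.step_nm * np.arange(self.count)

    @classmethod
    def from_range(cls, start_nm: float, stop_nm: float, step_nm: float) -> "WavelengthGrid":
        """Grid implied by printed endpoints and sampling interval.

        The band count is the number of samples on ``[start, stop]`` at the
        given interval, i.e. ``round((stop - start) / step) + 1``.
        """
        count = int(round((stop_nm - start_nm) / step_nm)) + 1
        return cls(start_nm=start_nm, step_nm=step_nm, count=count)


@dataclass
class Hypercube:
    """A ``(rows, cols, bands)`` reflectance or intensity cube plus its grid."""

    data: np.ndarray
    grid: WavelengthGrid
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError(f"cube must be 3-D (rows, cols, bands), got shape {self.data.shape}")
        if self.data.shape[2] != self.grid.count:
            raise ValueError(
                f"band dimension {self.data.shape[2]} does not match grid count {self.grid.count}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("cube contains non-finite values")

    @property
    def rows(self) -> int:
        return self.data.shape[0]

    @property
    def cols(self) -> int:
        return self.data.shape[1]

    @property
    def bands(self) -> int:
        return self.data.shape[2]

    @property
    def calibrated(self) -> bool:
        return bool(self.meta.get("calibrated", False))


# ---------------------------------------------------------------------------
# ENVI dialect

_ENVI_DTYPES = {1: np.uint8, 2: np.int16, 4: np.float32, 5: np.float64, 12: np.uint16}
_ENVI_CODES = {np.dtype(np.float32): 4, np.dtype(np.uint16): 12}


def _parse_envi_header(path: str) -> dict[str, Any]:
    with open(path, "r") as fh:
        text = fh.read()
    if not text.lstrip().upper().startswith("ENVI"):
        raise FormatError(f"{path}: missing ENVI magic line")
    fields: dict[str, Any] = {}
    # Collapse brace-delimited multi-line values first.
    body = text.split("\n", 1)[1] if "\n" in text else ""
    i = 0
    lines: list[str] = []
    buf = ""
    in_braces = False
    for ch in body:
        if ch == "{":
            in_braces = True
        elif ch == "}":
            in_braces = False
        if ch == "\n" and not in_braces:
            lines.append(buf)
            buf = ""
        else:
            buf += ch
    if buf.strip():
        lines.append(buf)
    for line in lines:
        if "=" not in line:
            continue
        key, val = line.split("=", 1)
        key = key.strip().lower()
        val = val.strip()
        if val.startswith("{") and val.endswith("}"):
            items = [v.strip() for v in val[1:-1].replace("\n", " ").split(",") if v.strip()]
            fields[key] = items
        else:
            fields[key] = val
    return fields


def _read_envi(path: str) -> Hypercube:
    hdr_path = path if path.endswith(".hdr") else path + ".hdr"
    if not os.path.exists(hdr_path):
        raise FormatError(f"ENVI header not found: {hdr_path}")
    fields = _parse_envi_header(hdr_path)
    required = ("samples", "lines", "bands", "data type", "interleave", "wavelength")
    missing = [k for k in required if k not in fields]
    if missing:
        raise FormatError(f"{hdr_path}: missing required header field(s): {missing}")
    cols = int(fields["samples"])
    rows = int(fields["lines"])
    bands = int(fields["bands"])
    dtype_code = int(fields["data type"])
    if dtype_code not in _ENVI_DTYPES:
        raise FormatError(f"unsupported ENVI data type code {dtype_code}")
    interleave = str(fields["interleave"]).lower()
    if interleave not in ("bil", "bip", "bsq"):
        raise FormatError(f"unsupported interleave {interleave!r}")
    wavelengths = np.array([float(w) for w in fields["wavelength"]])
    if wavelengths.size != bands:
        raise FormatError(
            f"header declares {bands} bands but lists {wavelengths.size} wavelengths"
        )
    byte_order = int(fields.get("byte order", 0))
    dtype = np.dtype(_ENVI_DTYPES[dtype_code])
    if byte_order == 1:
        dtype = dtype.newbyteorder(">")

    bin_path = hdr_path[:-4]
    if not os.path.exists(bin_path):
        raise FormatError(f"ENVI binary not found: {bin_path}")
    flat = np.fromfile(bin_path, dtype=dtype)
    if flat.size != rows * cols * bands:
        raise FormatError(
            f"binary has {flat.size} elements, header implies {rows * cols * bands}"
        )
    if interleave == "bsq":  # (bands, rows, cols)
        data = flat.reshape(bands, rows, cols).transpose(1, 2, 0)
    elif interleave == "bil":  # (rows, bands, cols)
        data = flat.reshape(rows, bands, cols).transpose(0, 2, 1)
    else:  # bip: (rows, cols, bands)
        data = flat.reshape(rows, cols, bands)

    steps = np.diff(wavelengths)
    step = float(steps[0]) if steps.size else 1.0
    if steps.size and not np.allclose(steps, step, atol=1e-2):
        raise FormatError("wavelength list is not a uniform grid")
    grid = WavelengthGrid(start_nm=float(wavelengths[0]), step_nm=step, count=bands)
    meta: dict[str, Any] = {}
    if "description" in fields:
        meta["description"] = fields["description"]
    for key in ("class", "exposure_h", "calibrated"):
        if key in fields:
            meta[key] = fields[key]
    if "calibrated" in meta:
        meta["calibrated"] = str(meta["calibrated"]).lower() in ("1", "true", "yes")
    return Hypercube(data=data.astype(np.float32), grid=grid, meta=meta)


def _write_envi(cube: Hypercube, path: str, interleave: str = "bil") -> None:
    interleave = interleave.lower()
    if interleave not in ("bil", "bip", "bsq"):
        raise ValueError(f"unsupported interleave {interleave!r}")
    hdr_path = path if path.endswith(".hdr") else path + ".hdr"
    bin_path = hdr_path[:-4]
    data = cube.data.astype(np.float32)
    if interleave == "bsq":
        out = data.transpose(2, 0, 1)
    elif interleave == "bil":
        out = data.transpose(0, 2, 1)
    else:
        out = data
    wl = ", ".join(f"{w:.2f}" for w in cube.grid.wavelengths())
    lines = [
        "ENVI",
        f"samples = {cube.cols}",
        f"lines = {cube.rows}",
        f"bands = {cube.bands}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {_ENVI_CODES[np.dtype(np.float32)]}",
        f"interleave = {interleave}",
        "byte order = 0",
        f"wavelength = {{ {wl} }}",
    ]
    if cube.meta.get("calibrated"):
        lines.append("calibrated = 1")
    try:
        np.ascontiguousarray(out).tofile(bin_path)
        with open(hdr_path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
    except OSError as exc:
        raise OSError(f"cannot write ENVI cube at {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# HDF5 dialect

def _read_hdf5(path: str) -> Hypercube:
    with h5py.File(path, "r") as fh:
        if "data" not in fh or "wavelengths_nm" not in fh:
            raise FormatError(f"{path}: HDF5 cube needs datasets 'data' and 'wavelengths_nm'")
        data = np.asarray(fh["data"], dtype=np.float32)
        wl = np.asarray(fh["wavelengths_nm"], dtype=np.float64)
        meta = {}
        for key, val in fh.attrs.items():
            meta[key] = val.item() if isinstance(val, np.generic) else val
    if data.ndim != 3 or data.shape[2] != wl.size:
        raise FormatError(
            f"{path}: data shape {data.shape} inconsistent with {wl.size} wavelengths"
        )
    steps = np.diff(wl)
    step = float(steps[0]) if steps.size else 1.0
    grid = WavelengthGrid(start_nm=float(wl[0]), step_nm=step, count=wl.size)
    if "calibrated" in meta:
        meta["calibrated"] = bool(meta["calibrated"])
    return Hypercube(data=data, grid=grid, meta=meta)


def _write_hdf5(cube: Hypercube, path: str) -> None:
    try:
        with h5py.File(path, "w") as fh:
            fh.create_dataset("data", data=cube.data.astype(np.float32))
            fh.create_dataset("wavelengths_nm", data=cube.grid.wavelengths())
            for key, val in cube.meta.items():
                if isinstance(val, bool):
                    val = int(val)
                if isinstance(val, (str, int, float, np.generic)):
                    fh.attrs[key] = val
    except OSError as exc:
        raise OSError(f"cannot write HDF5 cube at {path}: {exc}") from exc


def _infer_format(path: str, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    if path.endswith((".h5", ".hdf5")):
        return "hdf5"
    return "envi"


def read_cube(path: str, format: str | None = None) -> Hypercube:
    """Read a hypercube from ENVI or HDF5.

    The format is inferred from the extension when not given
    (``.h5``/``.hdf5`` → HDF5, otherwise ENVI).
    """
    fmt = _infer_format(path, format)
    if fmt == "envi":
        return _read_envi(path)
    if fmt == "hdf5":
        return _read_hdf5(path)
    raise ValueError(f"unknown format {fmt!r}")


def write_cube(
    cube: Hypercube, path: str, format: str | None = None, interleave: str = "bil"
) -> None:
    """Write a hypercube losslessly (float32) to ENVI or HDF5."""
    fmt = _infer_format(path, format)
    if fmt == "envi":
        _write_envi(cube, path, interleave=interleave)
    elif fmt == "hdf5":
        _write_hdf5(cube, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def band_index_for_wavelength(grid: WavelengthGrid, nm: float) -> int:
    """Nearest band index for a wavelength; exact midpoints round down.

    Raises ``ValueError`` for wavelengths more than half a step outside the
    sampled range.
    """
    lo = grid.start_nm - grid.step_nm / 2
    hi = grid.stop_nm + grid.step_nm / 2
    if not lo <= nm <= hi:
        raise ValueError(
            f"wavelength {nm} nm outside sampled range "
            f"[{grid.start_nm}, {grid.stop_nm}] +/- step/2"
        )
    frac = (nm - grid.start_nm) / grid.step_nm
    # Nearest with exact .5 ties toward the lower index.
    idx = int(np.floor(frac + 0.5))
    if abs(frac - np.floor(frac) - 0.5) < 1e-12:
        idx = int(np.floor(frac))
    return int(np.clip(idx, 0, grid.count - 1))


def rgb_composite(cube: Hypercube, r: int, g: int, b: int) -> np.ndarray:
    """Three selected bands, each min-max scaled to [0, 1], stacked as RGB.

    A constant band scales to all zeros.
    """
    channels = []
    for idx in (r, g, b):
        if not 0 <= idx < cube.bands:
            raise IndexError(f"band index {idx} outside [0, {cube.bands})")
        band = cube.data[:, :, idx].astype(np.float64)
        span = band.max() - band.min()
        if span == 0:
            channels.append(np.zeros_like(band))
        else:
            channels.append((band - band.min()) / span)
    return np.stack(channels, axis=-1)
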