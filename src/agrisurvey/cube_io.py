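"""Hyperspectral/multispectral cube container and raster I/O.

A :class:`HyperCube` is a rows x cols x bands array with per-band center
wavelengths in nm, a units flag (raw digital numbers vs reflectance) and an
optional nodata sentinel. Two on-disk forms are supported:

* multiband TIFF, one band per page, with the wavelengths/units/nodata
  carried as a JSON document in the ImageDescription tag;
* the ENVI header-pair convention (text ``.hdr`` beside a raw ``.dat``/
  ``.img`` file, band-sequential layout) with wavelengths read from the
  ``wavelength = { ... }`` field.

Bands are stored ascending by wavelength (re-sorted on read if necessary) so
index arithmetic downstream is deterministic. Band lookup is by nearest
wavelength within a tolerance (default 15 nm, a typical multispectral band
half-width).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile

from .errors import InvalidInputError, MissingBandError, ParseError

__all__ = ["HyperCube", "read_cube", "write_cube", "band_at", "DEFAULT_TOL_NM"]

UNITS_DN = "DN"
UNITS_REFLECTANCE = "reflectance"

DEFAULT_TOL_NM = 15.0

_ENVI_DTYPES = {1: "u1", 2: "i2", 3: "i4", 4: "f4", 5: "f8", 12: "u2", 13: "u4"}
_ENVI_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


@dataclass
class HyperCube:
    """rows x cols x n_bands image cube with per-band center wavelengths (nm)."""

    data: np.ndarray
    wavelengths: np.ndarray
    units: str = UNITS_DN
    nodata: float | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise InvalidInputError(f"cube must be 3-D, got shape {self.data.shape}")
        if self.wavelengths.ndim != 1 or len(self.wavelengths) != self.data.shape[2]:
            raise InvalidInputError(
                f"{len(self.wavelengths)} wavelengths for {self.data.shape[2]} bands"
            )
        if np.any(np.diff(self.wavelengths) <= 0):
            order = np.argsort(self.wavelengths, kind="stable")
            if np.any(np.diff(self.wavelengths[order]) <= 0):
                raise InvalidInputError("wavelengths must be strictly increasing")
            self.wavelengths = self.wavelengths[order]
            self.data = self.data[:, :, order]
        if self.units not in (UNITS_DN, UNITS_REFLECTANCE):
            raise InvalidInputError(f"unknown units {self.units!r}")
        if np.issubdtype(self.data.dtype, np.floating):
            bad = ~np.isfinite(self.data)
            if self.nodata is not None and np.isfinite(self.nodata):
                if bad.any():
                    raise InvalidInputError("non-finite values that are not nodata")
            elif bad.any() and self.nodata is None:
                raise InvalidInputError("non-finite values present and no nodata set")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def band(self, b: int) -> np.ndarray:
        """A single band plane (rows x cols view)."""
        return self.data[:, :, b]

    def valid_mask(self) -> np.ndarray:
        """Boolean rows x cols mask of pixels valid in every band."""
        if self.nodata is None:
            return np.ones(self.data.shape[:2], dtype=bool)
        return ~np.any(self.data == self.nodata, axis=2)

    def __eq__(self, other) -> bool:
        if not isinstance(other, HyperCube):
            return NotImplemented
        return (
            self.units == other.units
            and self.nodata == other.nodata
            and np.array_equal(self.wavelengths, other.wavelengths)
            and self.data.dtype == other.data.dtype
            and np.array_equal(self.data, other.data)
        )


def band_at(cube: HyperCube, target_nm: float, tolerance_nm: float = DEFAULT_TOL_NM) -> int:
    """Index of the band nearest ``target_nm``; ties break toward the lower
    wavelength. Raises :class:`MissingBandError` if the nearest band deviates
    more than ``tolerance_nm``."""
    if tolerance_nm < 0:
        raise InvalidInputError(f"tolerance must be >= 0, got {tolerance_nm}")
    dev = np.abs(cube.wavelengths - target_nm)
    idx = int(np.argmin(dev))  # argmin returns the first (lower-wavelength) tie
    if dev[idx] > tolerance_nm:
        raise MissingBandError(
            f"no band within {tolerance_nm} nm of {target_nm} nm "
            f"(nearest: {cube.wavelengths[idx]} nm at index {idx})"
        )
    return idx


# ---------------------------------------------------------------------------
# TIFF


def _tiff_description(cube: HyperCube) -> str:
    return json.dumps(
        {
            "agrisurvey_cube": 1,
            "wavelengths_nm": [float(w) for w in cube.wavelengths],
            "units": cube.units,
            "nodata": cube.nodata,
        }
    )


def _write_tiff(cube: HyperCube, path: Path) -> None:
    # band-sequential pages so readers can stream one band at a time
    tifffile.imwrite(
        path,
        np.moveaxis(cube.data, 2, 0),
        description=_tiff_description(cube),
        photometric="minisblack",
    )


def _read_tiff(path: Path, wavelengths=None) -> HyperCube:
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        desc = tf.pages[0].description or ""
    if arr.ndim == 2:
        arr = arr[None, :, :]
    meta = {}
    try:
        meta = json.loads(desc)
    except (json.JSONDecodeError, TypeError):
        pass
    if wavelengths is None:
        wavelengths = meta.get("wavelengths_nm")
    if wavelengths is None:
        raise ParseError(
            f"{path}: no per-band wavelength metadata found; pass wavelengths "
            "explicitly (CLI: --wavelengths 450,560,...)"
        )
    if len(wavelengths) != arr.shape[0]:
        raise ParseError(
            f"{path}: {arr.shape[0]} bands but {len(wavelengths)} wavelengths listed"
        )
    return HyperCube(
        np.moveaxis(arr, 0, 2),
        np.asarray(wavelengths, dtype=float),
        units=meta.get("units", UNITS_DN),
        nodata=meta.get("nodata"),
    )


# ---------------------------------------------------------------------------
# ENVI header pair


def _parse_envi_header(text: str) -> dict:
    # collapse { ... } blocks (possibly multi-line) before splitting on '='
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    fields: dict[str, str] = {}
    for line in text.splitlines():
        if "=" not in line:
            continue
        key, _, val = line.partition("=")
        fields[key.strip().lower()] = val.strip()
    return fields


def _read_envi(hdr_path: Path, wavelengths=None) -> HyperCube:
    text = hdr_path.read_text()
    if not text.lstrip().upper().startswith("ENVI"):
        raise ParseError(f"{hdr_path}: not an ENVI header (missing 'ENVI' magic)", line=1)
    fields = _parse_envi_header(text)
    try:
        samples = int(fields["samples"])  # cols
        lines_n = int(fields["lines"])  # rows
        bands = int(fields["bands"])
        dtype_code = int(fields["data type"])
    except KeyError as e:
        raise ParseError(f"{hdr_path}: missing ENVI field {e.args[0]!r}") from None
    if dtype_code not in _ENVI_DTYPES:
        raise ParseError(f"{hdr_path}: unsupported ENVI data type {dtype_code}")
    interleave = fields.get("interleave", "bsq").lower()
    if interleave != "bsq":
        raise ParseError(f"{hdr_path}: only BSQ interleave supported, got {interleave}")
    byte_order = int(fields.get("byte order", 0))
    dtype = np.dtype(("<" if byte_order == 0 else ">") + _ENVI_DTYPES[dtype_code])

    if wavelengths is None and "wavelength" in fields:
        m = re.search(r"\{([^}]*)\}", fields["wavelength"])
        if m:
            wavelengths = [float(tok) for tok in m.group(1).split(",") if tok.strip()]
    if wavelengths is None:
        raise ParseError(
            f"{hdr_path}: no 'wavelength' field; pass wavelengths explicitly "
            "(CLI: --wavelengths 450,560,...)"
        )
    if len(wavelengths) != bands:
        raise ParseError(f"{hdr_path}: {bands} bands but {len(wavelengths)} wavelengths")

    dat_path = None
    for ext in (".dat", ".img", ".raw", ""):
        cand = hdr_path.with_suffix(ext)
        if cand != hdr_path and cand.exists():
            dat_path = cand
            break
    if dat_path is None:
        raise ParseError(f"no data file found beside {hdr_path}")
    raw = np.fromfile(dat_path, dtype=dtype)
    expected = samples * lines_n * bands
    if raw.size != expected:
        raise ParseError(
            f"{dat_path}: expected {expected} values, found {raw.size}"
        )
    data = raw.reshape(bands, lines_n, samples)  # BSQ
    units = UNITS_REFLECTANCE if "reflectance" in fields.get("data units", "").lower() else UNITS_DN
    nodata = float(fields["data ignore value"]) if "data ignore value" in fields else None
    return HyperCube(
        np.moveaxis(data, 0, 2),
        np.asarray(wavelengths, dtype=float),
        units=units,
        nodata=nodata,
    )


def _write_envi(cube: HyperCube, hdr_path: Path) -> None:
    dtype = cube.data.dtype.newbyteorder("<")
    if np.dtype(dtype.str[1:]) not in _ENVI_CODES:
        raise InvalidInputError(f"dtype {cube.data.dtype} not representable in ENVI")
    code = _ENVI_CODES[np.dtype(dtype.str[1:])]
    rows, cols, bands = cube.shape
    wl = ", ".join(f"{w:g}" for w in cube.wavelengths)
    lines = [
        "ENVI",
        "description = {agrisurvey cube}",
        f"samples = {cols}",
        f"lines = {rows}",
        f"bands = {bands}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {code}",
        "interleave = bsq",
        "byte order = 0",
        f"wavelength units = Nanometers",
        f"wavelength = {{ {wl} }}",
        f"data units = {{{cube.units}}}",
    ]
    if cube.nodata is not None:
        lines.append(f"data ignore value = {cube.nodata:g}")
    hdr_path.write_text("\n".join(lines) + "\n")
    dat_path = hdr_path.with_suffix(".dat")
    np.ascontiguousarray(np.moveaxis(cube.data, 2, 0)).astype(dtype).tofile(dat_path)


# ---------------------------------------------------------------------------
# dispatch


def read_cube(path, wavelengths=None) -> HyperCube:
    """Read a cube from multiband TIFF or an ENVI ``.hdr`` header pair.

    ``wavelengths`` (list of nm) overrides/supplies band metadata for files
    that lack it.
    """
    path = Path(path)
    if path.suffix.lower() == ".hdr":
        return _read_envi(path, wavelengths)
    if path.suffix.lower() in (".tif", ".tiff"):
        return _read_tiff(path, wavelengths)
    # sniff: ENVI headers are text starting with 'ENVI'
    head = path.open("rb").read(4)
    if head == b"ENVI":
        return _read_envi(path, wavelengths)
    return _read_tiff(path, wavelengths)


def write_cube(cube: HyperCube, path) -> Path:
    """Write a cube; format chosen by extension (.tif/.tiff or .hdr). Returns path.

    Round trip through :func:`read_cube` is bitwise for integer DN cubes and
    exact for float32/float64 reflectance cubes (values are stored verbatim).
    """
    path = Path(path)
    if path.suffix.lower() == ".hdr":
        _write_envi(cube, path)
    elif path.suffix.lower() in (".tif", ".tiff"):
        _write_tiff(cube, path)
    else:
        raise InvalidInputError(
            f"cannot infer cube format from extension {path.suffix!r} (use .tif or .hdr)"
        )
    return path
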