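"""Empirical-line surface-reflectance calibration.

Reference panels of known reflectance (classically a pure black, a pure
white and intermediate grays) are imaged within the scene. For each spectral
band, the mean digital number (DN) over each panel region is regressed
against the panel's known reflectance with ordinary least squares:

    reflectance = gain_b * DN + offset_b          (per band b)

Applying the fitted per-band affine map to every pixel converts the raw DN
cube into a surface-reflectance cube. With exactly two panels the line
interpolates both points; with more, the fit is OLS and the per-band
coefficient of determination r^2 is reported as a quality diagnostic.

Atmospheric correction is deliberately out of scope: at UAV altitudes the
atmospheric path is short enough that its contribution folds into the
panel-anchored line.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .cube_io import UNITS_DN, UNITS_REFLECTANCE, HyperCube
from .errors import DegenerateFitError, InvalidInputError, UnitsError

__all__ = [
    "PanelSpec",
    "CalibrationModel",
    "extract_panel_stats",
    "fit_empirical_line",
    "apply_correction",
    "calibrate",
    "load_panels",
    "PANEL_PRESETS",
]

#: Panel reflectance presets. "grayscale" follows the three-step calibration
#: template convention (black 10%, gray 30%, white 57%); "ideal" is the
#: textbook 0%-black / 100%-white pair.
PANEL_PRESETS: dict[str, dict[str, float]] = {
    "grayscale": {"black": 0.10, "gray": 0.30, "white": 0.57},
    "ideal": {"black": 0.0, "white": 1.0},
}


@dataclass(frozen=True)
class PanelSpec:
    """A calibration panel: known reflectance and its pixel region in the cube.

    ``reflectance`` is a fraction in [0, 1], either a scalar (flat spectrum)
    or a per-band curve matching the cube's band count. ``region`` is a
    half-open pixel rectangle (row0, row1, col0, col1) or a boolean mask.
    """

    label: str
    reflectance: float | np.ndarray
    region: tuple[int, int, int, int] | np.ndarray

    def __post_init__(self):
        r = np.asarray(self.reflectance, dtype=float)
        if np.any(r < 0) or np.any(r > 1):
            raise InvalidInputError(
                f"panel {self.label!r}: reflectance must lie in [0, 1], got {self.reflectance}"
            )

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        if isinstance(self.region, np.ndarray):
            m = self.region.astype(bool)
            if m.shape != shape:
                raise InvalidInputError(
                    f"panel {self.label!r}: mask shape {m.shape} != image shape {shape}"
                )
            return m
        r0, r1, c0, c1 = self.region
        if not (0 <= r0 < r1 <= shape[0] and 0 <= c0 < c1 <= shape[1]):
            raise InvalidInputError(
                f"panel {self.label!r}: region {self.region} outside image {shape}"
            )
        m = np.zeros(shape, dtype=bool)
        m[r0:r1, c0:c1] = True
        return m

    def reflectance_per_band(self, n_bands: int) -> np.ndarray:
        r = np.asarray(self.reflectance, dtype=float)
        if r.ndim == 0:
            return np.full(n_bands, float(r))
        if r.shape != (n_bands,):
            raise InvalidInputError(
                f"panel {self.label!r}: {r.size} reflectances for {n_bands} bands"
            )
        return r


@dataclass(frozen=True)
class CalibrationModel:
    """Per-band affine DN -> reflectance map with fit diagnostics."""

    gain: np.ndarray  # reflectance per DN
    offset: np.ndarray  # reflectance
    wavelengths: np.ndarray  # nm
    fit_r2: np.ndarray

    def __post_init__(self):
        for name in ("gain", "offset", "wavelengths", "fit_r2"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.wavelengths)
        if not (len(self.gain) == len(self.offset) == len(self.fit_r2) == n):
            raise InvalidInputError("calibration arrays must share the band count")
        if not np.all(np.isfinite(self.gain)):
            raise InvalidInputError("non-finite gain")

    @property
    def n_bands(self) -> int:
        return len(self.wavelengths)

    def to_table(self) -> str:
        """CSV report: wavelength_nm, gain, offset, r2."""
        lines = ["wavelength_nm,gain,offset,r2"]
        for w, g, o, r in zip(self.wavelengths, self.gain, self.offset, self.fit_r2):
            lines.append(f"{w:g},{g!r},{o!r},{r!r}")
        return "\n".join(lines) + "\n"


def extract_panel_stats(cube: HyperCube, panels: list[PanelSpec]) -> np.ndarray:
    """Mean DN over each panel region, per band: (n_panels, n_bands) array.

    Nodata pixels are excluded from the means; a region that is entirely
    nodata is an error.
    """
    if cube.units != UNITS_DN:
        raise UnitsError("panel statistics are extracted from a raw DN cube")
    if not panels:
        raise InvalidInputError("no panels given")
    valid = cube.valid_mask()
    means = np.empty((len(panels), cube.n_bands), dtype=float)
    for k, panel in enumerate(panels):
        m = panel.mask(cube.shape[:2]) & valid
        if not m.any():
            raise InvalidInputError(
                f"panel {panel.label!r}: region contains no valid (non-nodata) pixels"
            )
        for b in range(cube.n_bands):
            means[k, b] = float(cube.band(b)[m].mean())
    return means


def fit_empirical_line(
    panel_means: np.ndarray,
    panel_reflectances: np.ndarray,
    wavelengths: np.ndarray | None = None,
) -> CalibrationModel:
    """Per-band OLS fit of reflectance against mean panel DN.

    ``panel_means`` is (n_panels, n_bands); ``panel_reflectances`` is either
    (n_panels,) for flat spectra or (n_panels, n_bands). Requires >= 2 panels
    with distinct mean DN in every band.
    """
    dn = np.asarray(panel_means, dtype=float)
    refl = np.asarray(panel_reflectances, dtype=float)
    if dn.ndim != 2:
        raise InvalidInputError(f"panel_means must be 2-D, got shape {dn.shape}")
    n_panels, n_bands = dn.shape
    if n_panels < 2:
        raise DegenerateFitError(f"need >= 2 panels, got {n_panels}")
    if refl.ndim == 1:
        refl = np.broadcast_to(refl[:, None], dn.shape)
    if refl.shape != dn.shape:
        raise InvalidInputError(
            f"reflectance shape {refl.shape} incompatible with means {dn.shape}"
        )
    gain = np.empty(n_bands)
    offset = np.empty(n_bands)
    r2 = np.empty(n_bands)
    for b in range(n_bands):
        x, y = dn[:, b], refl[:, b]
        sx = x - x.mean()
        sxx = float(sx @ sx)
        if sxx == 0.0:
            raise DegenerateFitError(
                f"band {b}: all panels share the same mean DN ({x[0]}); cannot fit a line"
            )
        g = float(sx @ (y - y.mean())) / sxx
        o = float(y.mean() - g * x.mean())
        gain[b], offset[b] = g, o
        resid = y - (g * x + o)
        syy = float(((y - y.mean()) ** 2).sum())
        r2[b] = 1.0 if syy == 0.0 else 1.0 - float((resid**2).sum()) / syy
    if wavelengths is None:
        wavelengths = np.arange(n_bands, dtype=float)
    return CalibrationModel(gain, offset, np.asarray(wavelengths, float), r2)


def apply_correction(
    cube: HyperCube,
    model: CalibrationModel,
    clip: tuple[float, float] | None = (0.0, 1.5),
) -> HyperCube:
    """Convert a DN cube to reflectance: out = gain_b * DN + offset_b per band.

    Output is clipped to ``clip`` (default [0, 1.5]: keeps specular outliers
    above 1 while bounding them; pass None to disable). Nodata pixels are
    propagated unchanged. Works band-at-a-time so peak memory stays near two
    band planes plus the output.
    """
    if cube.units == UNITS_REFLECTANCE:
        raise UnitsError("cube is already in reflectance units; refusing to re-correct")
    if cube.units != UNITS_DN:
        raise UnitsError(f"expected a DN cube, got units {cube.units!r}")
    if model.n_bands != cube.n_bands:
        raise InvalidInputError(
            f"model has {model.n_bands} bands, cube has {cube.n_bands}"
        )
    nodata_out = -9999.0 if cube.nodata is not None else None
    out = np.empty(cube.shape, dtype=np.float64)
    invalid = None if cube.nodata is None else ~cube.valid_mask()
    for b in range(cube.n_bands):
        plane = model.gain[b] * cube.band(b).astype(np.float64) + model.offset[b]
        if clip is not None:
            np.clip(plane, clip[0], clip[1], out=plane)
        if invalid is not None:
            plane[invalid] = nodata_out
        out[:, :, b] = plane
    return HyperCube(out, cube.wavelengths.copy(), units=UNITS_REFLECTANCE, nodata=nodata_out)


def calibrate(
    cube: HyperCube,
    panels: list[PanelSpec],
    clip: tuple[float, float] | None = (0.0, 1.5),
) -> tuple[HyperCube, CalibrationModel]:
    """Fit the empirical line from the panels and apply it: (reflectance cube, model)."""
    means = extract_panel_stats(cube, panels)
    refl = np.stack([p.reflectance_per_band(cube.n_bands) for p in panels])
    model = fit_empirical_line(means, refl, cube.wavelengths)
    return apply_correction(cube, model, clip=clip), model


def load_panels(path: str | Path) -> list[PanelSpec]:
    """Read panel specs from YAML/JSON: a list of {label, reflectance,
    region: [row0, row1, col0, col1]} records, or {preset: name, regions:
    {label: [r0, r1, c0, c1]}} using :data:`PANEL_PRESETS` reflectances."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if isinstance(doc, dict) and "preset" in doc:
        preset = doc["preset"]
        if preset not in PANEL_PRESETS:
            raise InvalidInputError(
                f"unknown panel preset {preset!r}; options: {sorted(PANEL_PRESETS)}"
            )
        table = PANEL_PRESETS[preset]
        out = []
        for label, region in doc.get("regions", {}).items():
            if label not in table:
                raise InvalidInputError(
                    f"label {label!r} not in preset {preset!r} ({sorted(table)})"
                )
            out.append(PanelSpec(label, table[label], tuple(int(v) for v in region)))
        if not out:
            raise InvalidInputError(f"{path}: preset given but no regions")
        return out
    if not isinstance(doc, list):
        raise InvalidInputError(f"{path}: expected a list of panel records")
    return [
        PanelSpec(
            str(rec["label"]),
            rec["reflectance"],
            tuple(int(v) for v in rec["region"]),
        )
        for rec in doc
    ]
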