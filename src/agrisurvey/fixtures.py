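"""Deterministic synthetic data: survey polygons and multispectral scenes.

No field imagery is bundled; instead this module builds scenes with fully
known ground truth so every processing stage can be verified end-to-end:

* a reflectance field with soil background, vegetation regions whose
  640/860 nm bands are solved algebraically to hit target NDVI values, and
  gray-scale calibration panels stamped as flat-spectrum rectangles;
* a linear sensor model converting reflectance to digital numbers,
  DN = (reflectance - offset_true) / gain_true, plus optional additive
  gaussian DN noise — so the empirical-line calibration should recover
  (gain_true, offset_true) per band;
* a truth record carrying every generating parameter, including the exact
  healthy-pixel fraction of the noiseless NDVI field.

Everything is seeded: the same spec produces bit-identical cubes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .calibration import PANEL_PRESETS, PanelSpec
from .cube_io import UNITS_DN, HyperCube
from .errors import InvalidSpecError
from .geo import GeoPoint, LocalOffset, advance_point
from .indices import NDVI_HEALTHY_THRESHOLD, STANDARD_WAVELENGTHS
from .routeplan import SurveyPolygon

__all__ = [
    "VegRegion",
    "PanelRegion",
    "SceneSpec",
    "SceneTruth",
    "make_scene",
    "make_polygon",
    "default_scene_spec",
]

Rect = tuple[int, int, int, int]  # (row0, row1, col0, col1), half-open


@dataclass(frozen=True)
class VegRegion:
    """A vegetation patch with a prescribed NDVI.

    The red/NIR reflectances are solved from ``ndvi`` and the band-sum
    ``band_sum`` = red + nir: nir = band_sum (1 + ndvi) / 2 and
    red = band_sum (1 - ndvi) / 2, so (nir - red)/(nir + red) equals the
    target exactly before noise.
    """

    rect: Rect
    ndvi: float
    band_sum: float = 0.6

    def __post_init__(self):
        if not -1.0 < self.ndvi < 1.0:
            raise InvalidSpecError(f"NDVI target must be in (-1, 1), got {self.ndvi}")
        if not 0.0 < self.band_sum <= 2.0:
            raise InvalidSpecError(f"band_sum must be in (0, 2], got {self.band_sum}")

    @property
    def nir(self) -> float:
        return self.band_sum * (1.0 + self.ndvi) / 2.0

    @property
    def red(self) -> float:
        return self.band_sum * (1.0 - self.ndvi) / 2.0


@dataclass(frozen=True)
class PanelRegion:
    label: str
    reflectance: float
    rect: Rect


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of a synthetic multispectral scene."""

    shape: tuple[int, int] = (96, 128)
    wavelengths: tuple[float, ...] = STANDARD_WAVELENGTHS
    panels: tuple[PanelRegion, ...] = ()
    veg_regions: tuple[VegRegion, ...] = ()
    background_reflectance: float = 0.18  # dry-soil-like flat spectrum
    gain_true: float | Sequence[float] = 1e-3  # reflectance per DN
    offset_true: float | Sequence[float] = 0.0
    noise_sigma_dn: float = 0.0  # additive gaussian DN noise
    seed: int = 0

    def __post_init__(self):
        rows, cols = self.shape
        rects = [p.rect for p in self.panels] + [v.rect for v in self.veg_regions]
        for r0, r1, c0, c1 in rects:
            if not (0 <= r0 < r1 <= rows and 0 <= c0 < c1 <= cols):
                raise InvalidSpecError(f"region {(r0, r1, c0, c1)} outside {self.shape}")
        for a in range(len(rects)):
            for b in range(a + 1, len(rects)):
                r0, r1, c0, c1 = rects[a]
                s0, s1, d0, d1 = rects[b]
                if r0 < s1 and s0 < r1 and c0 < d1 and d0 < c1:
                    raise InvalidSpecError(f"regions {rects[a]} and {rects[b]} overlap")

    def per_band(self, value) -> np.ndarray:
        arr = np.asarray(value, dtype=float)
        if arr.ndim == 0:
            return np.full(len(self.wavelengths), float(arr))
        if arr.shape != (len(self.wavelengths),):
            raise InvalidSpecError(
                f"{arr.size} values for {len(self.wavelengths)} bands"
            )
        return arr

    def panel_specs(self) -> list[PanelSpec]:
        """The panels as calibration inputs (known reflectance + region)."""
        return [PanelSpec(p.label, p.reflectance, p.rect) for p in self.panels]


@dataclass(frozen=True)
class SceneTruth:
    """Everything needed to verify downstream processing without re-derivation."""

    reflectance: np.ndarray  # rows x cols x bands, noiseless
    gain: np.ndarray  # per band
    offset: np.ndarray
    ndvi: np.ndarray  # rows x cols, from the noiseless reflectance
    healthy_fraction: float  # fraction of pixels with NDVI > threshold
    spec: SceneSpec


# vegetation-like relative spectrum for the non-NDVI bands, scaled per region:
# low blue/red, mid green, red-edge rise, NIR plateau, declining SWIR
_VEG_SHAPE = {
    450: 0.25,
    531: 0.45,
    560: 0.55,
    570: 0.50,
    680: 0.30,
    705: 0.75,
    750: 1.30,
    800: 1.45,
    1240: 1.10,
    2200: 0.40,
}


def make_scene(spec: SceneSpec) -> tuple[HyperCube, SceneTruth]:
    """Build the DN cube and its ground truth from a scene spec.

    The noiseless reflectance field is constructed first (background, then
    vegetation regions with exact-NDVI red/NIR values, then panels), the
    true NDVI and healthy fraction are computed from it, and the DN cube is
    derived through the inverse sensor model plus seeded gaussian noise.
    """
    rows, cols = spec.shape
    wl = np.asarray(spec.wavelengths, dtype=float)
    n_bands = len(wl)
    refl = np.full((rows, cols, n_bands), spec.background_reflectance, dtype=float)

    i_red = int(np.argmin(np.abs(wl - 640.0)))
    i_nir = int(np.argmin(np.abs(wl - 860.0)))
    for region in spec.veg_regions:
        r0, r1, c0, c1 = region.rect
        for b in range(n_bands):
            if b == i_red:
                val = region.red
            elif b == i_nir:
                val = region.nir
            else:
                rel = _VEG_SHAPE.get(wl[b], 0.5)
                val = np.clip(rel * region.band_sum / 2.0, 0.0, 1.0)
            refl[r0:r1, c0:c1, b] = val
    for panel in spec.panels:
        r0, r1, c0, c1 = panel.rect
        refl[r0:r1, c0:c1, :] = panel.reflectance

    red, nir = refl[:, :, i_red], refl[:, :, i_nir]
    with np.errstate(invalid="ignore", divide="ignore"):
        ndvi = (nir - red) / (nir + red)
    healthy = float(np.mean(ndvi > NDVI_HEALTHY_THRESHOLD))

    gain = spec.per_band(spec.gain_true)
    offset = spec.per_band(spec.offset_true)
    if np.any(gain == 0):
        raise InvalidSpecError("sensor gain must be nonzero in every band")
    dn = (refl - offset[None, None, :]) / gain[None, None, :]
    if spec.noise_sigma_dn > 0:
        rng = np.random.default_rng(spec.seed)
        dn = dn + rng.normal(0.0, spec.noise_sigma_dn, size=dn.shape)

    cube = HyperCube(dn, wl, units=UNITS_DN)
    truth = SceneTruth(
        reflectance=refl,
        gain=gain,
        offset=offset,
        ndvi=ndvi,
        healthy_fraction=healthy,
        spec=spec,
    )
    return cube, truth


def default_scene_spec(
    seed: int = 0,
    shape: tuple[int, int] = (96, 128),
    noise_sigma_dn: float = 0.0,
) -> SceneSpec:
    """The stock demo scene: three gray-scale panels along the top edge and
    two vegetation patches (healthy NDVI 0.6, stressed NDVI 0.2) over soil."""
    rows, cols = shape
    ph = max(4, rows // 12)
    pw = max(4, cols // 8)
    gap = pw // 2
    panels = tuple(
        PanelRegion(label, PANEL_PRESETS["grayscale"][label], (2, 2 + ph, c0, c0 + pw))
        for label, c0 in (
            ("black", 2),
            ("gray", 2 + pw + gap),
            ("white", 2 + 2 * (pw + gap)),
        )
    )
    band = rows // 3
    veg = (
        VegRegion((band, 2 * band, 4, cols - 4), ndvi=0.6),
        VegRegion((2 * band + 2, rows - 2, 4, cols - 4), ndvi=0.2),
    )
    return SceneSpec(
        shape=shape,
        panels=panels,
        veg_regions=veg,
        noise_sigma_dn=noise_sigma_dn,
        seed=seed,
    )


def make_polygon(
    kind: str, size_m: float, anchor: GeoPoint = GeoPoint(40.0, -3.7)
) -> SurveyPolygon:
    """Deterministic WGS-84 test polygons around ``anchor`` (the SW corner).

    Kinds: ``rectangle`` (size_m x 1.2 size_m), ``L`` (six-vertex concave
    L-shape), ``concave12`` (12-vertex star-like concave ring).
    """
    if size_m <= 0:
        raise InvalidSpecError(f"size must be positive, got {size_m}")

    def at(dx: float, dy: float) -> GeoPoint:
        return advance_point(anchor, LocalOffset(dx, dy))

    if kind == "rectangle":
        w, h = size_m, 1.2 * size_m
        pts = [at(0, 0), at(w, 0), at(w, h), at(0, h)]
        name = f"rectangle-{size_m:g}m"
    elif kind == "L":
        s = size_m
        pts = [at(0, 0), at(s, 0), at(s, s / 2), at(s / 2, s / 2), at(s / 2, s), at(0, s)]
        name = f"L-{size_m:g}m"
    elif kind == "concave12":
        # alternate outer/inner radii -> guaranteed concave 12-gon
        r_out, r_in = size_m, 0.45 * size_m
        cx = cy = size_m  # keep the ring in the +x/+y quadrant of the anchor
        pts = []
        for k in range(12):
            ang = 2.0 * np.pi * k / 12.0
            r = r_out if k % 2 == 0 else r_in
            pts.append(at(cx + r * np.cos(ang), cy + r * np.sin(ang)))
        name = f"concave12-{size_m:g}m"
    else:
        raise InvalidSpecError(f"unknown polygon kind {kind!r}")
    return SurveyPolygon(tuple(pts), name=name, description=f"synthetic {kind} fixture")
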