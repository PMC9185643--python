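"""Vegetation-index registry, per-pixel computation, classification, histograms.

Each index is a declarative :class:`IndexDefinition`: the spectral bands it
needs (target center wavelength + matching tolerance, by physiological
role), an arithmetic formula over those roles, and any named coefficients
with their literature defaults. Computation is a point-by-point evaluation
of the formula on reflectance bands; pixels where any input is nodata or a
denominator vanishes become nodata in the output map.

The registry holds 18 indices. Only NDVI has a single universal form; the
rest follow their canonical literature definitions:

* NDVI (Rouse et al. 1974), RVI (Jordan 1969), EVI (Huete et al. 2002),
  SAVI (Huete 1988), ARVI (Kaufman & Tanre 1992), GCI (Gitelson et al.
  2003), MCARI (Daughtry et al. 2000), DCNI (Chen et al. 2010), SIPI
  (Penuelas et al. 1995), NBR/DNBR (Key & Benson 2006), NDWI (Gao 1996),
  PRI (Gamon et al. 1992), PSRI (Merzlyak et al. 1999).
* CCI is registered as the spectral chlorophyll/carotenoid index of Gamon
  et al. (2016), (R531 - R640)/(R531 + R640) — the nearest band-arithmetic
  reading of the "citrus color index" label, whose original definition is a
  colorimetric (CIELAB) quantity with no reflectance-band form.
* SSC, TA and PLS are chemometric regression indices (soluble solid
  content, titratable acidity, PLS water-stress score) with no universal
  closed form: they are registered as linear combinations of named bands
  whose coefficients MUST be supplied by the caller (no silent defaults).

All coefficients (EVI's G/C1/C2/L, SAVI's L, ...) are overridable per call,
so a discrepancy with any particular legacy implementation is a
configuration change, not a code change.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile

from .cube_io import UNITS_REFLECTANCE, HyperCube, band_at
from .errors import (
    InvalidInputError,
    InvalidRulesError,
    MissingBandError,
    UnitsError,
    UnknownIndexError,
)

__all__ = [
    "BandRequirement",
    "IndexDefinition",
    "IndexMap",
    "index_registry",
    "lookup",
    "compute_index",
    "compute_dnbr",
    "classify",
    "histogram",
    "save_index_map",
    "NDVI_HEALTHY_THRESHOLD",
]

#: NDVI above this value is classified as healthy vegetation by default.
NDVI_HEALTHY_THRESHOLD = 0.3

#: Standard band set (nm) that resolves every non-parameterized index.
STANDARD_WAVELENGTHS = (450, 531, 560, 570, 640, 680, 705, 750, 800, 860, 1240, 2200)


@dataclass(frozen=True)
class BandRequirement:
    role: str  # identifier the formula refers to
    target_nm: float
    tolerance_nm: float = 15.0


@dataclass(frozen=True)
class IndexDefinition:
    """Declarative vegetation index: bands, formula, coefficients, semantics."""

    name: str
    long_name: str
    required_bands: tuple[BandRequirement, ...]
    formula: str
    coefficients: dict = field(default_factory=dict)  # None value = must be supplied
    range_hint: tuple[float, float] | None = None
    classification: tuple[tuple[str, float, float], ...] | None = None
    two_epoch: bool = False

    @property
    def parameterized(self) -> bool:
        """True if some coefficient has no default and must come from config."""
        return any(v is None for v in self.coefficients.values())


_ND_RANGE = (-1.0, 1.0)
_INF = float("inf")

_NDVI_RULES = (
    ("not_healthy", -_INF, NDVI_HEALTHY_THRESHOLD),
    ("healthy", NDVI_HEALTHY_THRESHOLD, _INF),
)


def _nd(a: str, b: str) -> str:
    return f"({a} - {b}) / ({a} + {b})"


_REGISTRY: tuple[IndexDefinition, ...] = (
    IndexDefinition(
        "NDVI",
        "Normalized Difference Vegetation Index",
        (BandRequirement("nir", 860), BandRequirement("red", 640)),
        _nd("nir", "red"),
        range_hint=_ND_RANGE,
        classification=_NDVI_RULES,
    ),
    IndexDefinition(
        "RVI",
        "Ratio Vegetation Index",
        (BandRequirement("nir", 860), BandRequirement("red", 640)),
        "nir / red",
        range_hint=(0.0, 30.0),
    ),
    IndexDefinition(
        "EVI",
        "Enhanced Vegetation Index",
        (
            BandRequirement("nir", 860),
            BandRequirement("red", 640),
            BandRequirement("blue", 450),
        ),
        "G * (nir - red) / (nir + C1 * red - C2 * blue + L)",
        coefficients={"G": 2.5, "C1": 6.0, "C2": 7.5, "L": 1.0},
        range_hint=_ND_RANGE,
    ),
    IndexDefinition(
        "SSC",
        "Soluble Solid Content (chemometric regression)",
        (
            BandRequirement("re705", 705),
            BandRequirement("re750", 750),
            BandRequirement("nir", 860),
        ),
        "c0 + c1 * re705 + c2 * re750 + c3 * nir",
        coefficients={"c0": None, "c1": None, "c2": None, "c3": None},
    ),
    IndexDefinition(
        "SAVI",
        "Soil Adjusted Vegetation Index",
        (BandRequirement("nir", 860), BandRequirement("red", 640)),
        "(1 + L) * (nir - red) / (nir + red + L)",
        coefficients={"L": 0.5},
        range_hint=_ND_RANGE,
    ),
    IndexDefinition(
        "CCI",
        "Chlorophyll/Carotenoid Index (spectral reading of 'Citrus Color Index')",
        (BandRequirement("g531", 531), BandRequirement("red", 640)),
        _nd("g531", "red"),
        range_hint=_ND_RANGE,
    ),
    IndexDefinition(
        "ARVI",
        "Atmospherically Resistant Vegetation Index",
        (
            BandRequirement("nir", 860),
            BandRequirement("red", 640),
            BandRequirement("blue", 450),
        ),
        "(nir - (red - gamma * (blue - red))) / (nir + (red - gamma * (blue - red)))",
        coefficients={"gamma": 1.0},
        range_hint=_ND_RANGE,
    ),
    IndexDefinition(
        "GCI",
        "Green Chlorophyll Index",
        (BandRequirement("nir", 860), BandRequirement("green", 560)),
        "nir / green - 1",
        range_hint=(-1.0, 15.0),
    ),
    IndexDefinition(
        "MCARI",
        "Modified Chlorophyll Absorption in Reflectance Index",
        (
            BandRequirement("re700", 705),
            BandRequirement("red670", 680),
            BandRequirement("g550", 560),
        ),
        "((re700 - red670) - a * (re700 - g550)) * (re700 / red670)",
        coefficients={"a": 0.2},
        range_hint=(-1.0, 2.0),
    ),
    IndexDefinition(
        "DCNI",
        "Double-peak Canopy Nitrogen Index",
        # the canonical 720 nm red-edge shoulder is represented by the 750 nm
        # band of the standard set (the nearest band above the 700 nm peak)
        (
            BandRequirement("re750", 750, 15.0),
            BandRequirement("re700", 700, 15.0),
            BandRequirement("red670", 670, 15.0),
        ),
        "(re750 - re700) / (re700 - red670) / (re750 - red670 + c)",
        coefficients={"c": 0.03},
        range_hint=(-50.0, 50.0),
    ),
    IndexDefinition(
        "SIPI",
        "Structure Insensitive Pigment Index",
        (
            BandRequirement("nir800", 800),
            BandRequirement("blue445", 445, 15.0),
            BandRequirement("red680", 680),
        ),
        "(nir800 - blue445) / (nir800 - red680)",
        range_hint=(0.0, 2.0),
    ),
    IndexDefinition(
        "NBR",
        "Normalized Burn Ratio (calcination index)",
        (BandRequirement("nir", 860), BandRequirement("swir", 2200, 100.0)),
        _nd("nir", "swir"),
        range_hint=_ND_RANGE,
    ),
    IndexDefinition(
        "DNBR",
        "Difference Normalized Burn Ratio (pre-fire NBR minus post-fire NBR)",
        (BandRequirement("nir", 860), BandRequirement("swir", 2200, 100.0)),
        _nd("nir", "swir"),  # evaluated per epoch; the difference is taken across epochs
        range_hint=(-2.0, 2.0),
        two_epoch=True,
    ),
    IndexDefinition(
        "NDWI",
        "Normalized Difference Water Index",
        (BandRequirement("nir", 860), BandRequirement("swir1240", 1240, 50.0)),
        _nd("nir", "swir1240"),
        range_hint=_ND_RANGE,
    ),
    IndexDefinition(
        "PLS",
        "PLS-Regression Water Stress Index (chemometric regression)",
        (
            BandRequirement("nir", 860),
            BandRequirement("swir1240", 1240, 50.0),
            BandRequirement("swir", 2200, 100.0),
        ),
        "c0 + c1 * nir + c2 * swir1240 + c3 * swir",
        coefficients={"c0": None, "c1": None, "c2": None, "c3": None},
    ),
    IndexDefinition(
        "PRI",
        "Photochemical Reflectance Index",
        (BandRequirement("g531", 531), BandRequirement("g570", 570)),
        _nd("g531", "g570"),
        range_hint=_ND_RANGE,
    ),
    IndexDefinition(
        "PSRI",
        "Plant Senescence Reflectance Index",
        (
            BandRequirement("red678", 678, 15.0),
            BandRequirement("g500", 500, 35.0),
            BandRequirement("re750", 750),
        ),
        "(red678 - g500) / re750",
        range_hint=(-1.0, 1.0),
    ),
    IndexDefinition(
        "TA",
        "Titratable Acidity (chemometric regression)",
        (
            BandRequirement("green", 560),
            BandRequirement("re705", 705),
            BandRequirement("re750", 750),
        ),
        "c0 + c1 * green + c2 * re705 + c3 * re750",
        coefficients={"c0": None, "c1": None, "c2": None, "c3": None},
    ),
)

_BY_NAME = {d.name: d for d in _REGISTRY}


def index_registry() -> list[IndexDefinition]:
    """All 18 registered vegetation-index definitions, in registry order."""
    return list(_REGISTRY)


def lookup(name: str) -> IndexDefinition:
    try:
        return _BY_NAME[name.upper()]
    except KeyError:
        raise UnknownIndexError(
            f"unknown index {name!r}; known: {', '.join(_BY_NAME)}"
        ) from None


@dataclass
class IndexMap:
    """Per-pixel values of one index: 2-D float array with NaN at nodata."""

    values: np.ndarray
    index_name: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InvalidInputError(f"index map must be 2-D, got {self.values.shape}")

    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    @property
    def valid_values(self) -> np.ndarray:
        return self.values[self.valid_mask]

    @property
    def range_hint(self) -> tuple[float, float] | None:
        try:
            return lookup(self.index_name).range_hint
        except UnknownIndexError:
            return None


def _resolve_bands(cube: HyperCube, definition: IndexDefinition) -> dict[str, int]:
    roles = {}
    for req in definition.required_bands:
        try:
            roles[req.role] = band_at(cube, req.target_nm, req.tolerance_nm)
        except MissingBandError as e:
            raise MissingBandError(
                f"index {definition.name} needs a band near {req.target_nm} nm "
                f"({req.role}): {e}"
            ) from None
    return roles


def _evaluate(
    definition: IndexDefinition,
    bands: dict[str, np.ndarray],
    coefficients: dict | None,
) -> np.ndarray:
    coeffs = dict(definition.coefficients)
    if coefficients:
        unknown = set(coefficients) - set(coeffs)
        if unknown and coeffs:
            raise InvalidInputError(
                f"index {definition.name} has no coefficient(s) {sorted(unknown)}"
            )
        coeffs.update(coefficients)
    missing = [k for k, v in coeffs.items() if v is None]
    if missing:
        raise InvalidInputError(
            f"index {definition.name} is a chemometric regression: coefficients "
            f"{missing} must be supplied (no universal defaults exist)"
        )
    ns = {**bands, **{k: float(v) for k, v in coeffs.items()}}
    with np.errstate(divide="ignore", invalid="ignore"):
        result = eval(definition.formula, {"__builtins__": {}}, ns)  # noqa: S307 - registry-internal expressions
    return np.asarray(result, dtype=float)


def compute_index(
    cube: HyperCube, name: str, coefficients: dict | None = None
) -> IndexMap:
    """Evaluate one index per pixel on a reflectance cube.

    Pixels where any input band is nodata, or where the formula produces a
    non-finite value (zero denominator), become NaN in the result.
    """
    definition = lookup(name)
    if definition.two_epoch:
        raise InvalidInputError(
            f"{definition.name} is a two-epoch index; use compute_dnbr(pre, post)"
        )
    if cube.units != UNITS_REFLECTANCE:
        raise UnitsError(
            f"index {definition.name} needs a reflectance cube, got {cube.units!r} "
            "(run the empirical-line calibration first)"
        )
    roles = _resolve_bands(cube, definition)
    bands = {role: cube.band(b).astype(float) for role, b in roles.items()}
    values = _evaluate(definition, bands, coefficients)
    invalid = ~np.isfinite(values)
    if cube.nodata is not None:
        for b in roles.values():
            invalid |= cube.band(b) == cube.nodata
    values = values.copy()
    values[invalid] = np.nan
    return IndexMap(
        values,
        definition.name,
        provenance={
            "bands_used": {role: float(cube.wavelengths[b]) for role, b in roles.items()},
            "coefficients": {
                k: v for k, v in {**definition.coefficients, **(coefficients or {})}.items()
            },
        },
    )


def compute_dnbr(pre: HyperCube, post: HyperCube) -> IndexMap:
    """Two-epoch burn-severity index: NBR(pre-fire) - NBR(post-fire)."""
    nbr_pre = compute_index(pre, "NBR")
    nbr_post = compute_index(post, "NBR")
    if nbr_pre.values.shape != nbr_post.values.shape:
        raise InvalidInputError(
            f"epoch shapes differ: {nbr_pre.values.shape} vs {nbr_post.values.shape}"
        )
    values = nbr_pre.values - nbr_post.values
    return IndexMap(
        values,
        "DNBR",
        provenance={"pre": nbr_pre.provenance, "post": nbr_post.provenance},
    )


# ---------------------------------------------------------------------------
# classification and histograms


def _default_rules(name: str):
    definition = lookup(name)
    if definition.classification is None:
        raise InvalidRulesError(
            f"index {name} has no default classification; pass rules explicitly"
        )
    return definition.classification


def classify(
    imap: IndexMap, rules: list[tuple[str, float, float]] | None = None
) -> tuple[np.ndarray, dict[str, int]]:
    """Label pixels by half-open intervals (lower, upper]: v belongs to a
    class when lower < v <= upper. Returns (label array, counts).

    The NDVI default is {not_healthy: (-inf, 0.3], healthy: (0.3, +inf)} —
    a pixel at exactly the 0.3 threshold is not yet healthy. Valid pixels
    covered by no rule are labelled ``"unclassified"``; counts always sum to
    the non-nodata pixel count. Overlapping intervals are rejected.
    """
    rules = list(rules) if rules is not None else list(_default_rules(imap.index_name))
    if not rules:
        raise InvalidRulesError("empty rule list")
    spans = sorted((lo, hi, label) for label, lo, hi in rules)
    for (lo1, hi1, l1), (lo2, hi2, l2) in zip(spans, spans[1:]):
        if lo2 < hi1:
            raise InvalidRulesError(
                f"rules {l1!r} ({lo1}, {hi1}] and {l2!r} ({lo2}, {hi2}] overlap"
            )
    for label, lo, hi in rules:
        if not lo < hi:
            raise InvalidRulesError(f"rule {label!r}: empty interval ({lo}, {hi}]")

    labels = np.full(imap.values.shape, "", dtype=object)
    valid = imap.valid_mask
    labels[~valid] = None
    v = imap.values
    remaining = valid.copy()
    counts: dict[str, int] = {}
    for label, lo, hi in rules:
        sel = remaining & (v > lo) & (v <= hi)
        labels[sel] = label
        counts[label] = int(sel.sum())
        remaining &= ~sel
    if remaining.any():
        labels[remaining] = "unclassified"
        counts["unclassified"] = int(remaining.sum())
    return labels, counts


def histogram(
    imap: IndexMap, bins: int | np.ndarray = 10
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of valid pixels: (edges, counts), counts summing to the
    valid-pixel count. ``bins`` is a bin count or explicit edge array; with a
    count, normalized-difference indices use the fixed [-1, 1] span, others
    span [min, max] of the data."""
    vals = imap.valid_values
    if vals.size == 0:
        raise InvalidInputError("cannot histogram an all-nodata index map")
    if np.isscalar(bins):
        if int(bins) < 1:
            raise InvalidInputError(f"need >= 1 bin, got {bins}")
        hint = imap.range_hint
        if hint == (-1.0, 1.0):
            rng = hint
        else:
            lo, hi = float(vals.min()), float(vals.max())
            rng = (lo, hi if hi > lo else lo + 1.0)
        counts, edges = np.histogram(vals, bins=int(bins), range=rng)
        # np.histogram drops values outside `range`; fold them into end bins
        counts[0] += int((vals < rng[0]).sum())
        counts[-1] += int((vals > rng[1]).sum())
    else:
        counts, edges = np.histogram(vals, bins=np.asarray(bins, dtype=float))
        counts[0] += int((vals < edges[0]).sum())
        counts[-1] += int((vals > edges[-1]).sum())
    return edges, counts


def save_index_map(imap: IndexMap, path, counts: dict | None = None) -> Path:
    """Persist as a single-band float32 TIFF plus a JSON sidecar holding the
    index name, provenance and (optionally) classification counts."""
    path = Path(path)
    tifffile.imwrite(path, imap.values.astype(np.float32), photometric="minisblack")
    sidecar = path.with_suffix(".json")
    doc = {"index": imap.index_name, "provenance": imap.provenance}
    if counts is not None:
        doc["class_counts"] = counts
    sidecar.write_text(json.dumps(doc, indent=2) + "\n")
    return path
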