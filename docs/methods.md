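# Methods

This note documents the models implemented in agrisurvey, the choices made
where the design was genuinely open, and what the synthetic-data tests do
and do not demonstrate about real imagery.

## Geodesy

All planning geometry runs in a local tangent plane anchored at the
bottom-left corner of the survey polygon's bounding box. Distances between
geographic points use the haversine formula on a sphere of mean radius
R = 6,371,000 m (configurable via `EarthModel`); full ellipsoidal geodesy
is out of scope because survey fields span hundreds of meters, where the
spherical error is far below a pixel.

Metric offsets convert to degree increments by the small-displacement
approximation dlat = (180/πR)·dy. For longitude two modes exist:

* **literal** — dlon = (180/πR)·dx, the equator-only form some legacy
  field tools use;
* **corrected** (default) — the same divided by cos(lat_ref). Without the
  cosine factor, east–west waypoint spacing at latitude 40° is stretched
  by ~31%, compressing the effective image overlap; the literal mode is
  retained only to reproduce legacy missions.

Validity: offsets ≤ 50 km. A property test verifies that a corrected-mode
displacement of ≤ 1 km at |lat| ≤ 60° lands within 0.1% of the requested
metric distance (measured by haversine). The corrected mode refuses
references within 0.1° of the poles.

## Camera model

A nadir pinhole: altitude H_f = GSD·F_l/P_s with P_s the **pixel pitch**
in mm/pixel — the only dimensionally consistent reading (GSD[m/px] ·
mm / (mm/px) = m). Camera configs accept either the pitch directly or
sensor width + resolution. The footprint identity
2·H_f·tan(β/2) = GSD·n_px holds exactly and is enforced to double
precision by a property test over random cameras. Overlap is expressed as
a step fraction O ∈ (0, 1] (1 = adjacent tiles touch, 0.2 = 80% image
overlap); the complementary overlap fraction 1 − O is exposed as a
property to avoid confusion. Lens distortion, gimbal tilt and rolling
shutter are not modeled.

## Tessellation and inclusion rule

Tile centers sit at (fp/2 + i·step) in the local plane, so the first
tile's lower-left corner coincides with the bounding-box reference point;
columns then advance left→right, rows bottom→top. Ray-casting uses the
even–odd crossing count with the strict `y > y_p` comparison, which makes
every edge half-open: lower/left boundary points are inside, upper/right
outside, so each boundary point is classified deterministically and
adjacent tiles never both claim a shared corner. A tile is kept when its
center **or any of its four corners** is inside — keeping the
boundary-straddling tiles a center-only rule would drop.

Numerical choices: local ring coordinates are snapped to 1 µm before
tiling, because the degree↔meter round trip reproduces a nominal 120 m
side as 120.0000000001 m, which would flip the half-open classification
of corners lying exactly on the far boundary. Degenerate (zero-area)
rings, self-intersecting rings and duplicate consecutive vertices are
rejected on construction.

Known limitation: the center-or-corner rule can still miss a thin sliver
of the polygon that crosses a tile edge *between* two corners; on random
convex polygons the uncovered area measures ~0.03% and the property test
asserts ≥ 99.9% coverage rather than 100%.

## Zigzag ordering

Columns are visited left→right; the k-th visited column is swept
bottom→top for even k, top→bottom for odd k (up, right, down, right, …),
starting at the bottom-left-most kept tile. On full rectangular grids
every consecutive pair of tiles differs in exactly one grid coordinate;
on ragged/concave grids this strict property is geometrically
unattainable at some column transitions (a column ending at row 7
followed by a column spanning rows 2–5 must change both coordinates), so
the guarantee there is: column index non-decreasing, and within-column
moves change only the row, monotonically.

## Sub-routes and the range budget

Waypoint headings follow the incoming leg bearing (0° for the first
waypoint). At each waypoint w_i the continuation risk is
r = d(w_i, w_{i+1}) + d(w_{i+1}, home), 2-D ground distance (altitude is
excluded; at survey altitudes it changes the budget by well under 1%). If
r > d_max a go-home waypoint is inserted after w_i. After insertion every
flown leg a→b satisfies d(a,b) + d(b,home) ≤ d_max, provided every
waypoint is individually reachable (2·d(home,w) ≤ d_max — violations
raise an error naming the waypoint). The default d_max derives from a
configurable endurance × cruise speed (20 min × 5 m/s = 6 km), matching
typical small-UAV autonomy of 20–30 min. Note the rule is per-leg, not a
cumulative energy model: it only fires when a single leg is long relative
to the home distance, and a go-home stop is modeled as a battery change
(no explicit "resume" waypoint is inserted; the next survey waypoint
follows directly).

## Mission formats

JSON is the lossless dialect: a versioned document with home, metadata
(GSD, overlap, camera, polygon name) and one record per waypoint
{lat, lon, alt_m, wait_s, heading_deg, kind}. QGC WPL 110 is one
NAV_WAYPOINT row per survey waypoint (hover seconds in param1, yaw in
param4) and a RETURN_TO_LAUNCH row per go-home stop; floats are written
with shortest-round-trip precision so re-importing reproduces waypoints
bit-for-bit. The WPL dialect itself carries no home record or mission
metadata: on import, home is recovered from the first RETURN_TO_LAUNCH
row, else taken as the first waypoint. A `QGC WPL 109` header parses
best-effort with a warning.

## Cube model and I/O

Cubes are rows × cols × bands arrays with strictly increasing per-band
center wavelengths in nm; bands are re-sorted by wavelength on read so
index arithmetic is deterministic. Two formats: multiband TIFF (one band
per page, wavelengths/units/nodata as JSON in the ImageDescription tag)
and the ENVI header pair (.hdr text beside raw BSQ data, wavelengths from
the `wavelength = { … }` field). Band lookup is nearest-wavelength within
a tolerance (default 15 nm, a typical multispectral band half-width; each
index definition can override it), ties breaking toward the lower
wavelength. Processing applies corrections band-at-a-time, so peak memory
stays near two band planes plus the output rather than two full cubes.

## Empirical-line calibration

Per band, ordinary least squares of panel reflectance on mean panel DN
(means exclude nodata pixels). Regressing reflectance **on** DN makes
application a single multiply–add per pixel. With two panels the line
interpolates them exactly; with more, r² is reported per band as a fit
diagnostic. Output reflectance is clipped to [0, 1.5] by default —
preserving specular outliers above 1 while bounding them; the clip is
configurable and can be disabled. Two panel-reflectance presets ship:
`grayscale` (black 10%, gray 30%, white 57%, the three-step calibration
template convention) and `ideal` (0% black, 100% white); neither is
silently preferred — callers choose. Panel regions are user-supplied
rectangles or masks; automatic panel detection is out of scope, as is
atmospheric correction (negligible over UAV path lengths) and
multivariate calibration across correlated bands.

Caveat on the noise model: DN noise perturbs the regressor, so OLS is
formally attenuation-biased; with panel regions of ≥ 64 pixels the bias
is ~2·10⁻⁵ relative — far below the replicate standard error — which is
why the unbiasedness check passes comfortably.

## Vegetation-index registry

Indices are data, not code: each definition declares its bands (role,
target nm, tolerance), a formula string over the roles, and named
coefficients with literature defaults (EVI's G=2.5, C1=6, C2=7.5, L=1;
SAVI's L=0.5; ARVI's γ=1; MCARI's 0.2; DCNI's 0.03). Any coefficient can
be overridden per call, so a discrepancy with some legacy implementation
is a configuration change. The standard band set
{450, 531, 560, 570, 640, 680, 705, 750, 800, 860, 1240, 2200} nm
resolves every non-parameterized index. Three design decisions:

* **SSC, TA, PLS** are chemometric regressions (fruit soluble solids,
  titratable acidity, PLS water-stress score) with no universal closed
  form; they are linear combinations of named bands whose coefficients
  must be supplied explicitly — there are no silent defaults.
* **CCI** is registered as the spectral chlorophyll/carotenoid index
  (R531 − R640)/(R531 + R640); the colorimetric "citrus color index" has
  no reflectance-band form.
* **DCNI**'s canonical 720 nm shoulder is represented by the 750 nm band,
  the nearest standard band above the 700 nm absorption peak.

DNBR is a two-epoch index (pre-fire NBR minus post-fire NBR) and takes
two cubes through `compute_dnbr`; the single-cube path refuses it.
Division by zero and nodata inputs yield nodata pixels, never ±inf, so
downstream histograms stay finite. Classification rules are half-open
intervals (lower, upper]: the NDVI default is healthy strictly above 0.3,
so a pixel at exactly 0.3 is not yet healthy.

## Rendering and reports

Pseudo-color maps are 8-bit RGBA with nodata transparent and a linear
value→color ramp over the index's expected range (e.g. [−1, 1] for
normalized differences); the default palette is red-to-green
(RdYlGn: red = stressed, green = vigorous). Embedded report images are
decimated to ≤ 2048 px per side. All outputs are byte-deterministic:
PNG/PDF software and timestamp metadata are suppressed, so re-running a
report on the same inputs yields identical bytes — reports can be diffed.
A report is 1 + n_indices pages.

## Synthetic scenes: what they show and what they don't

`make_scene` builds a noiseless reflectance field first — soil background
(flat 0.18), vegetation patches whose 640/860 nm values are solved from
the target NDVI t and band sum s (ρ_NIR = s(1+t)/2, ρ_RED = s(1−t)/2,
other bands follow a fixed vegetation-like relative spectrum), gray
panels stamped as flat spectra — then derives DN through the inverse
linear sensor (default gain 10⁻³ reflectance/DN, offset 0, i.e. DN
0–1000) plus optional seeded additive gaussian DN noise. The truth record
carries the exact per-band gain/offset and the exact healthy-pixel
fraction of the constructed NDVI field. Default scene: 96 × 128 px, 12
bands, three panels (10/30/57%), two patches at NDVI 0.6 and 0.2, giving
healthy fraction 0.3125.

Passing tests on these scenes demonstrate algorithmic correctness —
formulas, band routing, classification bookkeeping, exact parameter
recovery under the generating model. They do **not** demonstrate
robustness to what real UAV imagery adds: nonlinear sensor response,
spatially varying illumination, shadows, BRDF effects, misregistration
between bands, or panel non-uniformity. The 1%-noise replicate study
bounds only estimator bias under the stated noise model.

## Problem sizes

Default verification sizes: 10,000 polygon/point pairs for the inclusion
oracle, 200 random cameras, 30 random routes, 200 replicate noisy scenes
at 96 × 128 × 12, chosen to keep the whole suite and the acceptance
script in the tens of seconds while leaving statistical headroom on every
check.
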