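# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of `fluxfoot`. It states no empirical result beyond
what the test suite and `scripts/acceptance.py` themselves compute.

## Footprint model

The half-hourly footprint is the two-dimensional flux-footprint
parameterization (FFP) for surface-layer measurements. With `z_m` the
measurement height **above the zero-plane displacement** (`z_m = H_m − d`,
`d = 0.67 H_c`, `z₀ = 0.1 H_c`), the crosswind-integrated footprint in
scaled coordinates is

    F*(X*) = a (X* − d₀)^b exp(−c / (X* − d₀)),
    a = 1.4524, b = −1.9914, c = 1.4622, d₀ = 0.1359,

mapped to metric distance via `x = X* · z_m (1 − z_m/h)⁻¹ (ln(z_m/z₀) − ψ_M)`,
where `h` is the boundary-layer height and ψ_M the integrated stability
correction (Businger–Dyer form for L < 0, `−5.3 z_m/L` for stable, 0 for
|L| ≥ 5000 m). The crosswind spread is Gaussian with

    σ_y*(X*) = 2.17 · sqrt(1.66 X*² / (1 + 20 X*)),

rescaled by `z_m σ_v / u*` and an empirical stability factor (capped at 1).
The fitted constants are taken verbatim from the parameterization's source
publication, not re-fitted. The streamwise axis points toward the
meteorological wind direction (the bearing the wind blows *from*), so the
source area lies upwind of the tower; this rotation convention is stated
explicitly because conventions differ across codes.

Validity bounds (`z_m/L ≥ −15.5`, `20 z₀ < z_m < 0.8 h`) are enforced both
by the record filter and by the footprint function itself, which refuses
out-of-bounds records naming the violated rule. A record failing several
rules is counted against the first failed rule in the order stability →
lower height bound → upper height bound, making the filter report
deterministic.

Closed-form checks used in the tests: the scaled curve peaks at
`X*_max = d₀ − c/b ≈ 0.870`, and its integral over (d₀, ∞) is
`a c^(b+1) Γ(−b−1) ≈ 1.0015`, which is why a 4 km domain captures ≈ 0.93
of the total weight. The 2-D density maximum sits slightly upwind of the
crosswind-integrated peak because the `1/σ_y(x)` factor decreases with
distance; both lie within one 10 m cell of the analytic values.

## Derived drivers

- **Obukhov length**: `L = −ρ c_p T u*³ / (k g H)` with ρ from the ideal
  gas law at (PA, TA), k = 0.4, g = 9.81 m s⁻², c_p = 1004 J kg⁻¹ K⁻¹,
  R_d = 287.05 J kg⁻¹ K⁻¹. Flux archives rarely ship L directly; this is
  the standard surface-layer estimate from fields they do ship.
- **Boundary-layer height**: measured values pass through. For stable /
  neutral stratification the equilibrium diagnostic
  `h = (L/3.8)(−1 + √(1 + 2.28 u*/(f L)))` is used (f = Coriolis
  parameter); its neutral limit is the classical `h ≈ 0.3 u*/f`. For
  convective conditions no diagnostic equilibrium exists without time
  integration, so a configurable default of 2000 m is used — adequate
  because `h` enters the footprint only through the weak `(1 − z_m/h)`
  factor and the `0.8 h` upper validity bound.
- **σ_v predictor**: a 100-tree random forest (fixed seed, default depth)
  over USTAR, WS, SW_IN, PA, z₀, H_m, H_c, with k-fold cross-validated R²
  and MAE reported from pooled out-of-fold predictions. The tree-ensemble
  family and covariate set are the field's standard choice for this
  gap-filling task; predictions are floored at 10⁻³ m s⁻¹ since σ_v is a
  turbulence magnitude.

## Climatology and contours

Footprints are accumulated cell-wise and renormalized; percentile source
areas are **cell-set quantiles**: the smallest count of highest-weight
cells whose summed weight reaches r/100, with ties broken by (weight
descending, row, column). The marching-squares boundary polyline is
cosmetic; the mask is authoritative. This makes areas exactly
`count × cell²`, guarantees nesting across levels, and is invariant to
positive rescaling of the weights. Fetch is measured to boundary-cell
centres of the 80 % mask; `SI = A/(π fetch²)` is ≈ 1 for a tower-centred
disc and 2/π for a centred square (both verified against constructions
whose level sets are exactly those shapes). Monthly or seasonal
climatologies are the same operation applied to time-sliced inputs; only
the annual climatology drives the downstream stages.

## Overlays

Land-cover recoding follows the fine-classification → IGBP aggregation
table (croplands 10/11/12/20 → 12, needleleaf 70/71/72 → 1, grassland
130 → 10, sparse/bare classes → 16, filled 250 → 17, etc.; 14 distinct
IGBP targets). Footprint cells sample the 30 m raster by nearest
neighbour at their centres; cover percentages are footprint-weighted and
normalized over valid samples, so they sum to 100. Dominant-type ties go
to the smaller IGBP code. Because the 30 m product has no woody-savanna,
savanna or closed-shrubland classes, sites labelled WSA/SAV/CSH are
matched through the aliases WSA→DBF, SAV→ENF, CSH→DBF; mismatching sites
are flagged, never dropped — exclusion is a reporting-layer decision.

## Semivariograms

Inside the 80 % contour, NDVI semivariograms are estimated in four
directions (E-W, NE-SW, N-S, NW-SE) with ±22.5° angular tolerance so the
sectors tile the plane (each sector owns the half-open interval
[centre − 22.5°, centre + 22.5°)). Lag bins are one NDVI cell (10 m);
the default maximum lag is half the mask's bounding-box diagonal. Two
estimator modes exist: the classical unweighted estimator (exactly
`Σ(z_α − z_β)²/(2N(h))`, verified against brute-force pair enumeration),
and a footprint-weighted variant with pair weight φ_α·φ_β normalized per
lag — retained because masking-versus-weighting is a genuinely open
choice in footprint-aware heterogeneity analysis; the pipeline uses the
weighted mode. The omnidirectional estimate is the per-lag arithmetic
mean of the four directions.

The spherical model
`γ(h) = nugget + (sill − nugget)(1.5 h/a − 0.5 (h/a)³)` for `h < a` is
fitted by bounded least squares parameterized as (nugget, partial sill,
range) so `0 ≤ nugget ≤ sill` holds by construction; weights are
√(N(h)/max N); initialisation takes the nugget from the first lag, the
sill from the mean of the last third, and the range from the first lag
reaching 95 % of that sill. A flat empirical variogram fits as pure
nugget (ratio 100 %, range pinned at the first lag) and is flagged
degenerate; a constant field (γ̂ ≡ 0) reports nugget = sill = 0 with
ratio 0. The nugget/sill ratio is reported in **percent** throughout,
matching the classification bands.

## Sensor location bias and rating

`NDVI_fp` renormalizes the climatology weights over the 80 % mask;
`NDVI_target` is the **unweighted** mean over the target cells (the 80 %
contour, or tower-centred squares of side 30·(2i−1) m, i = 1..50, by
cell-centre membership — deterministic and resolution-stable). SLB is the
relative difference and is undefined (flagged, not fabricated) when the
target mean is zero. The three indicators are banded as: dominant cover
< 50 → 3, 50–80 → 2, > 80 → 1; nugget/sill < 25 → 1, 25–75 → 2, > 75 → 3;
|SLB| < 0.05 → 1, 0.05–0.1 → 2, > 0.1 → 3. Band edges belong to the
middle band, a convention fixed here because interval notation alone
leaves endpoints ambiguous.

## Synthetic scenes

The generator supplies the statistical structure the pipeline assumes,
not radiative-transfer realism. Defaults describe a moderately
heterogeneous grassland tower and are fixed once:

- ±1980 m window (≈ ±0.02° of latitude, chosen so both the 30 m
  land-cover and 10 m NDVI cells divide the extent evenly), 8000
  half-hours (about half a year of accepted intervals).
- Wind rose: eight sectors with a westerly preference (25 % at 270°);
  12° jitter within a sector.
- Stability mix 0.5/0.3/0.2 unstable/neutral/stable; |L| is drawn
  log-uniformly in 10–500 m for non-neutral regimes and 2000–4900 m for
  neutral, and the sensible heat flux is back-computed from L so the
  drivers are mutually consistent.
- NDVI: a Gaussian random field with spherical covariance — nugget
  2·10⁻⁴, sill 1·10⁻³, range 240 m, mean 0.45 — synthesised by circulant
  (FFT) embedding on a doubled torus. The embedding is exact up to
  truncation of negative eigenvalues, which is why simulation-recovery
  tests carry 15–25 % tolerances rather than machine precision. The iid
  nugget component is added separately.
- σ_v training: a documented smooth generating function (affine in u*
  and WS with a mild interaction plus small covariate terms) plus
  Gaussian noise whose SD is set so the attainable R²
  (= signal variance / total variance) equals 0.78, a realistic
  cross-site skill level; the attainable value is computed analytically
  from the generator, making the predictor's CV skill checkable without
  circularity.

What passing tests on these scenes does *not* show: robustness to sensor
noise and gap structure in real half-hourly archives, to geolocation and
classification error in real land-cover products, to cloud contamination
beyond a scene-level flag, or to seasonal NDVI dynamics (a single annual
composite is used by design).

## Problem sizes and numerics

Default grids are 10 m cells over ±1980–2000 m (≈ 400² nodes); one
half-hourly footprint evaluates in milliseconds, and the shipped
configurations (8000 half-hours; 400² NDVI fields; 12 000-row σ_v
training tables) keep the full test suite and the acceptance script in
the minutes range on a single CPU. Variogram recovery uses a 240 m range
against a 4 km field so dozens of correlation lengths are sampled.
Contour-area accuracy against the Gaussian closed form is ≈ 0.3 % at
cell = σ/15 (3 % tolerance asserted at cell ≤ σ/10). All randomness flows
through per-call `numpy` generators seeded from the configuration; there
is no global random state, and identical seeds reproduce byte-identical
output tables.

## Known limitations

- The footprint is a parameterization of surface-layer dispersion: no
  along-wind advection correction, no Lagrangian stochastic transport,
  and validity bounds exclude strongly convective very-low-measurement
  configurations by design.
- Tower-relative metric grids stand in for projected rasters; for the
  ±0.02° windows involved the planar approximation error is negligible,
  but no geographic CRS handling is provided.
- The convective boundary-layer default (2000 m) is a constant, not a
  diagnosed height.
- Footprint-versus-raster co-registration is nearest-neighbour at cell
  centres; no area-weighted resampling.
- The σ_v predictor is only as good as its training distribution; the
  synthetic table spans broad multi-site ranges but real-site transfer
  error is not represented.
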