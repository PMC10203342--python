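# Methods

## Problem and model

`greenheat` quantifies how many person·days of extreme surface heat an
urban population experiences, explains the spatial pattern of heat
exceedances from surface properties, and asks how much greening — and
where — would reduce that exposure.

A city is a planar grid of 1 km × 1 km cells. For each cell the package
tracks resident population, mean NDVI, the distance to the nearest water
cell `D_w` and its normalized inverse-square transform
`d_w = (1/D_w²) / max(1/D_w²)`, and the mean number of warm-season days
(`Y_d`) and nights (`Y_n`) on which land-surface temperature (LST) exceeds
the city's heat threshold.

**Exposure.** The day (night) threshold is the q-th percentile — default
q = 90 — of the pooled distribution of all daytime (nighttime) LST values
over all pixels and all dates of a reference period. Exceedance is strict
(`LST > t`), counted over the three warmest months of each year and
averaged over years. Exposure multiplies counts by population:
`TE_D = Y_d · pop`, `TE_N = Y_n · pop`, `TE_T = (TE_D + TE_N)/2`, in
person·days per season; per-capita exposure divides the city total by the
city population. SUHI is the urban-core mean LST minus the buffer-ring
mean LST.

**Spatial lag model.** Exceedance counts are spatially autocorrelated
beyond what NDVI and `d_w` explain, so counts are modelled as

    y = ρ W y + X β + ε,    ε ~ N(0, σ² I)

with `X = [1, NDVI, d_w]` and W a row-standardized 8-nearest-neighbour
weights matrix on pixel centroids (equal weights 1/8; Euclidean distance;
equidistant candidates broken by ascending pixel id so results are
platform-independent). Estimation is maximum likelihood with ρ
concentrated out: for candidate ρ, β(ρ) and σ²(ρ) come from OLS of
`(I − ρW) y` on X, and

    L(ρ) = −(n/2)[ln 2π + 1] − (n/2) ln σ²(ρ) + ln|I − ρW|

is maximized by bounded scalar search on [−0.99, 0.99] (a boundary hit is
flagged as non-convergence). The log-determinant uses a one-off eigenvalue
decomposition of W for n ≤ 2000 and sparse LU above that; no dense n×n
matrix is formed for large problems (dense algebra is reserved for test
oracles). A spatial two-stage least-squares fit (instruments
`[X, WX, W²X]`) is available as a robustness alternative. Prediction is
the reduced form `ŷ = (I − ρW)⁻¹ X β`, solved sparsely and clipped to
[0, season length] for exposure use; the nonnegative entries of the
spatial multiplier make predicted exposure strictly decreasing in any
pixel's NDVI whenever β_NDVI < 0 and 0 ≤ ρ < 1.

**Cross-validation.** k-fold CV (default 5) shuffles pixels by seed. Each
fold fits on the training pixels with W restricted to the training
subgraph (rows re-standardized); held-out pixels are predicted by the
reduced form on the full graph with the training-fold coefficients, so
held-out outcomes never enter a prediction. The arithmetic mean of the
per-fold coefficient estimates is what the scenario engine consumes.
Training-subgraph fitting is mildly misspecified relative to the full
graph (a training pixel loses its held-out neighbours), which is why even
noiseless data give test R² slightly below 1.

**Scenarios.** Scenario "uniform" raises NDVI by δ at every land pixel
with observed NDVI below the 0.85 cap, clipping at the cap; pixels at or
above the cap, water pixels, population and `d_w` are never touched.
Scenario "targeted" applies the increment only on the minimal set of
highest-population pixels holding 80% of residents (ties by pixel id) and
sizes it by bisection on [0, cap] so the relative exposure change
`ΔTE_T(%) = 100(TE¹−TE⁰)/TE⁰` matches the uniform scenario's; since
TE¹(δ) is monotone non-increasing, the root is unique up to cap-saturated
flat stretches and the smallest root is returned (tolerance 1e−6 on δ,
which lands the achieved ΔTE within 1e−4 percentage points in practice).
An unreachable target returns an explicit infeasibility record with the
best achievable change rather than raising. The greening-efficiency
statistic is `100 (NDVI₈₀ − NDVI_all)/NDVI_all` on post-intervention
city-wide NDVI sums — negative when targeting commits less total
greenness; summaries also report its magnitude as "savings". The baseline
TE⁰ is the model-predicted exposure on observed features (not observed
counts), so ΔTE isolates the counterfactual from residual offsets and the
two scenarios stay internally comparable.

## Synthetic cities

The generator emulates the statistical structure the analysis assumes, not
urban physics:

* **NDVI**: Gaussian white noise smoothed with a Gaussian kernel
  (default length scale 5 km) and affinely rescaled to `ndvi_range`
  (default [0.1, 0.8]); only smoothness and seedability matter, not the
  exact covariance.
* **Population**: monocentric exponential surface (e-folding 8 km) scaled
  to `population_total` (default 10⁶) and integerized by largest-remainder
  rounding, so the total is conserved to the person; water is uninhabited.
* **Water**: an edge strip or a circular blob; `D_w` via the exact
  Euclidean distance transform, `d_w` as above. With no water the feature
  is flagged excluded rather than imputed.
* **Counts**: drawn directly from the spatial lag process over land
  pixels — `(I − ρW) y = Xβ + ε` solved sparsely — with day coefficients
  (10, −4.7, −1.2) and night (10, −2.7, −0.6) in days per unit feature
  (the fold-averaged day/night coefficient pairs of the reference
  analysis; the intercept is a repository choice), ρ = 0.5 and σ = 0.5
  days (repository defaults; the reference analysis prints neither), then
  clipped to [0, 92]. Clipping is counted and a warning raised above 5%,
  since heavy clipping biases recovery experiments; under the default
  configuration no clipping occurs.
* **Daily LST series** (optional): back-filled so the exposure module
  reproduces the DGP counts. Below-threshold observations are a
  per-channel constant (30 °C day, 15 °C night) and exceedance days sit
  ≥ 6 °C above it; because exceedances stay far below 10% of all
  observations on full 365-day years, the pooled 90th percentile lands
  exactly on the constant and strict counting returns the per-year
  integer allocation, whose mean matches the DGP count to within
  0.5 + 1/(2·n_years) days. The constant below-threshold level is an
  exactness device, not a climate model.

One root seed feeds named substreams (NDVI field, day noise, night noise,
LST back-fill), making every output bit-reproducible.

What passing tests on these cities do **not** show: realism of urban LST
dynamics, NDVI–temperature physics, demographic detail, or threshold
behaviour under missing-data patterns of real satellite series. They do
show that the estimator, the exposure accounting and the scenario solver
are correct for the data-generating process the analysis postulates.

## Numerical choices

* Percentile convention: linear interpolation between order statistics
  (`numpy.percentile` default), pinned by tests.
* Ties at the threshold count as non-exceedance (strict `>`).
* Distance is centroid-to-centroid Euclidean; no geodesic correction at
  city scale.
* `d_w` on water pixels: the inverse square diverges at `D_w = 0`, so
  water cells take the maximum *land* raw value before normalization —
  preserving "closest to water = largest d_w" without infinities.
  Normalization is per city.
* ρ search: `scipy.optimize.minimize_scalar(method="bounded")`,
  xatol 1e−8, interval clipped strictly inside (1/λ_min, 1) when
  eigenvalues are available.
* Missing NDVI pixels are excluded from fitting (count reported via a
  warning), never imputed.
* Bisection in the targeted solver returns the smallest root; pixels
  saturated at the cap stay saturated as δ grows.

## Study sizes

Recovery experiments use 40×40 cities (1560 land pixels) with 25 seeds,
where the seed-mean of each coefficient estimate carries a standard error
of roughly 0.02–0.07 days — comfortably inside the ±0.15 acceptance band.
Oracle-equivalence checks run at n ≤ 100 against dense grid searches and
exhaustive neighbour scans; the end-to-end pipeline check runs one 40×40
city. These sizes were chosen so the whole suite completes in about a
minute while keeping every statistical check well-powered.

## Known limitations

* The ΔTE-versus-δ response is linear only while the 0.85 cap rarely
  binds. Under the default NDVI range [0.1, 0.8] roughly a third of pixels
  saturate at large δ and the response turns concave (line-fit R² ≈ 0.95);
  with moderate greenness (NDVI ≤ 0.5, headroom for every δ ≤ 0.5) the
  linearity of the underlying model shows cleanly (R² > 0.99). The
  linearity checks therefore use the moderate-greenness regime, which is
  also where real cities sit.
* CV predicts held-out pixels through the full-graph reduced form with
  training coefficients; alternatives that condition on observed
  neighbouring outcomes would score higher but leak held-out information.
* The savings statistic compares NDVI *sums*; it says nothing about
  spatial equity or feasibility of the increments, which are out of scope.
* Thresholds and counting periods are independent configuration values;
  no claim is made about which multi-year window is "correct".
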