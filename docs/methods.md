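# Methods

## Scope and design

`ecoserv` evaluates five ecosystem services on categorical land-use rasters,
accounts for land-use change between epochs, and attributes regional service
variation to land-use composition.  Everything spatial is a plain row-major
numpy grid with cell (0,0) at the north-west corner; areas come from
`cell_size_km²`, never from projection math, because the synthetic data have
no real CRS.  The library under `src/ecoserv/` carries all computation; the
numbered scripts under `analysis/` are thin narrative drivers.

## Service models

**Carbon.**  Purely table-driven: total density per class is the sum of the
four pools (aboveground, belowground, soil organic, dead matter, t/hm²),
and a cell's stock is density × 100 hm²/km² × cell area.  Because no spatial
interaction exists, a tabular closed form (Σ class area × density) runs
alongside the raster path; the two are tested for agreement to 1e-9
relative and the tabular path serves the totals.

**Water yield.**  The printed form of the yield equation in our source
tables is dimensionally inconsistent (an additive "1 +" against a depth);
we implement the standard annual Budyko–Fu formulation used by InVEST:
Y = (1 − AET/P)·P with AET/P = 1 + φ − (1 + φ^ω)^{1/ω}, φ = PET/P,
ω = Z·AWC/P + 1.25.  Z (seasonality) defaults to 5.0 — the conventional
mid-range value, configurable because no source value exists.  PET is
Kc(class)·ET₀; AWC is PAWC × rooting depth, with no root-restricting-layer
raster (rooting depth alone bounds AWC).  Numerics: for φ > 1 the curve is
evaluated as φ·(1 + φ^{−ω})^{1/ω} so that φ^ω never overflows and the
energy-limited limit AET → P is exact; cells with P = 0 return AET = 0; the
AET/P ratio is clamped to [0, 1], making the water balance Y + AET = P and
the bounds 0 ≤ Y, AET ≤ P cell-exact.

**Soil loss.**  USLE A = R·K·LS·C·P per cell, totals in 10⁴ t reading the
rate as t/hm².  Erosivity uses the monthly power-sum formula
R = 1.2157·10^{−0.0818}·Σ (Pᵢ²/P)^{1.5}; months with Pᵢ = 0 contribute 0 and
an all-dry year gives R = 0 (convention, not an error).  R's printed unit
string in the source is garbled, so R is treated as an opaque consistent
unit and only products and ratios are asserted.  LS is consumed as an input
raster; a slope-based helper (McCool S relation with a fixed-length L term)
exists for convenience but the pipeline does not require it.  The
run-together cover/practice digits of the source attribute table were
resolved as paddy C 0.412/P 0.2, dry C 0.412/P 0.6, urban C 0.99/P 1,
unused C 0.85/P 1 (root depth 5000 mm, Kc 0.75 — the only clean split of
that row); all ship as overridable CSV fixtures.

**Habitat quality.**  Q = H_j·[1 − D^z/(D^z + k^z)] with both D and k
raised to z (z = 2.5, the InVEST default; the source calls z only a
normalization constant).  Degradation is a weighted sum across four threat
classes of distance-decayed influence × class sensitivity.  Influence per
threat uses the nearest source cell (max-combine) via a Euclidean distance
transform — under any monotone decay the nearest source dominates, and this
avoids unbounded stacking on dense threat maps; a sum-over-cells mode
exists for sensitivity analysis.  Decay is linear (1 − d/d_max) by default,
exponential (e^{−2.99 d/d_max}) selectable per threat.  k defaults to half
the realized maximum degradation, recomputed per run as the stated rule
requires; an explicit override enables cross-run comparability (used in the
monotonicity tests).  Zero degradation everywhere makes the k rule
degenerate; Q = H_j is returned with a warning.  The accessibility modifier
of the full InVEST formulation is fixed at 1 (no protected-area layer).

**Provisioning value.**  Equivalent-factor valuation restricted to the two
provisioning services analyzed (food, raw material), coefficients in
Yuan/hm² = dimensionless equivalent × 1,505.8 Yuan/hm².  The combined
coefficient is computed as the sum of the two components rather than read
from the source's combined row, which disagrees with its own components by
±1 Yuan for paddy and forest (rounding); the printed row ships as an
alternative column.  A region of pure dry land values at
1882 Yuan/hm² × 100 hm²/km² = 18.82 × 10⁴ Yuan/km², which doubles as a
cross-check against the published food-supply regression intercept.

## Land-use accounting

Transfer matrices are oriented rows = earlier year, columns = later year,
so column sums reproduce the later year's class areas.  Cells nodata in
either year are dropped from the matrix and both marginals (symmetric-mask
rule), keeping total area conserved.  Percent change is undefined (NaN)
where the base-year value is zero.  Full precision is kept internally;
rounding (2 decimals for areas, integer percent for services) is applied
only at display.  In the source transfer table the interior cells do not
all reconcile with the marginals (transcription loss in one row), so the
marginals and change rows are shipped as the authoritative fixture and the
interior is not used.

## Synthetic landscape generator

The generator defines the study conditions; its defaults are fixed, not
tuning knobs.

* **Land use**: one Gaussian-smoothed noise field per class (smoothing
  radius 4 cells); classes claim their target cell counts greedily from
  their own fields, rarest class first, giving autocorrelated patches
  (Moran's I of each class indicator ≫ 0 on the rook lattice) with realized
  proportions exact up to integer rounding.  Default proportions are the
  seven-class base-year shares of the study region (dry 0.501, paddy 0.197,
  urban/rural 0.117, forest 0.091, water 0.049, grassland 0.042, unused
  0.003).
* **Change**: per-decade rules (fraction of the source class converted,
  drawn preferentially adjacent to existing target patches) reproduce the
  dominant observed dynamic — urban expansion onto cropland, grassland loss
  to dry land, modest water expansion, near-disappearance of unused land,
  near-stable forest.
* **Climate**: annual precipitation is a deterministic linear south-to-north
  gradient (default 2 mm/row) centred so the domain mean is exactly
  992.9 mm, the region's long-term mean; monthly values split the annual
  total by a monsoonal profile (June–September > 50%), so the erosivity
  formula sees realistic monthly concentration.  Epoch-specific means
  (990/970/960/1107 mm) reproduce the observed dip-then-rise.  PET runs
  weakly opposite to the gradient around 1000 mm.
* **Soil**: lognormal smoothed K (≈0.03) and LS (≈1.5) fields, clipped PAWC
  around 0.12 — magnitudes typical of regional USLE/Budyko inputs.
* **Regions**: nearest-seed tessellation from 29 uniformly drawn seed
  cells; Voronoi cells on the lattice are contiguous and exhaustive by
  construction.
* All randomness flows from explicit integer seeds (`SeedSequence`-spawned
  per epoch); every generator is a pure function of (spec, seed).

What the generator does *not* emulate: real geography (mountain belts,
river networks, coastlines), within-class heterogeneity of carbon density
or coefficients, inter-annual weather variability beyond one representative
year per epoch, and any correlation between soil fields and land use.
Consequently, passing tests demonstrate correctness of the accounting and
the recovery machinery under the planted structure — not that the absolute
synthetic totals match any real region.  In particular the synthetic
cross-service correlation structure differs from the published one where it
is climate-driven (e.g. water yield is highest on low-Kc urban cells here,
so the water–food synergy of the real region is not reproduced).

## Statistics layer

The panel has one row per (region, year): extensive totals (carbon 10⁸ t,
water 10⁸ m³, erosion 10⁴ t, value 10⁸ Yuan) and per-unit-area parallels
(t/hm², mm, t/km², 10⁴ Yuan/km²); habitat quality is an intensive mean.
Correlations are cross-sectional per year across regions (with four time
points, temporal correlation is deliberately not offered); stars follow the
two-sided t test at 0.05/0.01/0.001, raw by default with an optional
Benjamini–Hochberg flag.

Hierarchical partitioning computes each predictor's independent
contribution as its Shapley value with OLS R² as the characteristic
function, via the closed-form subset weighting over all 2^k − 1 subset fits
(k capped at 12); the exhaustive order-averaging enumeration serves as an
independent oracle in the tests (k ≤ 4, equality to 1e-10).  Σ I_j equals
the full-model R² identically; negative I_j under suppression are reported,
not clipped, and % shares normalize by Σ I.  The seven proportions sum to
one, so the full design is rank-deficient with an intercept; R² comes from
the least-norm fit, whose fitted values are unique.

Stepwise selection is bidirectional on p-values (add the most significant
candidate below α_in = 0.05, then drop any included predictor above
α_out = 0.10, until stable), matching per-equation-significance reporting
conventions; an AIC criterion was considered and rejected for that reason.
Candidates that would make the design rank-deficient are skipped, so one of
a duplicated pair enters; entry stops once the fit is numerically perfect
(R² ≥ 1 − 1e-10), where residual p-values are floating-point noise.  A
known property of this rule: under a global null with k independent
candidates, the intercept-only model survives with probability (1 − α_in)^k
— about 0.70 for k = 7 — because entry tests the minimum of k p-values.
The test suite asserts this true rate.

## Problem sizes and defaults

Analyses and the acceptance script run on a 200×200 grid (1-km cells), four
epochs, 29 regions — large enough for stable regional statistics while the
full pipeline completes in seconds.  Stepwise/HP defaults: α_in 0.05,
α_out 0.10, per-year HP shares averaged over years (pooled mode available).
The null-rate simulation uses 500 replicates at n = 29 with 7 predictors.

## Known limitations

* ASCII-grid I/O only; no GeoTIFF/CRS support.
* The sum-over-cells threat-influence mode is O(cells × sources) and meant
  for small sensitivity studies only.
* Erosivity units are consistent but opaque; absolute erosion tonnage is
  comparable within a configuration, not across erosivity formulas.
* Habitat class "totals" (sums of cell Q) are emitted for completeness but
  have no physical unit; regional means are the primary statistic.
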