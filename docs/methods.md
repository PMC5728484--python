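# Methods

## The model

pheasim evaluates a fixed log-linear species-habitat regression over a
simulated landscape; nothing is estimated at run time. At pixel *p* the
relative habitat suitability is

    suitability_p = exp(η_p)
    η_p = β₀ + α_R R_p + α_C C_p
          + α_RC RC_p + α_RC2 RC_p² + α_RC3 RC_p³
          + α_G G_p + α_G2 G_p² + α_G3 G_p³
          + α_T T_p + α_W W_p

where the covariates are the un-centred, un-standardised proportions of
rangeland (R), CRP grassland (C), row crop (RC), small grain (G), trees
(T) and wetland (W) within a circular window around *p*. Row crop and
small grain enter as cubic polynomials of the *same* focal value
(pheasant abundance peaks at intermediate crop cover); the other four
enter linearly. The residual class `other` is carried on rasters but
never enters the model. Detection probability is assumed constant and
elevation is excluded, so exp(η) is a relative abundance-scale index:
comparable across pixels and scenarios, not an absolute density.

**Coefficients.** The intercept defaults to β₀ = 3.07 (log scale). The
ten slopes are *not* published together with that intercept, so pheasim
refuses to pretend otherwise: they ship as a required configuration file
whose bundled default (`data/default_coefficients.yaml`) is explicitly a
placeholder with field-plausible signs (trees negative; CRP, rangeland,
wetland positive; hump-shaped crop cubics). Every suitability number
produced with the placeholders is therefore illustrative of the
machinery, not a statement about pheasants. Supply fitted values via
`CoefficientSet.from_yaml` or the `coefficients:` key of a run config.

## Landscape simulation

A township is a 9324 ha block. At the 100 m pixel size implied by the
10 px = 1 km window equivalence, one pixel is 1 ha; the default core is
**84 × 111 pixels** — exactly 9324 pixels — because 9324 has no integral
square root and an 84 × 111 rectangle is the factorisation closest to
square. A **50-pixel buffer** (configurable) surrounds the core so that
every focal window centred on a core pixel lies fully on data; no edge
correction is therefore needed, and none is applied.

Pixel counts per class are obtained by **largest-remainder (Hamilton)
apportionment** over the full core-plus-buffer grid: floor each exact
quota, then hand the leftover pixels to the largest fractional
remainders, ties broken by the fixed class order (crp, row_crop,
small_grain, rangeland, trees, wetland, other). Counts are exact to
within one pixel of each quota and conserve the total exactly. Whether
to round or apportion is an implementation choice; apportionment was
chosen for exact conservation and determinism.

Placement is a seeded uniform random permutation (numpy Generator,
PCG64) of the repeated class codes over the whole grid — the buffer is
drawn from the same assignment as the core, so windows reaching into it
see no compositional bias. The landscape is deliberately spatially
neutral: it stands for the average composition of a region, not a map
of any real place. Autocorrelated or patch-structured landscapes are an
extension point, not a feature.

## Focal statistics

Window membership is centre-to-centre Euclidean distance ≤ radius,
boundary included; a radius-10 window covers exactly 317 cells and
radius 50 covers 7845. Two radii are standard: 10 px (1 km) and 50 px
(5 km). **Which covariate takes which radius is an assumption**, shipped
as an overridable default (row_crop, small_grain, rangeland → 50 px;
crp, trees, wetland → 10 px — matrix cover at the broad scale, patchier
cover at the fine scale); the true covariate↔scale mapping of the source
regression is configuration, not asserted fact.

Counts are accumulated in int64 by decomposing the circular window into
its horizontal runs (for row offset dy the members span
|dx| ≤ ⌊√(r²−dy²)⌋, a difference of two row cumulative sums) and divided
by the window cell count once at the end, so the implementation agrees
bit-for-bit with a brute-force recount — a property the test suite
checks on 20 random grids against an independent double-loop oracle.

## Categorisation

The suitability surface is summarised into *k* ordinal categories.
Neither the number nor the breakpoints of the original display
categories are published, so the default is **k = 5 equal-count
(quantile) categories of the current surface** — scale-free, hence
insensitive to the placeholder slopes. Cuts sit at the order statistics
at ranks round(i·n/k); ties always share a category, and explicit break
values can be passed instead. On a surface of distinct values the five
default categories are equal in size to within one pixel.

## Economics

All formulas work in acres (1 ha = 2.47105381 acres) over a horizon
defaulting to **10 years**, the length of a typical CRP contract.

* Annual gross income = row-crop acres × yield (bu/acre) × price ($/bu)
  + small-grain acres × yield × price + rangeland acres × pasture
  rental ($/acre/yr). CRP, trees, wetland and `other` earn landowners
  nothing here; the CRP rental is charged in the contract term below and
  is never double-counted as income.
* Agricultural incentive cost = (baseline income − scenario income) ×
  horizon + CRP rental × ΔCRP⁺ acres × horizon, where ΔCRP⁺ =
  max(0, scenario − baseline) CRP acres: **new contracts only**, baseline
  contracts being treated as sunk. Whether existing contracts should
  also be charged is genuinely ambiguous, so `crp_charge="all"` exposes
  the alternative. The income difference may be negative (the scenario
  is more profitable); it is reported as-is with a sign note, not
  floored.
* Management cost is one-sided by assumption: tree removal at
  **$650/acre** only when tree acres decrease (no cost to plant, no
  revenue from removal); wetland restoration at **$6250/acre** only when
  wetland acres increase (draining costs the manager nothing).
* Total = agricultural + tree + wetland. No discounting, inflation or
  proration; those are out of scope.

## Synthetic county profiles

Real county landcover means and NASS economics are not bundled.
`generate_fixture_profiles` draws compositions from a symmetric
Dirichlet(2) over the seven classes (covering the simplex without
favouring any class, with `other` recomputed exactly as the residual)
and economics uniformly over order-of-magnitude-plausible ranges:
yields 20–200 bu/acre, prices $2–15/bu, rentals $10–250/acre/yr. The
fixtures are schema-faithful and value-arbitrary: they exercise every
code path with realistic magnitudes, so passing tests demonstrate the
machinery — conservation, determinism, formula arithmetic — but say
nothing about any actual county, and the placeholder slopes mean the
suitability magnitudes are likewise illustrative only.

## Run configuration and determinism

A YAML run config names a county (plus a profile CSV) or gives an
explicit composition with inline economics; the scenario is either an
explicit composition or slider-style deltas on the baseline with the
residual `other` re-balancing. CLI flags override file values. Baseline
and scenario rasters use the **same seed**, so an identity scenario
yields identical outputs and any difference is attributable to the
landcover change alone. Changing only the seed changes pixel placement
but not class counts, category-count distributions' expectations, or any
cost figure. The run log records the seed, a SHA-256 hash of the
resolved configuration, and library versions.

Rasters are written as plain single-band TIFFs with a code↔class sidecar
CSV; the grid is a local, non-georeferenced frame because the township
intentionally represents no real place.

## Numerical notes

* Composition validity: proportions in [0, 1], summing to 1 within
  1e-9; `other` is the residual and is recomputed exactly where absent.
* Profile CSVs round-trip exactly (floats written with `repr`, read with
  pandas' round-trip parser).
* Focal arithmetic is exact integer until one final division.
* `exp` overflow (|η| implausibly large, e.g. mis-scaled coefficients)
  raises an error naming the offending pixel and predictor value rather
  than propagating infinities.
* Problem sizes in the test suite are the defaults (84 × 111 core,
  50 px buffer) where the check concerns the standard geometry, and
  miniature grids (20–40 px, buffers 3–10) where the check is
  scale-free, e.g. oracle equivalence and placement uniformity over 500
  seeds.

## Limitations

* Spatially random landscapes only; no patches, edges or
  autocorrelation, so edge-density or patch-size covariates cannot be
  represented.
* Placeholder slopes make absolute suitability values meaningless until
  replaced with fitted coefficients.
* Constant detection probability and no uncertainty propagation:
  predictions use point coefficients; seed-to-seed reruns expose only
  placement variability, not parameter uncertainty.
* Economics ignores discounting, partial contracts and landowner
  behaviour; pasture rental is taken as the landowner income from
  rangeland symmetrically with crop revenue.
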