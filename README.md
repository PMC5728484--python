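# pheasim

A township-scale simulator for ring-necked pheasant (*Phasianus
colchicus*) habitat suitability and land-management economics, for
wildlife managers and landscape ecologists exploring "what if we changed
the landcover?" scenarios on Great Plains agricultural landscapes.

Given the landcover composition of a hypothetical township (the 6×6-mile
public-land-survey block, 9324 ha), pheasim:

1. **simulates** a categorical raster realising that composition — pixels
   assigned to classes in exact proportion (largest-remainder
   apportionment) and placed uniformly at random, plus a 50-pixel buffer
   so moving windows never run off the data;
2. **derives** per-pixel focal proportions of each landcover class within
   circular windows of 10 px (1 km) or 50 px (5 km) radius;
3. **predicts** relative habitat suitability at every core pixel from a
   log-linear species-habitat regression

   suitability_p = exp( β₀ + α_R R_p + α_C C_p
                        + α_RC RC_p + α_RC2 RC_p² + α_RC3 RC_p³
                        + α_G G_p + α_G2 G_p² + α_G3 G_p³
                        + α_T T_p + α_W W_p )

   where R, C, RC, G, T, W are the focal proportions of rangeland, CRP
   grassland, row crop, small grain, trees and wetland (row crop and
   small grain enter as cubics), β₀ = 3.07, and detection probability is
   assumed constant — so the surface is a relative abundance-scale
   index, not a count;
4. **prices** the 10-year cost of converting a baseline composition into
   a scenario: forgone gross income (crop acres × yield × price,
   rangeland × pasture rental) × 10 years, plus new 10-year CRP
   contracts at the county rental rate, plus one-sided habitat
   management costs (tree removal $650/acre, wetland restoration
   $6250/acre; planting trees and draining wetlands are free by
   assumption).

The slope coefficients of the regression are **not bundled as truth**:
the package ships a clearly labelled placeholder configuration
(`src/pheasim/data/default_coefficients.yaml`) with field-plausible
signs only; supply fitted values for real use. Real county landcover and
NASS economics are likewise replaced by a schema-identical synthetic
fixture generator.

## Worked example

```bash
pheasim fixtures --n-counties 3 --seed 42 --out profiles.csv

cat > scenario.yaml <<'YAML'
county_id: county_001
profiles: profiles.csv
scenario_deltas:
  crp: 0.05       # enroll 5% of the township into CRP
  trees: -0.02    # remove 2% tree cover
seed: 42
YAML

pheasim run --config scenario.yaml --out out/
```

prints

```
Cost of the specified management scenario over 10 years (county county_001)
  Agricultural incentive cost: $1,095,398.42
  Tree removal cost:           $299,521.37
  Wetland restoration cost:    $0.00
  Total cost:                  $1,394,919.80
outputs written to out/
```

The agricultural line is the 10-year gross income forgone plus the new
CRP contracts; tree removal prices the 2% (≈460.8 acres) of tree cover
removed at $650/acre; wetland cover did not increase, so restoration is
$0. `out/` holds landcover and suitability rasters (TIFF) for both the
baseline and scenario landscapes, per-category pixel-count summaries
(CSV; five equal-count suitability categories by default), `cost.json`,
and `run_log.txt` recording the seed and a configuration hash — the same
config and seed reproduce every output byte for byte. In this run the
scenario raises mean relative suitability from 46.2 to 52.5 (placeholder
slopes; the direction reflects their signs, CRP positive and trees
negative, not a fitted magnitude).

Each stage is also exposed alone (`pheasim simulate`, `predict`, `cost`)
and as a library (`pheasim.generate_township`, `compute_stack`,
`predict_surface`, `total_cost`, ...).

## Layout

- `src/pheasim/composition.py` — the seven-class landcover simplex
- `src/pheasim/profiles.py` — county profiles and synthetic fixtures
- `src/pheasim/landscape.py` — quantization and township simulation
- `src/pheasim/focal.py` — circular moving-window focal proportions
- `src/pheasim/suitability.py` — the habitat equation and categorisation
- `src/pheasim/economics.py` — 10-year scenario costing
- `src/pheasim/pipeline.py`, `cli.py` — batch runs and the `pheasim` CLI
- `docs/methods.md` — model, assumptions, numerical choices, limitations
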