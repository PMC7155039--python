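# endolakes

Surface-water analysis for endorheic (closed-basin) watersheds: reconstruct
annual lake and wetland inundated area from multispectral imagery by
constrained spectral mixture analysis, quantify two-period change, and rank
climate and human water-use drivers with random-forest permutation
importance. A seeded synthetic-watershed generator emulates a 35-year annual
scene record so the whole pipeline is testable offline.

## Pipeline stages

| module | what it does |
| --- | --- |
| `endolakes.synth` | synthetic scenes, polygons, truth areas, climate and human-use series for snowmelt / monsoonal regimes |
| `endolakes.endmembers` | NDWI/NDVI percentile masks and static plots → water / wetland-vegetation / upland / alkali-soil endmember spectra |
| `endolakes.unmix` | 6-month seasonal composites; fully constrained least-squares unmixing (fractions ≥ 0, sum to 1) |
| `endolakes.accounting` | polygon rasterization, ≥10 % water-fraction area accounting, max-NDVI irrigated extent, population spline |
| `endolakes.change` | P1 (1984–1999) vs P2 (2000–2018, no 2012) summaries, Wilcoxon rank-sum, OLS trends, change vectors, regional rollups |
| `endolakes.attribution` | regression forests with per-tree OOB permutation VIMP and double-bootstrap subsampling confidence intervals |

## Quick start

```python
import endolakes as el

bundle = el.simulate_series(el.snowmelt_params(seed=1))     # 35-yr record
water, human = el.run_bundle(bundle)                        # full pipeline

summary = el.period_summary(                                # two-period change
    water.query("`class` == 'lake'")["year"],
    water.query("`class` == 'lake'")["area_ha"],
)

table = el.assemble_design(bundle.truth_areas, bundle.climate,
                           bundle.human, "snowmelt", response_class="wetland")
vimp = el.permutation_vimp(el.fit_forest(table, n_trees=5000, seed=1))
```

## CLI

```sh
endolakes simulate  --regime snowmelt --seed 1 --out bundle/
endolakes unmix     --images scenes/ --window snowmelt \
                    --endmembers bundle/endmembers.csv --out fractions_1990.tif
endolakes account   --fractions fractions/ --polygons bundle/polygons.geojson --out series/
endolakes change    --series series/surface_water.csv --out change.csv
endolakes attribute --table design.csv --trees 5000 --subsamples 500 \
                    --alpha 0.05 --seed 1 --out vimp.csv
```

Rasters are written as multi-page TIFF with a JSON sidecar describing band
names, date, and grid placement; polygons as GeoJSON; series as CSV.

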