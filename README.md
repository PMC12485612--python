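# urbwell

Analysis pipeline linking **urbanization gradients** to **stratified
subjective well-being (SWB)** and **street-scene ecology**, exercised
end-to-end on synthetic cohorts with planted effects.

Cities reshape who feels well and where. This package implements, as a
tested and reusable pipeline, an analysis framework for that question:
urban extents are delineated objectively from nighttime-light (NTL)
intensity rasters ("natural cities"), ordered into concentric
urbanization rings U1..UT by the year each area became urban, and
within each ring post-level sentiment scores in [0, 1] are stratified
into well-being levels P1..P8 (the 10th–80th percentiles). Ring-level
street ecology and socioecological covariates then drive an
association battery — correlations, stepwise regression, Geodetector,
and a regression-discontinuity linearity check. Because the original
post, imagery and light data are proprietary, the package ships a
first-class synthetic-data generator whose planted structure every
stage must recover.

## The statistics at the core

* **Head/tail breaks.** For a heavy-tailed intensity raster, iterate:
  take the mean of the current subset, keep the strictly-above-mean
  "head", stop when the head/tail split is balanced (tolerance 0.05) or
  the head empties. The final mean thresholds bright urban components.
* **Expansion rate.** For an annual area series `A_1..A_N`,
  `r = 100/(N-1) · Σ (A_{i+1} − A_i)/A_i` percent per year; geometric
  growth at factor g gives exactly `100·(g−1)`.
* **Well-being strata.** `P_i = percentile(A, i)`, `i = 0.1..0.8`, of
  the score multiset within a ring (linear-interpolation percentiles).
  Inequality is summarized by the per-level SD and Gini
  `G = Σ_{j,k}|x_j − x_k| / (2n²μ)`, and the gap statistic P8 − P1.
* **Street ecological index.** From 19-class segmentation counts over
  N = 4 view angles: GN (vegetation), GY (built structures), OP
  (sky/ground/road), CR (people/vehicles) as sums of per-image pixel
  fractions, and `SE = (GN · OP)/(GY · CR)`.
* **Associations.** Forward/backward stepwise OLS (partial-F entry,
  t-test removal) per city × level with factor-importance counting;
  Geodetector `q = 1 − SSW/SST` over quantile-binned strata with
  permutation significance; regression discontinuity
  `δ = |left(c) − right(c)|` as a linearity check (δ < 0.05 accepted).

## Worked example

```bash
python analysis/01_delineate_gradients.py 1
python analysis/02_stratify_swb.py 1
```

prints, for the three-city synthetic cohort (seed 1):

```
city 0: 15 rings, area 53 -> 1099 cells^2, r = 24.8 %/yr
...
level  slope_pct  planted_slope_pct      p_value
   P1   0.615236           0.607039 1.923308e-09
   P2   0.527412           0.534625 5.687101e-11
   ...
   P8   0.273421           0.262725 6.292673e-08

P8 - P1 disparity change along the gradient: 23.4% decrease (planted: 24.2%)
```

Each city keeps all 15 nested rings and expands at ~25 %/yr. The
estimated level trends (percentage points per gradient step) match the
analytic Beta-quantile slopes planted by the generator: the lowest
stratum P1 rises fastest and the highest P8 slowest, so the well-being
gap narrows outward along the gradient — the estimated 23.4% disparity
decrease recovers the planted 24.2%. `analysis/03_street_ecology.py`
and `analysis/04_associations.py` continue with the street-scene
indices and the association battery (stepwise recovery of the planted
coefficients 0.5/0.3 as 0.51/0.31, RD max δ = 0.012, Geodetector
interaction q up to 0.91).

The same stages are available as a CLI
(`urbwell simulate|delineate|se|swb|assoc|run`) for use on external
rasters and tables.

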