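# rseikit

A raster-analytics toolkit for composite remote-sensing ecological
quality assessment in arid and semi-arid regions, built for ecologists
and remote-sensing analysts who track ecosystem condition from
surface-reflectance archives.

## What it computes

**Component indicators.** From co-registered reflectance bands b1 (red),
b2 (NIR), b4 (green), b6 (SWIR1), b7 (SWIR2) and a thermal DN raster,
the toolkit derives five ecological indicators over non-water land cells
(water is masked first with MNDWI = (b4 − b6)/(b4 + b6)):

- greenness SAVI = (1 + L)(b2 − b1)/(b1 + b2 + L), soil constant L = 0.5
- humidity SWCI = (b6 − b7)/(b6 + b7)
- dryness NDBBI = (1.5 b6 − (b2 + b4)/2)/(1.5 b6 + (b2 + b4)/2)
- heat LST = 0.02·DN − 273.15 (°C)
- salinity CSI = mean of the [0,1]-normalized SI-T = 100·b1/b2,
  NDSI = (b1 − b2)/(b1 + b2), and SI4 = b6/b2

**Composite index (RSEI).** Each indicator is min–max normalized to
[0, 1]; the index is the first principal component of their covariance,
oriented so it increases with greenness, rescaled to [0, 1] and graded
into five classes (bad < 0.2 ≤ poor < 0.4 ≤ moderate < 0.6 ≤ good
< 0.8 ≤ excellent).

**Temporal dynamics.** Change-vector grading of the classified index
(Δ grade −4…4, five change types), FROM–TO transition tables with
areas, per-cell coefficient of variation (five stability levels), and
rescaled-range (R/S) Hurst exponents with four persistence classes.

**Driver attribution (OPGD).** The geographical-detector q-statistic
q = 1 − SSW/SST measures how much a stratified driver explains the
index's spatial variance. For continuous drivers the optimal-parameter
variant scans five discretization methods (equal interval, natural
breaks, quantile, geometric, standard deviation) across 5–10 classes
and keeps the combination maximizing q; interaction detection overlays
two stratifications and classifies the joint q against the marginals.

**Synthetic scenes.** A seeded generator emits multi-epoch band stacks
driven by a smooth latent quality field with embedded water bodies,
monotone trends, and driver rasters constructed to a target q — so
every stage is testable without a satellite archive.

## Worked example

```python
import rseikit as rk

cfg = rk.RunConfig(out_dir="demo", seed=7, opgd_permutations=99,
                   synthetic={"shape": (128, 128), "epochs": 12,
                              "trend": -0.03, "noise_sd": 0.005})
report = rk.run_pipeline(cfg)
epoch0 = report["stages"]["rsei"][0]
print(round(epoch0["pc1_contribution"], 3))      # 0.889
print(report["stages"]["dynamics"]["pairs"][-1]) # full 2001-2023 pair
print(report["stages"]["opgd"]["top_factor"],
      round(report["stages"]["opgd"]["top_q"], 3))
```

prints

```
0.889
{'pair': '2001_2023', 'median_delta': -1.0}
driver_strong 0.938
```

The first principal component carries 89% of the indicator variance, so
the composite index summarizes the five layers well; under the imposed
degradation trend the median cell loses one quality grade over the
12-epoch record; and factor detection correctly ranks the strong
synthetic driver first. All rasters (per-epoch index and class grids,
Δ-grade, CV, Hurst) and tables (PCA loadings, correlations, class
areas, transitions, factor and interaction q) land under `demo/`.

The same workflow runs from the shell:

```bash
rseikit simulate --out-dir scene --epochs 12 --seed 7
rseikit rsei --manifest scene/manifest.yaml --out-dir out
rseikit run-all --out-dir run --seed 7
```

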