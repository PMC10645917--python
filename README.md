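# viseam

Seamless NDVI/EVI time-series reconstruction from satellite surface
reflectance.

Optical vegetation-index (VI) records such as 8-day MODIS NDVI and EVI are
riddled with cloud, snow and sensor dropouts: contaminated composites read
far below (NDVI) or scatter around (EVI) the true canopy signal, and
missing steps are filled with the sentinel value −0.2. `viseam` implements
a learning-based reconstructor for such per-pixel series, together with the
sample-construction procedure needed to train it and the classical
smoothers it is compared against. It is aimed at remote-sensing and
carbon-cycle researchers who need gap-free, contamination-free VI series at
the pixel level.

## Method

**Indices.** NDVI = (NIR − RED)/(NIR + RED) and
EVI = 2.5·(NIR − RED)/(NIR + 6·RED − 7.5·BLUE + 1), computed per 8-day step
(46 steps/year), clipped to [−0.2, 1]; steps with negative reflectance,
solar zenith angle above 85°, or missing bands are set to −0.2.

**High-quality training targets** are built from contaminated VI plus a
co-registered leaf-area-index (LAI) series in four steps:

1. an upper-envelope Savitzky–Golay filter (half-width 12 steps, 2
   iterations that lift points below the fit) flags outliers deviating
   from the smooth fit by more than 0.4 (NDVI) or 0.2 (EVI);
2. the saturating relation VI = c − e^(a·LAI + b) is fitted by least
   squares to the surviving (LAI, VI) pairs and evaluated back onto the
   LAI series; pixels with min LAI > 5 over two years use a sign-bounded
   two-stage refit (saturation special case);
3. an upper-envelope interpolation of the cleaned observations is merged
   with the LAI-fit curve by an element-wise maximum;
4. where the smoothed original drops below 0.2 on snow/ice pixels, genuinely
   low winter values are blended back in with weight
   w = (VI_ori + 0.2)/0.4, and a final SG pass smooths the result.

**Reconstructor.** A three-layer stacked LSTM with 8 hidden units per
layer, a GELU nonlinearity and a per-step linear head maps the raw
(red, NIR, blue) two-year reflectance sequence (92 steps) directly to the
clean VI sequence — no gap pre-filling required. Training minimises MSE
with Adam; the learning rate decays from 1e−4 to 1e−8 along a half cosine;
pixels split 80/10/10 into train/validation/test and the checkpoint with
the lowest validation loss is kept.

**Baselines and metrics.** The upper-envelope SG filter applied directly
to the contaminated series (fill values included, as in standard practice)
and a Whittaker smoother (second-order differences, λ = 2) serve as
references. Reconstructions are scored with RMSE and R² against
good-quality reference steps, the upper-envelope rate (fraction of results
below the observations) and the distance (mean |result − observation|).

Everything is exercised on a seeded synthetic benchmark: double-logistic
phenology truth curves, LAI consistent with the truth through the
exponential relation, reflectance consistent with the observations through
the index formulas, and stratified contamination (tropical long cloud
runs, mid-latitude clouds, boreal snow troughs, a high-LAI saturation
stratum).

## Worked example

```python
from viseam import benchmark
from viseam.evaluate import reports_to_table

result = benchmark.run_benchmark(n_pixels=500, index_kind="NDVI",
                                 cloud_fraction=0.4, seed=1)
print(reports_to_table(result.reports).query("stratum == 'all'"))
```

prints (seed 1, held-out 10% of pixels, all good steps pooled):

```
method index stratum     rmse  r2_standard  env_rate  distance  n_good
  LSTM  NDVI     all 0.069302     0.937255  0.294483  0.138361    4600
    SG  NDVI     all 0.122019     0.805489  0.361379  0.076127    4600
    WT  NDVI     all 0.194386     0.506347  0.572414  0.069857    4600
```

Read: against the clean truth of 50 held-out pixels, the trained LSTM
reconstructs NDVI with RMSE 0.069, well below the SG filter (0.122) and
the Whittaker smoother (0.194), whose moving windows are dragged down by
−0.2 fill values and negatively biased cloud steps. The LSTM also has the
lowest upper-envelope rate (29% of steps below the observations), i.e. its
curve sits closest to the upper envelope of the raw series. The higher
LSTM "distance" is expected: distance measures fidelity to the *raw*
observations, 40% of which are contaminated low — a good reconstruction
departs from them.

The same pipeline is available from the shell:

```sh
viseam simulate --n-pixels 500 --seed 1 --out corpus.csv
viseam build-samples --corpus corpus.csv --out samples.csv
viseam train --corpus corpus.csv --samples samples.csv --seed 1 --out model.npz
viseam compare --n-pixels 500 --seed 1 --out report.tsv
```

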