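# Methods

This note documents the models, parameter choices and numerical decisions
behind `viseam`, and what the synthetic benchmark does and does not show.

## Data model

All series live on an 8-day composite grid, 46 steps per year; the
canonical window is two years (92 steps), long enough to contain a full
growing cycle plus context from the neighbouring year. Invalid VI
observations hold exactly the sentinel −0.2 (the MODIS VI fill
convention); every valid value lies in [−0.2, 1]. Reflectance is accepted
in [−0.01, 1.6] (slightly negative values arise from atmospheric
correction; super-unity values occur over bright targets). A step is
invalidated when any required band is negative or missing **or** the solar
zenith angle exceeds 85°; the conjunction in the originating convention is
ambiguous, so the stricter both-conditions mode is available behind a
flag (`strict_and`).

## Target construction

The builder turns a contaminated VI series plus a gap-free LAI series into
a gap-free "high-quality" target. Parameters and rationale:

- **SG filter**: half-width 12 steps (≈ one quarter year, the
  TIMESAT-style setting), 2 upper-envelope iterations in which points
  below the current fit are replaced by the fitted value before refitting.
  The **polynomial order defaults to 6**: with the window fixed at 25
  steps (~200 days), a quadratic cannot follow green-up/senescence
  transitions at 8-day sampling and distorts even clean series by ~0.08
  RMSE; order 6 brings that to ~0.01 while still suppressing step-scale
  noise. Order 2 remains available for strictly TIMESAT-like behaviour.
  The fit is computed directly as windowed least squares on an abscissa
  scaled to [−1, 1]; this agrees with the exact per-window solution to
  machine precision at all supported orders (convolution-coefficient
  implementations lose ~1e−10 at order 6 to ill-conditioning).
- **Outlier threshold**: absolute deviation from the smooth fit above 0.4
  (NDVI) or 0.2 (EVI) marks a step invalid; equality keeps the point. EVI
  additionally gets a high-side pre-clean at +0.2 above the fit, since its
  contamination is two-sided.
- **LAI–VI fit**: VI = c − e^(a·LAI + b), nonlinear least squares
  (trust-region reflective, analytic Jacobian) initialised from a small
  grid over c with log-linearisation. Parameters are box-bounded
  (|a|, |b| ≤ 20, c ∈ [−0.5, 1.25]): c is the saturating asymptote of a
  vegetation index, and without the cap the direction a→0, c→∞ (the model
  degenerating to a line in LAI) is flat and the solver drifts on weakly
  curved pixels. Because residual sub-threshold contamination biases VI
  low while high values are trustworthy, the fit is repeated on the pairs
  lying above the first curve (`upper_refit`, on by default; a no-op on
  noiseless data). For pixels whose LAI never drops below 5 (evergreen
  saturation), the sign of `a` is additionally bounded; the printed form
  of the relation makes the natural saturating orientation a < 0, so the
  sign used by the special case is configurable and neither convention is
  asserted as uniquely correct.
- **Upper envelope**: a valid step is interpolated (linearly, between its
  flanking envelope points) only when it is a *strict local minimum*
  among valid neighbours; first/last valid steps anchor the ends. This
  removes downward spikes while leaving monotone segments untouched —
  the reading under which a constant, strictly increasing, or smooth
  seasonal series passes through unchanged.
- **Snow blend**: where the SG-filtered original drops below 0.2, the
  synthetic series is blended with the original with weight
  w = (VI_ori + 0.2)/0.4 clamped to [0, 1], so genuinely low winter
  values survive. The blend runs only on pixels that actually carry
  snow/ice-coded quality steps (when QA is available): applying it to any
  pixel with a low smoothed winter would re-inject cloud-biased values
  into the targets of ordinary mid-latitude pixels.
- **Final pass**: a single plain SG smoothing (no envelope iterations, no
  re-flagging) — the envelope machinery exists to reject low outliers,
  which steps 1–3 have already removed; iterating it here would only bias
  troughs upward.
- Targets are clipped to stay strictly above −0.2 so no target step can be
  mistaken for a fill value.

## Reconstructor

Three stacked LSTM layers, 8 hidden units each; per-step head = GELU then
a linear map to one output; inputs are the raw red/NIR/blue reflectance
(invalid steps carry a fill value of 0; an optional binary validity
channel exists but is off by default so the model consumes exactly the
three bands). One model per index kind.

The implementation is self-contained numpy — explicit forward,
backpropagation-through-time and Adam — with the two sequential per-layer
loops JIT-compiled by numba when available (identical results either
way). Gradients are validated against central finite differences in the
test suite.

Training choices:

- **Loss**: mean squared error over all 92 steps (consistent with
  RMSE-based evaluation).
- **Learning rate**: half-cosine decay from 1e−4 to 1e−8 over the run,
  lr(t) = lr_min + (lr_max − lr_min)(1 + cos(πt/T))/2.
- **Epochs/batch**: 300 epochs, batch size 1. With a 400-sequence
  training set and the 1e−4 ceiling, the number of optimiser updates is
  the binding constraint on convergence; fully stochastic updates give
  120k steps per run (~2 minutes on one CPU) where batch 64 would give
  2.4k and underfit badly. Both are configurable.
- **Cyclic warm-up** (`warmup_passes=1`): the two-year window is
  seasonally near-periodic, so the sequence is fed once to spin up the
  recurrent state before outputs are read (training and inference use the
  same scheme). Without it the first ~6 steps of every window carry a
  cold-start error several times larger than the rest of the series.
- **Initialisation**: uniform ±1/√H; forget-gate bias +1; head bias at
  0.4, the midpoint of the valid VI range, so optimisation starts centred
  rather than spending its limited step budget moving the output mean.
- The best-validation checkpoint is returned; with no validation set the
  final epoch is returned with a warning. Fixed seeds make corpus
  generation, training and prediction byte-reproducible.

Checkpoints are single `.npz` archives holding the weight arrays plus a
JSON blob with both configs and the loss history; save/load round-trips
predictions exactly.

## Baselines

- **SG baseline**: the same upper-envelope SG filter applied directly to
  the contaminated series *without* interpolating sentinels — the −0.2
  fill values enter the windows, reproducing the documented failure mode
  of filter methods on long outages.
- **Whittaker**: minimises Σ w(z−y)² + λΣ(Δ²z)² with λ = 2 and
  second-order differences, solved as a symmetric banded system.
  Sentinels are zero-weighted by default; a fill-value mode (weights all
  one, sentinels contributing −0.2) reproduces the harsher variant and is
  what the comparison harness uses.

## Evaluation

RMSE is the standard root-mean-square error (the raw summed variant,
dimensionally inconsistent, is preserved behind `printed_form` for
auditability). R² defaults to the explained-variation ratio
Σ(result − ȳ)²/Σ(ref − ȳ)² with ȳ the mean of good reference values; the
conventional 1 − SSres/SStot is computed alongside (clipped at 0).
Envelope rate counts strict undershoots of the observations; distance is
the mean absolute deviation from them. The comparison harness pools all
good steps across pixels before computing metrics (pooled RMSE equals
RMSE on the concatenated step set) and can stratify by latitude bands
(defaults: all, 40°N–60°N, 10°S–10°N).

## Synthetic benchmark

The generator is a declared simulation, not a claim about MODIS
statistics. Truth curves are double-logistic seasonal cycles; LAI is
obtained by inverting the exponential VI–LAI relation with fixed
per-stratum coefficients, so the builder's fit is recoverable by
construction; reflectance is solved per step from the index formulas
(NDVI: total brightness drawn in [0.3, 0.5]; EVI: red declining with
canopy density, blue tied to red), so computing the index on the
generated bands reproduces the observation to 1e−6. Contamination:
geometric-length cloud runs covering a target fraction of steps
(negative bias −0.4…−0.2 plus noise for NDVI, zero-mean sd 0.1 noise for
EVI), a winter snow season on boreal pixels that genuinely depresses the
*truth* (snow cover is a surface state, so evaluation rewards retaining
it), and 5% missing steps as sentinels. Four strata: tropical (long cloud
runs, 30%), temperate (40%), boreal (snow, 20%), and a high-LAI
saturation stratum (10%) that exercises the constrained-refit branch.

The benchmark protocol: 500 pixels, 40% cloud fraction, 80/10/10 split by
pixel, one LSTM trained per index on builder targets, all methods scored
on the held-out 10% against clean truth. Problem sizes were chosen so the
whole pipeline (both indices) completes in minutes on a single CPU.

What passing shows — and does not. The benchmark demonstrates that the
pipeline is internally consistent: targets approximate truth, the model
learns the reflectance→VI mapping through contamination, and the ordering
of methods under fill-value stress matches qualitative expectations
(LSTM < SG < Whittaker for NDVI RMSE). It does not demonstrate
performance on real MODIS data: real reflectance has BRDF and aerosol
structure, spatially correlated contamination, and QA errors that the
generator does not emulate. On EVI the synthetic contamination is
zero-mean by construction, which favours symmetric smoothers: the plain
SG baseline beats the LSTM there (the upper-envelope premise does not
apply to two-sided noise), and the acceptance report records this
honestly.

## Known limitations

- The recurrent model is unidirectional; reconstruction inside a long gap
  uses only past context (plus the cyclic warm-up's summary of the whole
  window).
- The snow blend partially retains low values by design (weight ramps
  over [−0.2, 0.2]), so deep snow troughs are reproduced attenuated.
- The LAI–VI relation is fitted per pixel over two years; land-cover
  change within the window violates its assumptions.
- Product-name handling covers the filename convention only; no HDF-EOS
  raster I/O, tiling, or projection math is included.
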