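# Methods

This package implements a three-part analysis: a process-based rice growth
simulator, a synthetic weather generator that drives it, and a distillation
pipeline that trains a small convolutional network (CNN) to emulate the
simulator and then interrogates the network with gradient saliency maps to
ask whether it rediscovered the physiology encoded in the simulator.

## Crop model

The simulator is a daily-step restatement of the SIMRIW family of models
(Horie & Nakagawa lineage) for irrigated japonica rice.

**Phenology.** A developmental index DVI acts as the physiological clock:
0 at emergence (assumed at planting), 1 at heading, 2 at maturity. It is
advanced daily by a developmental rate DVR. Before heading,

    DVR = 1 / { Gv [1 + exp(−A (Tmean − Th))] }            DVI ≤ DVI*
    DVR = [1 − exp(Bp (L − Lc))] / { Gv [1 + exp(−A (Tmean − Th))] }
                                                           DVI > DVI*, L ≤ Lc
    DVR = 0                                                DVI > DVI*, L > Lc

a logistic temperature response (half-maximal at `Th`, saturating at
`1/Gv`) modulated, once the crop becomes photoperiod-sensitive at
`DVI*`, by a short-day response with critical day length `Lc`. During
grain filling (1 < DVI ≤ 2),

    DVR = { 1 − exp[−Kr (Tmean − Tcr)] } / Gr

floored at 0 below the base temperature `Tcr` (development cannot
reverse; the raw expression would go negative). DVI is capped at exactly
2.0 on the maturity day, and heading/maturity are flagged on the first
crossing of 1.0 / 2.0, so a season that lands exactly on 2.0 counts as
matured.

**Growth.** Daily dry matter gain is ΔWt = Cs · Ss, with Ss the
canopy-absorbed short-wave radiation and Cs the conversion efficiency.
Cs equals `C0` before heading, declines smoothly to ~0 through the back
half of grain filling via `Cf (1 + Bf) / (1 + Bf exp((DVI − 1)/tf))`, and
carries a saturating CO2 factor `1 + Rm (P − 330)/((P − 330) + Kc)` that
equals 1 at the 330 ppm reference.

**Canopy surrogate.** The canopy submodel of the original SIMRIW (leaf
area dynamics from differential equations) is not part of this package;
it is replaced by a documented surrogate that preserves the two
properties the rest of the model needs: absorbed radiation is a function
of leaf area index (LAI), and LAI rises to its maximum at heading then
declines. Concretely LAI(DVI) = `LAI_max · DVI^lai_rise_exp` for
DVI ≤ 1 and `LAI_max · exp(−lai_decline_rate (DVI − 1))` after, with
Beer's-law absorption Ss = S (1 − e^(−k_beer · LAI)). Simulated dry
matter totals and yields should therefore be read as internally
consistent magnitudes, not field calibrations.

**Sterility and yield formation.** Spikelet sterility γ is the maximum of
two components. Cool-summer damage accumulates a cooling-degree sum
Qt = Σ max(0, 22 − Tmean) over days with 0.75 < DVI < 1.2 (the
clamping at 0 is the standard cooling-degree convention: days warmer
than 22 °C contribute nothing) and maps to

    γL = clamp(γ0 + Kq · Qt^aq, 0, 1).

The sign on the Kq term is written so that cooling *increases* sterility,
which is the stated physiology; γL is clamped into [0, 1] and treated as
a fraction throughout. Heat damage at anthesis is a fixed logistic in the
mean daily maximum temperature TH over 0.96 < DVI ≤ 1.22:

    γH = 1 / { 1 + exp[−0.853 (TH − 36.6)] }.

If a season never enters the anthesis window, γH is defined as 0 (the
season is excluded anyway). The harvest index is

    h = max(0, hm (1 − γ) {1 − exp[−Kh (DVI_final − 1.22)]})

and grain yield is YG = h · Wt. Seasons whose DVI has not reached 2.0 by
October 05 (day index 157 from the May 01 planting, non-leap calendar)
are flagged `excluded` and dropped from all downstream analysis.

The daily loop evaluates, in order: DVR from the day's weather and the
current DVI; the DVI update; then LAI, absorption, conversion efficiency
and the dry-matter increment at the updated DVI. Growth stops once
matured. The simulator is a pure float64 function of (weather,
parameters); an independently coded straight-line reference loop in the
test suite must agree with it to 1e-9 relative on full trajectories.

**Cultivar parameters.** The packaged Koshihikari-like parameter file
(`src/cropdistill/data/koshihikari.txt`) carries literature-informed
values with provenance notes; the cool-damage response converts the
published percent-scale form γL = 4.6 + 0.054 Qt^1.56 to fractions. No
test depends on their absolute values. Boundary conventions: the Eq-9
branch (constant C0) is used for DVI < 1.0 exactly; the pre-heading DVR
branch applies while DVI ≤ 1.

## Synthetic weather

One series is 184 days (May 01–Oct 31, non-leap calendar; leap years are
ignored as irrelevant to the season window) of day length L, mean and
maximum temperature, daily total global solar radiation, and constant
CO2 (350 ppm by default, configurable because the CO2 response keeps it
a live input).

The generative model is the package's own design (the analysis only
assumes realistic structure, not a particular distribution):

- seasonal mean temperature `Tann(lat) + Tamp(lat) cos(2π (doy − 210)/365)`
  with Tann = 16 − 1.0 (lat − 35.7) °C and Tamp = 10.5 + 0.2 (lat − 35.7) °C,
  emulating a warm-south/cool-north latitude gradient peaking in late July;
- AR(1) daily noise (ρ = 0.7, innovation scale `noise_sd`, default 1.5 °C)
  plus a N(0, 0.7 °C) year effect;
- Tmax = Tmean + max(0, 4.5 + N(0, 1)) °C;
- radiation = clearness × top-of-atmosphere radiation (FAO-56 form),
  clearness an AR(1) process clipped to [0.12, 0.78];
- day length from the civil sunrise-to-sunset hour-angle formula with
  Cooper's declination (no twilight or refraction; |lat| < 66.5° only).

Scenarios perturb the baseline additively, so seed-matched series differ
exactly by the perturbation: `cool_summer` subtracts `delta_T` (default
5 °C) from Tmean on days 65–120; `heat_anthesis` adds `delta_T` (default
6 °C) to Tmax on days 70–120; `cold_region` subtracts `delta_T` (default
12 °C) from both over the whole season, which reliably prevents maturity.
Windows are chosen to straddle heading across the 31–42 °N latitude band.
Default scenario mix: baseline 0.55, cool_summer 0.20, heat_anthesis
0.20, cold_region 0.05. Under this mix roughly a fifth of grid-years
fail the October-05 rule (cold regions everywhere, plus cool summers and
baselines at high latitude), and both sterility modes are well populated.

What the generator does **not** emulate: spatial correlation between
grids, temperature–radiation cross-correlation beyond independent AR
processes, humidity/precipitation (unused by the model), typhoons, and
real interannual climate trends. Passing tests therefore show that the
pipeline recovers structure the simulator put into synthetic data — not
that it would do so on observed weather.

## Corpus construction

Each kept grid-year becomes a 184 × 5 matrix with columns in fixed order
L, Tmean, Tmax, Ss, P. The Ss column is the *incident* daily global
solar radiation from the weather series — the five columns are
meteorological inputs, and canopy-absorbed radiation is a simulator
internal. Rows strictly after the maturity day are zeroed so all inputs
share one shape (the maturity day itself still acted on the crop and is
kept).

Normalization is per-factor z-scoring with statistics from the training
split only, computed over non-padded cells; padded cells stay exactly
zero. The constant CO2 column has no variance, so it falls back to
identity scaling (center 0, scale 1) and passes through at 350 — the
network's initialization absorbs the scale mismatch (below). Uniform
noise in [−0.001, 0.001] is then added per cell to both splits, and
padded rows are re-zeroed so "zero padding" stays meaningful. Whether
the original protocol normalized before padding or noised the padding is
not knowable from its description; this order is the package's
documented choice. The 75/25 split is a seeded uniform partition by
grid-year unit.

## Surrogate and training

The network maps the single-channel 184 × 5 matrix to one scalar yield:
3 × 3 convolution, stride 1, padding 2, 1 → 32 maps, ReLU; the same
geometry 32 → 64 maps, ReLU; flatten (feature maps grow 184 × 5 →
186 × 7 → 188 × 9 with this padding, giving 108,288 features); dense
ReLU layer of 64 units; scalar linear head — 6,949,377 parameters in
total. It is implemented in NumPy (im2col + GEMM with explicit
reverse-mode gradients), which also provides the input gradients that
saliency analysis needs.

Training minimizes MSE with Adam (lr 1e-3, batch 64 by default — width,
batch and rate are unstated in the protocol being reproduced and live in
config). Targets are standardized with training-split mean/sd inside the
trainer; predictions and recorded losses are mapped back to g m⁻².
Initial weights are Glorot-uniform except the head (std 1e-3), followed
by a layer-sequential unit-variance rescaling on a 256-sample batch:
each layer's weights are divided by its activation standard deviation so
the un-standardized CO2 column cannot blow up early optimization.
Early stopping: training ends when validation loss has not strictly
decreased (ties count as no improvement) for 10 consecutive epochs, or
at `max_epochs`; the weights of the best-validation epoch are
checkpointed each epoch and restored at the end.

**Study size.** The distillation study in the tests and the acceptance
script uses 68 grids × 40 years (2,720 grid-years, ≥ 2,000 surviving
matrices after exclusion), three training seeds, and a fixed epoch
budget (`max_epochs` 20) at which validation R² plateaus near 0.93 on
this corpus; the accuracy bar (R² ≥ 0.9 in at least 2 of 3 seeds) is a
property of the distillation, not of a particular seed.

## Saliency analysis

"Positive saliency" is implemented as the rectified input gradient of
the predicted yield, per map rescaled to maximum 1 (identically zero
maps stay zero) — the simplest definition consistent with "cells whose
increase raises the output". Signed gradients are retained alongside for
direction-of-effect readouts. Other backprop variants can be swapped
behind the same contract.

Three cases are analyzed: all kept training data; the subset at or below
the 10th percentile of hγH (harvest index recomputed with heat sterility
only); and the analogous hγL subset. Percentiles are computed on the
corpus at hand, not imported from any external dataset. From each case,
500 training inputs are sampled (seeded; without replacement when the
subset is large enough, with replacement otherwise, which the small
stress subsets require).

Each non-padded day-row of each map contributes its five factor
saliencies to the DVI bin (width 0.05) holding that day's simulated DVI;
bin means are taken across all contributing (map, day) rows — per
day-row, not per map first. The knowledge-recovery check is a paired
sign-flip permutation test (2,000 resamples, two-sided) on the per-map
difference between mean saliency inside and outside a DVI window: Tmax
inside (0.9, 1.22] for the heat case, Tmean inside (0.7, 1.2] for the
cool case. A small p-value says the network treats those factors
differently exactly where the simulator's sterility windows sit, despite
never having been shown DVI.

## Numerical and engineering choices

- Simulator in float64; training corpus and network in float32 (the
  384-MB-per-batch patch matrices make float64 training pointless); the
  float32 storage rounds the 350-ppm CO2 column at the ~3e-5 level.
- Permutation p-values use the add-one convention (p ≥ 1/(n+1)).
- All randomness flows through explicit integer seeds via NumPy
  Generators; per-series seeds are derived from (seed, year, latitude,
  scenario seed) so any grid-year is reproducible in isolation.
- Run manifests hash array contents rather than file bytes, so
  compressed-container timestamps cannot break idempotence checks.

## Known limitations

- The canopy surrogate and the cultivar parameter file are plausible,
  not calibrated; absolute yields (≈ 600–800 g m⁻² for favorable
  baseline seasons) are in the right range for potential-yield
  simulation but carry no field validity.
- The weather generator's realism bounds every downstream claim; see
  above for what it omits.
- γH is fixed to 0 for seasons that never reach the anthesis window;
  such seasons are excluded before any analysis that uses γH.
- The CNN engine supports exactly the stated geometry family
  (padding = kernel − 1); it is an emulation target, not a general
  deep-learning library.
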