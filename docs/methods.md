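# Methods

This note documents the models, parameter choices, numerical decisions,
and known limitations of the soarscape pipeline.  It describes what the
code computes; every number quoted here is produced by the test suite or
the `analysis/` drivers.

## Behavior classification

Each GPS fix is characterized by its *track segment*: all fixes of the
same bird within ±45 s (a closed 90-s window).  Six features are
computed per segment:

| feature | definition | units |
|---|---|---|
| `a_speed` | mean of consecutive-fix 3-D speeds ‖Δ(x, y, ASL)‖/Δt | m/s |
| `b_rate_asl` | OLS slope of altitude ASL vs time | m/s |
| `c_rate_agl` | OLS slope of altitude AGL vs time | m/s |
| `d_r2_asl_time` | R² of the ASL–time regression | — |
| `e_r2_agl_asl` | R² of the AGL–ASL regression | — |
| `f_domfreq` | periodogram peak frequency of the heading series | cycles/s |

Decisions taken where the design was genuinely open:

- **Feature `c` in m/s.**  The two stated regressions are ASL-on-time
  and AGL-on-ASL, yet the AGL rate is conventionally reported in m/s.
  We compute `c` as the OLS slope of AGL on time, honoring the units;
  the AGL-on-ASL regression contributes only its R² (`e`).  The
  dimensionless AGL-on-ASL slope is a plausible alternative reading and
  would only change `c`'s scale, not the classifier's information.
- **Heading series and the 360° wrap.**  Headings are consecutive-fix
  compass bearings.  The series is linearly detrended before the
  periodogram but *not* unwrapped by default: circling flight turns the
  wrapped bearing into a sawtooth whose period is exactly the circling
  period — a strong, useful signature.  An `unwrap` option exists.
- **Frequency scale under mixed sampling.**  The periodogram (boxcar
  window, `scipy.signal.periodogram`) treats the series as evenly
  spaced; per-sample frequency converts to cycles/s via the segment's
  modal sampling interval.  This is adequate when nearly all data are at
  3–4 s, which the interval filter guarantees.
- **Zero-variance responses.**  R² of a constant response is the 0/0
  case; it is defined as 0 (and the slope as 0) so that perched
  segments remain representable.
- **Local time.**  SAST is a fixed UTC+2 offset (no DST); the midday
  activity filter keeps the half-open window [11:00, 15:00).

Data-quality rules: fixes with sampling interval > 6 s are excluded
(first fix of a bout takes the following gap); segments with fewer than
five fixes, or without any fix whose interval rounds to 3 s, are
dropped with a logged reason.

The classifier is a 500-tree random forest (√p features per split, no
class reweighting by default — both exposed).  Accuracy is reported as
the out-of-bag error: each training row is predicted only by trees whose
bootstrap resample excluded it; per-class errors and the OOB confusion
matrix come from the same votes.  Argmax ties resolve in the fixed order
perched < gliding < orographic < thermal.  Training rows are drawn by
sampling ⌈10% × n_days⌉ tracking days per bird (all fixes of a sampled
day), mirroring day-level manual annotation; sampling locations within
days instead is a supported variant.

## Covariates

- **Slope/aspect**: Horn 8-neighbor finite differences on the DEM;
  slope = atan(‖∇h‖); aspect is the compass direction the slope *faces*
  (downhill direction, 0° = north, clockwise).  This convention is fixed
  by the windward anchor case: a south-facing slope (β = 180°) under a
  south wind (w = 180°) must give the maximal angle of incidence.
  Zero-gradient cells are flagged flat, with aspect undefined; border
  cells (one-sided stencil support) are flagged.
- **Solar position**: NOAA solar-calculator geometry (Fourier series
  for the equation of time and declination, hour angle at the site
  longitude).  The test suite cross-checks it against an independently
  coded Astronomical Almanac approximation (Michalsky); the two agree
  to well under 0.5° of great-circle separation across epochs
  1950–2050.
- **Hill shade** `hs = max(0, 255(cos z cos θ + sin z sin θ cos(α−β)))`,
  in [0, 255]; flat cells contribute through cos θ alone since
  sin θ = 0 annihilates the aspect term.
- **Angle of incidence** `v = 180° − angular separation(β, w)` in
  [0°, 180°], symmetric in its arguments, NaN over flat cells (no
  windward/leeward structure is fabricated on plains).
- **Weather join**: each fix joins the nearest-in-time hourly record of
  its station with a 30-min tolerance; beyond it the row is flagged and
  excluded from modeling.  Hill shade at a fix uses the fix's own
  timestamp, not the weather hour.

## Soaring GLMs

Responses: thermal = 1 vs other *flying* fixes = 0, and likewise for
orographic; perched fixes must be excluded beforehand (enforced).
Candidate terms: elevation, elevation², slope, slope², wind speed, v,
hs, temperature — entered raw (unscaled), so coefficients are per meter,
per degree, per m/s, per hill-shade unit, per °C.  Wind direction and
aspect never enter individually; only their interaction v does.

All admissible subsets are fitted (marginality: a quadratic only with
its linear parent — 144 models), by IRLS to deviance tolerance 1e-8
with a 100-iteration cap; |coefficient| > 15 on the raw logit scale
triggers a separation warning.  AIC = −2 logL + 2k exactly.  Averaging:
if the top model's Akaike weight exceeds 0.9 it is used alone;
otherwise the strict delta-AIC < 2 set is averaged with renormalized
weights.  *Full* (zero-substitution) averaging is the default — a term
absent from a model contributes 0, shrinking weakly supported effects —
with conditional averaging behind a flag.  Unconditional standard
errors follow Buckland, `SE = Σ wᵢ √(seᵢ² + (βᵢ − β̄)²)`; z = |β̄|/SE
with two-sided normal p-values and ±1.96·SE intervals.  Models are
pooled across birds (no random effects), a stated limitation.

AUC is computed by midranks (Mann–Whitney), ties counted one half; the
tests pin it to an O(n²) all-pairs concordance oracle at 1e-12.

## Prediction over territories

A territory is the set of DEM cells whose centers lie within 3 km of a
nest (the nest's own cell always belongs; an optional mask can exclude
cells, e.g. sea).  Weather scenarios are hourly records with local hour
in [07:00, 19:00], pooled across years, sampled uniformly without
replacement per calendar month (with replacement plus a warning when a
month's pool is short).  Per scenario and cell the linear predictor uses
the cell's elevation/slope terms, hill shade at the scenario's own
timestamp (solar position evaluated at the nest — the solar-geometry
variation across a 3-km buffer is negligible), v from cell aspect and
the scenario's wind direction, and the scenario's wind speed and
temperature; probability is the inverse logit.  Flat cells take the
territory-mean v of that scenario (90° if the whole territory is flat),
with the flat fraction available on the territory.  Monthly summaries
average over cells then scenarios (order-immaterial for means; scenarios
weighted equally), and the combined total is the sum of the thermal and
orographic means, in [0, 2].  Regions are compared per month with
Welch's t-test (Welch–Satterthwaite df).

## Synthetic data

The generator supplies what the analysis needs and nothing more; its
defaults are stand-ins chosen inside real raptor flight envelopes, not
estimates from any bird.

- **Terrain**: flat, inclined-plane, or ridge landscapes (north–south
  Gaussian ridges over a plain with smoothed low-amplitude roughness);
  the ridge family guarantees both a flat region (slope < 2°) and steep
  flanks (> 20°).  Grids are ESRI ASCII text; coordinates are local
  east/north meters anchored at a reference lon/lat via an
  equirectangular conversion (sub-meter accurate at study extents).
- **Weather**: hourly temperature = seasonal cosine (southern-hemisphere
  phase, peak mid-January, amplitude 6 °C) + diurnal cosine (peak 14:00
  local, amplitude 5 °C) + Gaussian noise (SD 1.5 °C) around an 18 °C
  mean; Gamma wind speeds (mean 4 m/s, shape 2); von Mises wind
  directions around a prevailing direction.
- **Tracks**: regimes executed on a schedule at 3-s fixes.  Thermal:
  left-turning circle of radius 25 m completed every 20 s (so the
  heading advances 54° per fix), climbing 1.5 m/s, optional wind drift
  (default 0).  Glide: straight at 15 m/s sinking 1.0 m/s, steering
  toward the lowest terrain ahead when the descent would meet rising
  ground (valley following), floored 5 m above ground.  Orographic:
  straight at 10 m/s holding 50 m above ground.  Perched: stationary on
  the ground.  Straight-flight regimes aim at a random interior point
  and steer back near the DEM margin so long schedules stay on the
  grid.  Isotropic Gaussian GPS noise (default SD 1.5 m per axis) is
  added after the kinematics; altitude AGL is ASL minus the bilinear
  DEM elevation at the exported fix, exactly at zero noise.
- **GLM responses**: Bernoulli draws from the inverse logit of a
  user-supplied coefficient set over any covariate table — the
  workhorse for parameter-recovery testing at printed-magnitude
  coefficients.

What the simulator does **not** emulate — and therefore what passing
tests do not show about real data: behavior choice is scheduled, not
driven by weather or terrain, so track-derived labels carry no
behavior–environment coupling (the model-fitting driver simulates
responses over the real covariate joint distribution instead); GPS error
is white, not autocorrelated; there is no wind advection of glides, no
flap-glide mixtures, no transitional behavior between regimes beyond
window mixing; and sampling is exactly regular, whereas real tags jitter
between 3 and 6 s.

## Problem sizes and runtime choices

The default study conditions are kept where they are stated: 3-s fixes,
90-s windows, 500 trees, 10% of days for training, 3-km territories,
100 scenarios per month per region, delta-AIC < 2.  Scale choices made
for the packaged analysis (and stated as such): 9 × 9 km DEMs at 30-m
cells, three birds × three simulated tracking days, three territories
per region, two-year weather series.  The full test suite runs in about
a minute; the six analysis drivers in a few minutes.

## Known limitations

- The equirectangular local projection and spherical-Earth constant are
  inappropriate beyond ~100-km extents.
- OOB error on clean, well-separated synthetic regimes (≈ 0.2–0.8%) is
  far below what heterogeneous real tracks would give; it validates the
  pipeline, not field accuracy.
- Nearest-hour station weather ignores sub-station spatial variability,
  exactly as in the motivating analysis; v and hs consequently inherit
  station-scale wind and clear-sky solar geometry (no cloud model).
- Model averaging assumes the candidate set spans the truth; the
  144-model lattice is the full admissible universe over the eight
  terms, nothing more.
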