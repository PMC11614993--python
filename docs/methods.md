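# Methods

## Recovery model and fitting

The observable is the integrated intensity of an imino-proton resonance
after band-selective inversion and a recovery delay τ:

    I(τ) = A + D·exp(−τ / selT1)

A (equilibrium intensity) and D (inversion coefficient) are in arbitrary
amplitude units; selT1 is in ms. D is fitted freely rather than fixed to
−2A because inversion efficiency in cells is unknown; a perfect inversion
gives D = −2A and I(0) = −A.

Fits are nonlinear least squares (Levenberg–Marquardt via lmfit) with
weights 1/σᵢ per point by default, σᵢ being the rms-noise-based standard
error from extraction; unweighted fitting is available (`weighted=False`)
since the original analysis does not document its weighting. Initialization:
A₀ from the largest delay, D₀ = I(τ_min) − A₀, selT1₀ from the delay whose
departure from A₀ is nearest |D₀|/e (median delay as fallback). selT1 is
constrained positive. A fit is flagged `failed` — never silently returned —
when the optimizer does not converge, selT1 collapses to its bound, the
covariance is unavailable, or the relative standard error of selT1 exceeds
100%.

Covariance convention: when per-point errors are supplied (weighted fit),
the weighted-NLS covariance is reported unscaled, which is the correct
frequentist covariance for known noise levels and is what makes the global
fit's pooling property (shared-selT1 SE ≤ best individual SE) hold
deterministically. Unweighted fits scale the covariance by the reduced χ²
(the usual default when errors are unknown).

The global model shares one selT1 across series while keeping per-series
(Aᵢ, Dᵢ); with one series it reduces to the individual fit. Technical
replicates can be brought to a common scale before global fitting by the
remeasured reference delay: each series is multiplied by the ratio of the
first series' first reference intensity to its own (the original procedure
is described only qualitatively; this ratio scaling is the simplest faithful
reading).

### Deterioration correction

Cell death over the hours-long session decays all signal roughly
proportionally. The repeated 0.32 ms reference delay interleaved in each
schedule tracks this: an OLS line through (start time, reference intensity)
defines a correction factor normalized to 1 at the first reference, and
every intensity and error is divided by the factor at its start time
(multiplicative correction; an additive variant exists behind
`mode="additive"` but proportional loss is the physical default). On
noiseless data with an injected linear multiplicative drift the correction
is exact: post-correction reference slope is zero to machine precision and
the generating selT1 is recovered exactly.

### Ratio table

In vitro / in-cell selT1 ratios are computed from unrounded fitted values
with first-order error propagation, and additionally reported rounded to one
decimal. In vitro peaks are matched to composite in-cell peaks by label
components (T4/T22 → T4/T22/T18). Note that the one-decimal ratio of the
rounded table values 253/84 is 3.0, while ratios computed from unrounded
fits can differ in the last digit — the package always reports the computed
value.

## Recovery-time planning

Sensitivity per unit time of the 120° fast-pulsing steady state:

    S(T_rec) = sin(π/3)·(1 − E) / ((1 − E·cos(π/3))·√(T_rec + t_ov)),
    E = exp(−T_rec/selT1).

The expression is implemented with the +cos(π/3) denominator term exactly as
used in the original planning curve. A 120° excitation would formally put
cos(2π/3) < 0 there; only the positive-cosine form reproduces the planning
optima this package is validated against (66 ms at selT1 = 84 ms, 173 ms at
253 ms), so that form is kept and the discrepancy documented here.

The optimum is found by golden-section search on (0, 20·selT1] to 0.01 ms;
an independent 0.1 ms grid search is used as a cross-check in the tests and
the acceptance script. Stationarity at zero overhead gives the universal
ratio T_rec*/selT1 = 0.6063 (from E/(1−E) − cE/(1−cE) = 1/(2x), c = 1/2).
Uncertainty in selT1 is propagated by re-optimizing at selT1 ± 1 SE, which
matches the asymmetric-bound style of the planning literature and is exact
for this monotone map.

Defaults: per-scan overhead t_ov = 11 ms (PC9 3.88 ms + Reburp 3.23 ms + two
1 ms gradients + two 0.2 ms gradient recoveries, rounded), configurable.
Instrument constraints default to minimum D1 = 30 ms, acquisition 77 ms,
disk write 30 ms, giving a 137 ms achievable floor; disk-write time enters
the floor arithmetic but not Tscan of the sensitivity expression (Tscan is
recovery time + pulse lengths), switchable if a console counts it
differently. In the quantitative regime the per-scan time is k·selT1 +
overhead with k = 5 (~99.3% recovery) by default.

## Synthetic data

The generator emulates exactly the data the analysis assumes:

- Lorentzian resonances: each contributes
  amp(τ)·exp(i2πΔν t − π·lw·t) to the FID, Δν the offset from the carrier;
  amp follows the recovery law times the drift factor.
- Acquisition defaults: 600.16 MHz, 22.04 ppm window, carrier 13.5 ppm,
  2048 complex points (≈155 ms acquisition).
- Noise: iid Gaussian on real and imaginary channels (white), σ in
  amplitude units; `calibrate_noise_sigma` sets σ so a target SINO-style SNR
  is reached for a chosen peak under a chosen recipe, calibrated empirically
  on noise-only FIDs so it remains valid for recipes that color the noise
  (linear prediction). Defaults target the in-cell SNR range ≈ 8–12.
- Drift: multiplicative linear factor 1 + s·(t − t₀) on all amplitudes;
  the in-cell-like magnitude is s ≈ −10%/4 h, matching the observed
  viability loss over one technical replicate.
- Schedules: `long9` = (0.32, 150, 300, 600, 1200, 0.32, 225, 450, 900) ms
  and `short9` = (0.32, 15, 50, 250, 900, 0.32, 7.5, 75, 4) ms, each with
  two reference entries. Wall-clock start times are derived from per-scan
  arithmetic (1024 scans × (968.5 ms saturation recovery + τ)); within-
  experiment signal averaging is not modelled (one effective FID per delay).
- Presets: `in_vitro` (7 peaks, 8 Hz lines) and `in_cell` (5 peaks, 25 Hz
  lines, near-degenerate resonances merged) carry the fitted selT1 values of
  each condition. Chemical shifts other than the 13.4 ppm composite are
  representative synthetic placements in the imino region, not assigned
  values; amplitudes make the composite the strongest peak and T9 the
  weakest.

Not modelled: pulse-shape selectivity, radiation damping, solvent signal,
B0 drift, baseline distortions. Passing tests therefore demonstrate the
statistical correctness of the estimators under the assumed model, not
robustness to instrument artefacts.

### Monte-Carlo validation scale

Estimator calibration runs 500 intensity-level replicates per condition at
SNR 10 over selT1 ∈ {24, 84, 253} ms (a few seconds total): median bias is
well under 5% and 1-SE interval coverage is ≈ 69%. The short schedule is
used for the fast-relaxing values (24, 84 ms) and the long schedule for
253 ms, mirroring how the schedules were designed: the long schedule's first
non-reference delay (150 ms) is ≈ 6×selT1 for a 24 ms peak and carries no
information about the decay.

## Processing

Recipes apply truncate → linear-predict → apodize → Fourier transform. The
order is a choice (the original description does not state one); predicting
from the raw truncated FID before windowing is the standard interpretation
and each step is independently callable. Details:

- Truncation keeps the first TDeff complex points (512 in the truncating
  recipes, with the 2048-point default acquisition).
- Exponential apodization multiplies point k by exp(−π·lb·k·dwell); adds lb
  Hz to Lorentzian linewidths (verified numerically via the convolution
  theorem).
- Linear prediction: forward autoregressive extrapolation; coefficients by
  least squares (minimum-norm when the signal has fewer modes than
  coefficients, which keeps noiseless extrapolation exact), prediction-
  polynomial roots outside the unit circle reflected to their conjugate
  reciprocals so extrapolation cannot diverge; rank-deficient or non-finite
  estimation falls back to zero-filling, recorded in provenance.
- Fourier step: first point halved (removes the flat baseline offset of a
  discretely sampled Lorentzian), zero-fill to the next power of two ≥ 2×
  length by default, real part taken with zero-order phase 0 — synthetic
  data are generated phase-coherent, so a positive-A resonance yields a
  positive absorptive peak and no first-order phasing is needed. The ppm
  axis is descending with the carrier at the centre.

### Known limitation: peak-tail overlap

Extraction reads single grid points; overlapping Lorentzian tails of
neighbouring peaks therefore leak between series (multi-peak deconvolution
is deliberately out of scope). In the crowded in-cell preset the weak T9
peak, 0.3 ppm from a 3× stronger composite, acquires a percent-level
selT1 bias that differs between processing recipes (heavier line broadening
→ longer tails). The processing-robustness guarantee (recipes agree within
1% on noiseless data) is therefore stated for peaks whose extraction window
isolates them — the composite main peak and isolated resonances — and a
characterization test bounds the crowded-preset bias at 4% for every peak
and recipe.

## Extraction

Peak shifts are frozen at the |intensity| extremum inside a per-peak search
window of the first spectrum; later spectra are read at the nearest grid
point to the frozen shift, never re-picked (robust at low SNR; a
moving-maximum diagnostic is reported per spectrum for peaks like merged
doublets whose apparent maxima wander, but it never triggers re-picking —
the quantitative threshold for exclusion is left to the analyst). Noise is
the mean-subtracted standard deviation of the 15–16 ppm region (mean
subtraction makes it immune to constant baseline offsets). SNR is defined
SINO-style as peak/(2·rms), under which the error formula I/(2·SNR) reduces
exactly to the rms noise — that noise value is attached to every point as
its standard error.

## Cell quantification conventions

- Volumes assume spheres: (π/6)d³; 17.0 µm → 2.57 pL.
- Washout: the pellet retains a fixed carryover volume (pellet − cells);
  each wash multiplies the retained concentration by carry/(V + carry); the
  final supernatant is one more dilution into (resuspension + carry). Two
  50 mL washes of a 400 µM load leave ≈ 0.002 µM. The single-wash case is
  convention-sensitive (published figures of ~1.9 and 2.8 µM bracket the
  ≈1.6 µM this convention yields); the two-wash result is insensitive to
  the choice.
- Gel quantification: total DNA = labelled quantity × 40 (the documented
  label ratio); a strict-total option uses ×41. Standards above a
  user-specified saturation threshold are excluded before the OLS fit.

## Numerical choices

- Golden-section tolerance 0.01 ms; grid oracles at 0.1 ms.
- selT1 lower bound 1e-9 ms (positivity only, never an active constraint in
  a healthy fit — hitting it flags failure).
- Zero-fill default: next power of two ≥ 2× effective FID length.
- All randomness flows through numpy Generators; experiment simulation
  derives every FID from one seeded generator, so fixed seeds give
  bit-identical series.
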