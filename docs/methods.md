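# Methods

## Scope

`ctpc` implements a complete analysis chain for cardiac thermal performance
curves (cTPCs) of ectotherms heated on a controlled ramp:

1. **cardiotrace** — raw sensor trace → beat times → windowed heart rate vs
   body temperature → flatline (upper lethal temperature, ULT) call;
2. **tpc** — Sharpe–Schoolfield fit per individual and extraction of the
   five thermal traits;
3. **pgls** — phylogenetic generalized least squares of species-mean traits
   on habitat (star / Brownian / Pagel), AICc model comparison,
   neighbour-joining tree construction, Newick I/O;
4. **stats** — within-habitat species comparisons (Gaussian linear models,
   likelihood-ratio tests, Tukey HSD with compact-letter display) and CV%
   variability summaries;
5. **synthetic** — generators for environments, traces, phylogenies and
   trait cohorts with known ground truth;
6. **pipeline / cli** — orchestration with YAML config, config-hash + seed
   stamping of all outputs, and independently re-runnable stages.

Sequence retrieval and alignment are out of scope: the phylogeny enters as a
Newick string or a pairwise distance matrix.

## The curve model and its traits

Heart rate (bpm) at body temperature `T` (Kelvin) follows the
high-temperature-inactivation Sharpe–Schoolfield form

    r(T) = r_Tref · exp(−E/k (1/T − 1/Tref)) / (1 + exp(Eh/k (1/Th − 1/T)))

- `r_Tref` (bpm): rate at the reference temperature. `Tref` is fixed at
  30 °C — the ramp start — for identifiability; it is a constant of the
  parameterization, not a fitted quantity.
- `E` (eV): activation energy — the **slope gradient** trait.
- `Eh` (eV): inactivation energy; `Eh > E > 0` guarantees a single interior
  optimum.
- `Th` (K): half-inactivation temperature (the denominator equals exactly 2
  at `T = Th`).

The optimum has the closed form `Topt = Eh·Th / (Eh + k·Th·ln(Eh/E − 1))`,
which serves as an oracle for the numerical argmax used in trait extraction
(0.01 °C grid over the observed temperature range; agreement ≤ 0.02 °C is
enforced in the tests). **HRmax** is the fitted rate at Topt. **Slope
curvature** is `2·c₂` from an ordinary least-squares quadratic
`HR = c₀ + c₁·T + c₂·T²` on the windows cooler than Topt, fitted on
untransformed bpm. **ULT** comes from the flatline call, not from the curve.

### Fitting

Nonlinear least squares (scipy `least_squares`, trust-region reflective,
bounded) with 20 random starts drawn from wide uniform boxes
(E ∈ [0.1, 2] eV, Eh ∈ [1, 10] eV, Th spanning the observed range in K);
the best-of-starts solution by RSS is kept and solutions with `Eh ≤ E` are
discarded. Multi-start matters: single-start fits of this model are
initialization-sensitive. Zero-rate windows and windows at or after the
flatline onset are excluded before fitting — a dead heart is a different
regime, not low performance — and series with fewer than six usable windows
or essentially constant rate are flagged `fit_ok = false` rather than
fitted.

## Trace processing

- **Smoothing.** `bartlett_smooth` convolves the signal with a unit-sum
  triangular kernel, renormalizing at the edges so constants pass through
  unchanged. The pipeline default smooths with a 0.15 s window — the width
  of the beat pulse, making the operation an approximate matched filter —
  before detection; the raw path remains available.
- **Beat detection** uses scipy `find_peaks` with a refractory spacing
  (default 0.25 s) and a prominence threshold, with prominence evaluated in
  a bounded 1 s neighbourhood (`wlen`). The bound is essential: in the long
  quiescent stretch after a flatline, unbounded prominence is measured
  against the deepest noise valleys of the whole stretch, and isolated noise
  maxima would register as beats at rates above the flatline floor. The
  default threshold is 5 × MAD of the median-centred signal; the MAD tracks
  the sensor noise floor because beat pulses occupy a minority of samples.
  This operating point was chosen by parameter sweep on simulated traces at
  the study noise level (noise SD = 20 % of pulse height): it yields
  essentially zero false beats after death while keeping > 96 % detection at
  peak heart rates. Sample rates below ~20 Hz undersample a 0.15 s pulse and
  degrade detection; the assay default is 40 Hz.
- **Rate windows.** `hr_series` counts beats in windows (default 60 s,
  stepped by 30 s, indexed by start time, full windows only):
  `hr = 60·n/window`. The window temperature is the arithmetic mean of the
  samples in the window, which is robust to mild ramp nonlinearity.
- **Flatline / ULT.** The ULT is the window-mean temperature of the first
  window that begins a run with `hr < 5 bpm` lasting at least 120 s **and
  persisting to the end of the trace**. A transient flatline followed by
  recovery is not lethal and is never called. Detection is defined only on
  heating ramps (non-decreasing window temperatures). The call is therefore
  quantized to the window grid: at 0.25 °C/min a 60 s window spans 0.25 °C,
  which bounds the resolution of the ULT estimate.

## Phylogenetic regression

With tree covariance `C[i,j]` = root-to-MRCA path length, Pagel's λ scales
the off-diagonals only. λ = 0 is the star model (phylogeny ignored; equal
root-to-tip depths make it exactly OLS), λ = 1 pure Brownian motion. GLS
estimates are `β̂ = (XᵀC⁻¹X)⁻¹XᵀC⁻¹y` with the variance profiled out;
likelihoods are **ML, not REML**, so AICc is comparable between fixed-λ and
estimated-λ models. AICc counts the residual variance among the parameters
(p = 3 for star/Brownian, 4 for Pagel) and is flagged undefined when
`n − p − 1 ≤ 0`. Coefficient t-tests use the unbiased variance with
`df = n − rank(X)`; with six species and a two-column design this gives
df = 4, and the df is reported as computed rather than forced to any other
convention. λ is maximized over [0, 1] by a coarse 21-point grid (including
both endpoints, since the profile likelihood can be multimodal) followed by
bounded scalar refinement to 1e−6; estimates within 1e−6 of a boundary are
reported as exactly 0 or 1. Akaike weights are
`w_i = exp(−Δ_i/2)/Σ exp(−Δ_j/2)`.

Species means are arithmetic, with temperatures averaged in °C; the Kelvin
transform is reserved for the CV% statistic. Neighbour joining is performed
by dendropy's Q-criterion implementation behind `nj_tree`, with negative
branch lengths clamped to zero (with a warning); tests verify exact recovery
of additive matrices and the 3-taxon closed form.

## Within-habitat statistics

"Gaussian GLM" is an ordinary linear model fitted by ML (identical
estimates, simpler contract); its log-likelihood feeds likelihood-ratio
tests with χ² asymptotics and df equal to the difference in mean-structure
parameters. At moderate sample sizes the ML-based LRT rejects slightly above
the nominal 5 % (≈ 5–6.5 % at n = 30/group) — the expected small-sample
behaviour of the χ² approximation, not an implementation artefact.

Tukey HSD uses the Tukey–Kramer statistic
`q = |ȳᵢ − ȳⱼ| / sqrt(MSE/2 · (1/nᵢ + 1/nⱼ))` with p-values from the
studentized-range distribution (k groups, residual df); for two groups this
reduces exactly to the pooled two-sided t-test. The compact-letter display
uses insert-and-absorb: levels ordered by mean are inserted into the first
letter group whose members they do not differ from significantly, new
groups are opened otherwise, and subset groups are absorbed. Zero residual
variance flags all unequal pairs significant with a warning. Individuals
are the error term (the acceptance-scale design has 9 per species).

CV% = 100·σ/|μ| per species, then mean ± SD across species. Topt and ULT
are converted to Kelvin first, so the ratio is taken on an absolute scale —
this strictly reduces their CV relative to °C and is why the temperature
traits sit at the canalized end of the hierarchy. |μ| keeps the statistic
non-negative for the negative-valued curvature trait; μ = 0 is flagged
undefined.

## What the generators emulate — and what they do not

- **Environments.** A diurnal sinusoid plus midday heat pulses with
  lognormal daily amplitude (semidiurnally modulated when `tidal_mod` is
  set), affinely calibrated so the series mean and maximum equal the preset
  exactly. The rocky-shore preset (mean 31.8 °C, max 51.3 °C) and mangrove
  preset (27.7 °C, 33.2 °C) encode the two habitat regimes; the generator
  targets the mean and maximum, so derived gaps follow from those two
  numbers. The waveform is plausible, not measured: no weather, seasons, or
  substrate heat capacity. Deterministic acclimation programs are provided
  ("cool": 12 h 27 °C / 12 h 30 °C; "hot": 6 h 27→40 °C, 6 h 40→27 °C,
  12 h 27 °C).
- **Traces.** Beats form an inhomogeneous renewal process — interval
  `60/r(T)` with 5 % multiplicative jitter, because heartbeats are
  quasi-regular, not Poisson — with a stereotyped Gaussian pulse (~0.15 s,
  1 mV) per beat on Gaussian sensor noise. Resting metabolic depression is
  modelled phenomenologically as a rate ceiling below an onset temperature
  (default 60 bpm below 40 °C), reproducing the low-temperature plateau
  without inventing a mechanism. Beats cease at the true ULT. No
  arrhythmias, movement artefacts, sensor drift, or post-flatline recovery.
- **Phylogenies and species traits.** Ultrametric pure-birth (Yule) trees
  scaled to unit depth; traits are
  `intercept + β·habitat + MVN(0, σ²·C_λ)`. Habitat is assigned by random
  split — no correlated habitat transitions along the tree.
- **Trait cohorts.** The six-species design (three rocky, three mangrove,
  9 individuals each) mirrors the study scale: slope gradient higher in the
  rocky lineage (≈1.0–0.8 eV vs ≈0.65–0.55 eV), HRmax spanning 108–150 bpm,
  ULT ≈ 51–52.5 °C. Individual dispersion in the *trait-cohort* generator
  follows the observed variability hierarchy (CV%: ULT 0.955, Topt 2.19,
  HRmax 12.6, slope gradient 19.2, slope curvature 91.1; temperatures
  dispersed on the Kelvin scale). The *trace-level* generator uses a
  smaller Topt jitter (SD 1.5 °C) and ULT jitter (SD 1 °C): a Topt SD of
  ~7 K, as the cohort CV implies, would routinely push an individual's
  optimum above its lethal limit, which the curve model forbids
  (`ULT > Topt` is enforced per individual).

Passing tests on these generators demonstrate that the chain recovers known
parameters under its own assumptions (quasi-regular beats, white sensor
noise, exact linear ramp, correctly specified curve family). They do not
demonstrate robustness to model misspecification in real recordings —
baseline drift, movement artefacts, non-SS curve shapes.

## Problem sizes and numerical choices

- Parameter-recovery checks use 20 simulated traces at the full assay
  protocol (0.25 °C/min, 30–65 °C, 40 Hz, noise 20 % of pulse height);
  median recovery is ~4–5 % relative error on E, ~0.02 °C on Topt, and one
  half-window (0.125 °C) on ULT.
- λ recovery uses 64-tip trees, 50 replicates; type-I-error calibration uses
  1000 null replicates each for the star-PGLS habitat test (16 tips, one
  fixed tree, traits redrawn) and the two-group LRT (n = 30/group). The
  studentized-range Monte-Carlo oracle uses 10⁶ draws (k = 3, df = 24).
  Unit tests run reduced versions of the same checks.
- Pipeline tests run a reduced assay (1 °C/min at 20 Hz) — the structure is
  identical and traces stay small; 20 Hz is the floor at which a 0.15 s
  pulse remains adequately sampled.
- Covariance solves use Cholesky factorization; the trait simulator adds a
  1e−12 ridge before factorizing. Tie-break at λ boundaries: values within
  1e−6 of 0 or 1 are snapped to the boundary.
- All randomness flows through explicitly passed seeds (NumPy
  `default_rng`); derived seeds are drawn below 2³¹.

## Known limitations

- The ULT call is quantized to the rate-window grid and biased upward by up
  to one window's temperature span (the flatline can only be recognized at
  the first fully dead window).
- The star model here is "λ = 0 with root-to-tip depths on the diagonal";
  for non-ultrametric trees this is not the same as OLS with iid errors.
- AICc at n = 6 species with p = 4 (Pagel) is barely defined
  (n − p − 1 = 1) and heavily penalizes the estimated λ; with so few
  species the Pagel model rarely wins, which is a property of the design,
  not a bug.
- Compact-letter displays are a greedy construction; they are not unique
  when the significance pattern is intransitive.
- No support for cooling ramps, repeated-measures designs, or
  non-Gaussian trait models.
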