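# Methods

## Scope and model

`amykit` analyzes the self-assembly kinetics of amyloidogenic peptides
(built around IAPP/amylin-type assays) and classifies small-molecule
inhibitors by the microscopic process they act on.  Fibril mass formation is
described by nucleated polymerization with secondary processes.  The
microscopic processes and their normalized rates at the initial monomer
concentration m₀ are

| process | rate law | normalized rate |
|---|---|---|
| primary nucleation | kₙ·m^(n_c) | νₙ = kₙ·m₀^(n_c) (μM/h) |
| elongation (two growing ends) | 2·k₊·m·P | ν₊ = k₊·m₀ (1/h) |
| fragmentation | k_f·M | k_f (1/h) |
| secondary nucleation (single-step) | k₂·m^(n₂)·M | ν₂ = k₂·m₀^(n₂) (1/h) |
| secondary nucleation (multistep) | k₂·m^(n₂)/(1+(m/K₂)^(n₂))·M | saturating in m₀ |

Units are hours and micromolar throughout; rate constants are stored in
those units.  Two macroscopic rates summarize each mechanism:

- λ = √(2·ν₊·νₙ/m₀) — the primary pathway (monomer → fibril conversion),
- κ = √(2·ν₊·ν₂) (or √(2·ν₊·k_f)) — the secondary pathway.

### Closed forms

Primary-only assembly uses the exact Oosawa solution

    M(t)/m₀ = 1 − sech^(2/n_c)(√(n_c/2)·λ·t),

which we verified analytically against the moment equations for general n_c
(substituting m = m₀·sech^(2/n_c)(√(n_c/2)·λ·t) satisfies them exactly).

With a secondary pathway the package uses the generalized-logistic
interpolant

    M(t)/m₀ = 1 − [1 + (λ²/(θκ²))·(cosh(κt) − 1)]^(−θ).

Its early-time expansion reproduces the exact linearized solution
(λ²/κ²)(cosh κt − 1), and its late-time relaxation rate is θκ.  Matching the
latter to the known moment-equation relaxation rate κ·√(2/(n₂(n₂+1))) ties
the depletion-sensitivity parameter to the secondary reaction order,

    θ = √(2/(n₂(n₂+1)))  (`theta_from_order`),

so θ ≈ 0.577 for n₂ = 2 and θ ≈ 0.323 for n₂ ≈ 3.9.  θ defaults to 0.323 in
the inhibitor scenario fits and is free in the monomer-series fits.  The
closed form is validated against the numerical oracle rather than asserted:
half-times agree within 5% for κ/λ ∈ [5, 500] (≤3.6% at n₂ = 2 across that
grid), and the κ→0 limit is compared against the oracle rather than assumed
to reduce to the Oosawa form.

### Numerical evaluation

Both closed forms are evaluated in log space (`log1p`/`expm1`,
`logaddexp`, and a large-argument expansion of log sinh) because the printed
expressions overflow for κ·t ≳ 700.  This is an implementation contract,
not a model change: values agree with naive evaluation to machine precision
wherever the latter is finite.

### The moment-ODE oracle

`moment_ode_oracle` integrates fibril number P, fibril mass M and free
monomer m as three independent state variables (LSODA, rtol 1e-9,
atol 1e-12·m₀ by default), with the elongation factor 2 for two growing
ends and the fragmentation source dP/dt = k_f·M (short-fragment corrections
neglected, consistent with the coarse-grained κ).  Because m is integrated
separately, conservation m + M = m₀ is a genuine integrator check; it holds
to <1e-6·m₀ across randomized parameter sets in the property tests.

`params_from_macroscopic` inverts (λ, κ) to microscopic constants.  The
normalized mass curve depends on the three rate products only through λ and
κ (the remaining degree of freedom rescales P), so ν₊ is pinned to 1 h⁻¹ by
convention during inversion.

## Global fitting and scenario selection

Dose-series fits pool residuals over all replicate wells and conditions,
unweighted, on normalized curves.  Because normalized data constrain only
λ and κ, the three perturbation scenarios are parameterized identifiably at
that level:

- **primary_only** — λ free per condition, κ shared;
- **secondary_only** — κ free per condition, λ shared;
- **elongation_only** — κ free per condition with a shared λ/κ ratio
  (elongation scales both rates as √ν₊);
- **none_vary** — one shared (λ, κ).

Each scenario for n conditions has n + 1 parameters, so AICc comparisons
reduce to residual comparisons on an equal footing.  Reported normalized
rates pin ν₊ = 1 h⁻¹; the recovered per-condition scaling factors
(νₙ,c/νₙ,0 = λ_c²/λ₀²) are convention-free.

Rates are fitted as log₁₀ values (positivity without penalties) with
bounds 10⁻⁶–10⁴ h⁻¹.  Optimization is `scipy.optimize.least_squares`
(trust-region reflective) with a deterministic multi-start: a heuristic
start derived from each condition's half-time and rise width, then Latin
hypercube points over the log-bounds (seeded; default budget 16).  The loop
stops early once the best RSS has not improved by more than 0.1% for three
consecutive starts after at least four — this keeps typical fits at 4–5
starts while retaining the global search on hard, multi-modal cases.  Fits
are bit-reproducible given the same seed and start schedule.

AICc uses the least-squares Gaussian-likelihood form
n·ln(rss/n) + 2k + 2k(k+1)/(n−k−1), where n counts every retained time
point across all wells and k counts the fitted parameters as listed above.
Curves are down-sampled to ≤300 points per well before fitting (uniform
index selection); the rule can be disabled with `max_points=0`.
Parameter errors are asymptotic: s²(JᵀJ)⁻¹ at the optimum, propagated from
log to linear scale.  Parameters within 1e-6 of a bound are flagged.

Monomer dilution series are fitted under four candidate mechanisms with
shared microscopic constants; only identifiable products enter (A = 2k₊kₙ,
B = 2k₊k₂ or 2k₊k_f, plus K₂ and θ where applicable), so the mechanisms
carry 1, 3, 3 and 4 parameters, and parsimony is arbitrated by AICc.
n_c and n₂ are fixed (default 2) rather than fitted.

## Plate screening

Raw plates are blank-subtracted (time-pointwise mean of blank wells) and
normalized per condition by the maximum over time of the replicate-mean
trace, so the mean trace plateaus at 1.  Half-times are the earliest
plateau-relative 50% crossing, located by linear interpolation; the plateau
is the mean of the final 10% of samples, smoothing off by default.  Wells
that never cross half-plateau are excluded with a logged reason, never
imputed.

Activity calls combine the fold-change in mean half-time (thresholds 0.8×
and 1.25×, SEM propagated from both groups) with a two-sided Mann–Whitney U
test on per-well half-times (exact distribution for group sizes ≤ 8, normal
approximation above; p threshold 1e-4).  `direction` reflects the
fold-change alone; `active` additionally requires significance.  Note the
exact two-sided test cannot reach p < 1e-4 below roughly 9 wells per group,
so activity calling presumes half-times pooled across plates/repeats
(~10–12 wells per group); the synthetic screening checks use 12.

## Auxiliary fits

- **Taylor dispersion**: Gaussian peak I(t) = A/√(2πσ²)·exp(−(t−t_R)²/2σ²)
  with σ² = a²·t_R/(24·D) (classic Taylor temporal variance for a pulse in
  a circular capillary); fitted in log-parameters by Levenberg–Marquardt
  with moment-based initialization.  R_h = k_B·T/(6πηD); defaults
  a = 37.5 μm, T = 303 K, η = 0.797 mPa·s.
- **SPR biexponential**: R(t) = A₁(1−e^(−k₁t)) + A₂(1−e^(−k₂t)) on the
  0–τ association window (τ = 60 s default); phases reported fast-first,
  plateau = A₁+A₂; k₁ ≈ k₂ within 0.1% is flagged effectively
  monoexponential, not an error.
- **SPR 1:1 kinetics**: two-piece Langmuir model, association to τ then
  exponential dissociation at k_off, fitted globally across concentrations
  with optional pinned B_max.  When the plateau is linear in [A]
  (R² > 0.999) and fitted K_D > 10× the top concentration, the result is
  returned with status `KD >> max [A]` — K_D is then an extrapolation, not
  a measurement.
- **NMR CSP**: √((ΔδH² + (0.14·ΔδN)²)/2), the Williamson amide weighting;
  intensity ratios I/I₀ use raw peak heights, not volumes.  Unmatched
  residues are excluded and logged.
- **Copelleting**: spectra are reference-subtracted and baselined at 400 nm;
  percent free = 100 × corrected A(λ_max, after)/A(λ_max, before).  λ_max
  defaults ship for the four study compounds (252/291/340/276 nm).
- **Buffer capacity**: Van Slyke β = ln10·(K_w/[H⁺] + [H⁺] + Σ C·K_a[H⁺]/
  (K_a+[H⁺])²), with pK_w interpolated against temperature from CRC values.
  Protolytic groups are treated as independent and no activity corrections
  are applied; published capacities computed under other conventions can
  differ by a few percent (160 mM single-pK_a 9.1 buffer at pH 7.4, 30 °C
  evaluates to 7.07 mM here).

## Elugram analysis

The running median uses a centered window (default 15 samples — samples,
not seconds) that shrinks at the trace ends; an even window takes the lower
median.  Samples exceeding the running median by more than the threshold
(default 0.01 normalized units, strict inequality) are flagged; contiguous
flagged runs merge into one spike located at maximal excess.  Plateau
quantification is the spike-masked median over the plateau window (default
30–80 s; baseline window 0–15 s), relative to the 100 μM compound control.

## Synthetic data

Generators emulate each modality from recorded ground truth: raw ThT plates
(per-well gain ~ 5% CV and baseline drawn once per well, additive Gaussian
read noise, 5-min sampling, 3 replicate + 3 blank wells); normalized dose
series with exactly one process scaled per concentration (factors default
1→0.1 over five conditions, σ = 0.01, 48 h window so the slowest condition
still plateaus); monomer dilution series under any of the four mechanisms;
Gaussian taylorgrams; biexponential/Langmuir sensorgrams (σ = 1 RU); and
step-plateau elugrams with single-sample spikes planted at jittered,
evenly spaced positions (≥16 samples apart so each is a distinct event;
σ = 0.002).  The default kinetic condition is λ = 0.02 h⁻¹, κ = 1.0 h⁻¹,
θ = 0.323 at m₀ = 10 μM (half-time ≈ 9.4 h).  All generators are seeded
(`numpy.random.default_rng`) and byte-reproducible.

What the generators do **not** emulate: photobleaching, evaporation,
flocculation, instrument noise spectra (noise is white Gaussian), plate
position effects, or compound interference with the dye.  Passing the
round-trip and recovery tests therefore demonstrates correctness of the
analysis chain under the stated signal models, not robustness to every
artifact of real plates.

## Problem sizes and tolerances

The shipped checks use 20-point random parameter grids for the
closed-form/oracle comparisons, 20 seeded replicates per perturbation type
for scenario identifiability, 100 seeded elugrams for spike detection and
100 seeded plates for the false-activity rate; these sizes give stable
pass/fail behavior across seeds.  Fit tolerances follow the generator noise:
λ recovers within 5% and κ within 10% at σ = 0.01 on a single condition,
and noise-free round-trips recover parameters to ≤0.5% (0.1% for
taylorgrams).

## Known limitations

- The closed-form secondary-pathway solution is an interpolant: mid-curve
  pointwise deviations from the ODE grow as κ/λ → 1; half-times are
  reliable in the secondary-dominated regime the fits target.
- Scenario fits assume one perturbed process; mixed mechanisms of action
  will select the dominant one.
- n_c and n₂ are fixed in fits; they are weakly identifiable from
  normalized single-m₀ data.
- The two-piece SPR model ignores mass-transport limitation.
- Buffer capacity ignores ionic-strength/activity corrections.
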