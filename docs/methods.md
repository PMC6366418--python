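# Methods

## Assay model

A well contains enzyme, substrate at concentration $S$ (mM) and
inhibitor at $I$ (µM). Product is a chromophore read at 405 nm, so
absorbance grows at a rate proportional to the reaction velocity. Within
the initial-rate regime (no appreciable substrate depletion, no product
inhibition, no enzyme inactivation) the trace is linear:

    A(t) = baseline + k · v(S, I) · t + ε(t)

where `k = ε₄₀₅ · l / (V · 10⁶)` converts a velocity in µmol/min into an
absorbance slope in AU/min via Beer–Lambert (molar absorptivity ε₄₀₅ in
M⁻¹cm⁻¹, optical path `l` in cm, well volume `V` in litres), and

    v(S, I) = Vmax · S / [ Km · (1 + I/Kic) + S · (1 + I/Kiu) ]

is the general reversible-inhibition rate law. Setting a constant
"absent" replaces its factor by exactly 1; the five mechanisms are the
nested family none ⊂ {competitive, uncompetitive, noncompetitive} ⊂
mixed, with noncompetitive constrained to a single Ki in both slots so
the fitter sees 3 free parameters. Absence is represented by `None`,
never by ∞, keeping parameter counts explicit for AICc and avoiding
overflow.

### Units

Vmax µmol/min, Km mM, Kic/Kiu µM, time minutes, absorbance AU. With I
and the Ki constants in the same unit the factors (1 + I/K) are
dimensionless, so the rate law is unit-consistent as written; fits are
exactly equivariant under rescaling the inhibitor unit.

## Synthetic plates

The simulator emulates the assay protocol of the reference study of
flavonoid α-amylase inhibitors: substrate at 0.25/0.5/1 mM, an inhibitor
two-fold dilution ladder spanning each compound's tested range
(0–200 µM for B4, 0–100 µM for C5 and D11, 0–2 µM for acarbose), always
including the uninhibited control, three replicates per condition, reads
every minute over 0–30 min. The published constants of the four
reference inhibitors are built in as simulation ground truth
(B4/C5/D11 competitive with Kic 132/71/21 µM; acarbose mixed with
Kic 6 µM, Kiu 0.71 µM).

Noise model: per-read additive Gaussian noise (default SD 0.002 AU) and
a per-well uniform baseline (default 0.04–0.06 AU) — plausible
plate-reader magnitudes; the source protocol reports neither raw
absorbance levels nor read cadence, so these are declared assumptions,
not reconstructions. The default conversion constants
(ε = 12900 M⁻¹cm⁻¹, path 0.58 cm for a 200 µL fill, volume 200 µL) are
likewise configuration: every analysis either cancels them in a ratio
(percent inhibition, IC50) or passes them symmetrically through
simulator and extractor, so recovered constants do not depend on them.

What the simulator deliberately does **not** model: substrate depletion
(an exponential-depletion variant was considered and dropped — the
analysed window is the linear phase by construction), DMSO co-solvent
effects, temperature drift, plate edge effects, pipetting error
correlated within a dilution series, and enzyme inactivation. Passing
recovery tests therefore demonstrate the *statistical* chain is
unbiased and correctly calibrated under idealised noise; they do not
certify robustness to systematic artefacts of real plates.

## Velocity extraction

Initial velocity = OLS slope of the reads inside the 5–30 min window
(endpoints inclusive; earlier reads are ignored as the mixing/lag
phase). At least 3 in-window reads are required. The slope estimator is
invariant to a constant absorbance offset, so blanks and baselines drop
out. Negative fitted slopes are clamped to zero velocity with a warning
(the raw slope is kept for diagnostics); a perfectly constant trace is
reported with slope 0 and r² = 1 since the horizontal fit is exact.
Each well yields one observation tagged with its (S, I, replicate);
failed wells are collected in a report, never silently dropped or fatal.

## Dose–response

Percent inhibition is 100·(1 − v_I/v₀) against the replicate-matched
uninhibited control at the same substrate concentration (0.5 mM by
default); noisy values slightly below 0 are passed through, not
clamped. If the mean inhibition never reaches 50% within the tested
range the compound is reported as "% at the highest tested
concentration" — mirroring the common screening convention of quoting
IC50 only when the curve actually crosses it. Otherwise a two-parameter
log-logistic pct = 100/(1 + (IC50/I)^h) with floor 0 and ceiling 100 is
fitted to the per-concentration means (chosen for parsimony; a
four-parameter variant with free floor/ceiling is a config switch), and
the SE is the leave-one-experiment-out jackknife over replicates. A
response that decreases with concentration beyond noise (negative
Spearman ρ) attaches a quality warning but still returns a result.

## Fitting

Nonlinear least squares on individual observations, in natural-log
parameter space (positivity for free), with `scipy.optimize.least_squares`
(Levenberg–Marquardt, ftol/xtol 1e-14). Multistart: the data-driven
initial guess (Vmax₀ = 1.2·max uninhibited v, Km₀ = median S, Ki₀ = the
inhibitor level that roughly halves the control velocity), any
warm-start points, then up to 10 seeded log-normal perturbations
(SD 0.5 in natural log), stopping once the best SSR has been stable
(relative change < 1e-12) for 3 consecutive starts.

The cascade fits none → competitive → noncompetitive → uncompetitive →
mixed. Every inhibition model receives (Vmax, Km) from the uninhibited
optimum and, crucially, one start that *is* the nested optimum (the
missing constant set to 10¹², i.e. factor ≈ 1); the mixed model is
additionally started from each three-parameter optimum. Because the
optimizer can only improve on a start, SSR is monotone non-increasing
along every nesting chain up to optimizer tolerance — the property the
F test's numerator relies on. Fitting inhibition mechanisms with no
I > 0 observations raises an identifiability error rather than
returning an arbitrary Ki.

## Model selection

Extra sum-of-squares F test on each nesting edge (including
none → mixed): F = [(SSRₛ − SSR_c)/(dfₛ − df_c)]/(SSR_c/df_c), with
"prefer complex" when F exceeds the upper 1−α quantile (α = 0.05 by
default — operationalising the convention of testing at the 0.95
probability level). A numerically negative SSR difference within 10⁻⁴
relative is treated as a tie; larger violations clamp F to 0 with a
warning since they indicate a warm-start failure.

AICc uses the Gaussian-SSR form with K = k_params + 1, counting the
residual variance as a fitted parameter (the statistically standard
choice; `count_variance=False` is available for sensitivity). Scores are
comparable only across fits of the same observation set; a numerically
zero SSR maps to −∞, which orders correctly against any finite score.

Decision procedure (the F tests and AICc are combined with an explicit
precedence, since using "both" leaves ties unspecified): (1) run all
edge F tests; (2) retain a mechanism only if no significantly better
complex model beats it, and retain a complex mechanism only if it is
significantly better than *every* simpler model on its chain (the three
3-parameter mechanisms are never F-compared with each other — equal
parameter counts, no nesting — they compete through AICc only); (3)
among the retained candidates take the lowest AICc, resolving near-ties
(< 2 AICc units, the conventional "no substantial support" band) toward
fewer parameters. If the F tests are mutually inconclusive and no
candidate survives, selection falls back to pure AICc ranking over all
five. Any non-converged fit aborts selection with a diagnostic.

## Jackknife errors

The unit of deletion is one velocity observation (one well). The
selected mechanism is refitted n times, each deletion set warm-started
at the full-data optimum (the deletion sets share its basin, so no
multistart). Primary output is the plain sample SD (ddof = 1) of the
leave-one-out estimates; the classical Tukey jackknife SE, which equals
SD·(n−1)/√n exactly, is carried alongside so either convention can be
quoted. Non-convergent deletion fits are excluded and counted. The
precondition n ≥ k + 2 keeps every deletion fit identifiable.

## Problem sizes and determinism

All randomness flows from explicit integer seeds (`numpy`
`default_rng`); identical seed + design + truth gives a bit-identical
plate, and the whole pipeline is deterministic given its seed. The
validation suite uses 20-seed recovery studies per compound (a default
plate is 45 wells × 31 reads), 50-seed classification runs for the
competitive and mixed ground truths and 200 for the no-inhibition null;
each simulated dataset analyses in well under a second, keeping the
full suite around a minute.

## Known limitations

- Ordinary (unweighted) least squares assumes homoscedastic velocity
  noise; strongly heteroscedastic plates would warrant weights.
- The IC50 jackknife SE needs ≥ 2 independent experiments; with fewer
  the SE is omitted rather than substituted by curve-fit covariance.
- With near-noiseless data the mixed model's extra constant is weakly
  identified when the truth is simpler; its fitted value may wander to
  very large magnitudes. This is harmless — selection discards the
  mechanism — but the value itself should not be interpreted.
- The published ± values for the reference constants cannot be used to
  calibrate the noise model (the mapping from read noise to constant SDs
  depends on unreported replicate structure), so simulated jackknife SDs
  are not comparable to the published SDs.
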