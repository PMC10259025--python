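# Methods

## Model and assumptions

The estimator maps one beat's noninvasive observables (PEP, ET, sBP, dBP) to
an ejection fraction through four steps.

1. **End-systolic pressure.** Pes = 0.205·sBP + 0.898·dBP + 0.4214 mmHg (the
   Kappus cuff regression). The constants are empirical and configurable
   (`CouplingConstants`); with the defaults and physiological inputs Pes lies
   strictly between dBP and sBP.

2. **Coupling ratio.** The ventricle's elastance rise is approximated
   bilinearly across the isovolumic-contraction and ejection phases; the
   ratio of the two slopes, k, is tied to coupling empirically as
   k = 0.53·x^0.51 with x = Ees/Ea. Combining the clamped-aorta peak pressure
   Pmax = Pad·(1 + k·ET/PEP) with Ees/Ea = (Pmax − Pes)/Pes and identifying
   Pad with cuff dBP yields the scalar root problem

       g(x) = (Pad/Pes)·(1 + 0.53·x^0.51·ET/PEP) − 1 − x = 0.

   Only the ratio ET/PEP enters, so the time unit cancels; the I/O layer
   nevertheless standardises on milliseconds and flags PEP outside
   [20, 400] ms or ET outside [100, 600] ms as implausible (warnings, not
   errors, and suppressible).

3. **Efficiency.** For a linear end-systolic pressure–volume relation through
   (V0, 0), external work EW = Pes·SV and pressure–volume area
   PVA = EW + ½·Pes·(ESV − V0) give Eff = EW/PVA = 1/(1 + 0.5·Ea/Ees).

4. **Ejection fraction.** EF = Eff/(2 − Eff). With r = SV/(ESV − V0) this is
   algebraically exact at V0 = 0 (Eff = 2r/(2r+1) ⇒ Eff/(2−Eff) = r/(r+1) =
   SV/EDV); for V0 > 0 it *overestimates* the volumetric EF, by an amount
   `pv_quantities`/`ef_shortcut_gap` computes exactly and which grows
   monotonically with V0. Note the direction: in vivo the echo EF *exceeded*
   the estimator (positive bias), which V0 alone cannot explain — the
   forward model makes that tension measurable rather than hiding it.

Absolute Ees and Ea are not identified by timing/pressure data alone (they
need volumes); only their ratio is estimated.

## Root solving

g is strictly concave on x > 0 because the exponent 0.51 lies in (0, 1), and
g → −∞ as x → ∞. In the physiological regime Pad < Pes, g(0⁺) < 0, so g has
zero or two positive roots. The solver restricts itself to the descending
branch: the maximiser x* = (A·c_k·p_k·ET/PEP)^(1/(1−p_k)) (A = Pad/Pes) is
available in closed form; if g(x*) < 0 there is no root and a `NoSolutionError`
reports g at the bracket ends. Otherwise Newton iterates from 1.0 with the
analytic derivative inside the maintained sign-change bracket [x*, high],
replacing any step that leaves the bracket by bisection — convergence is
therefore guaranteed. Defaults: tolerance 1e-10 on |g|, 100 iterations
maximum, bracket [1e-3, 50] (extended automatically, with a warning, if the
root lies beyond it). The *larger* root is returned deliberately: it is the
attracting fixed point of the natural iteration x ← A − 1 + A·c_k·(ET/PEP)·x^p
and matches observed cohort coupling (≈1.4 at the cohort means); the smaller
root implies implausibly low coupling. When Pad ≥ Pes (cuff artifact), the
single root is solved and flagged with a warning rather than failing, so
batch runs survive bad rows.

## Agreement statistics

Bland–Altman differences are oriented reference − test (echo minus estimate),
so an estimator reading low gives positive bias. Limits of agreement are
bias ± m·SD with m = 2 by default (m = 1.96 selectable); the SD uses the n−1
estimator. Percentage error is 100·2·SD(diff)/mean(reference), acceptable at
≤ 30%; it is invariant to expressing both series in percent or as fractions.
Pearson r (and r² — identical to the R² of a one-predictor regression) is
reported as NaN when either series is constant, without aborting the rest.
`summary_agreement` fills limits and PE from printed bias/SD/mean triples so
published summaries can be checked without subject-level data; from the
44-subject study's summaries (bias 8.5, SD 8.0, reference mean 66) it returns
a lower limit of exactly −7.5 and PE 24.2%. The printed upper limit there is
24.4 while 8.5 + 2·8.0 = 24.5 — an inconsistency of 0.1 presumably from
rounding of the underlying bias/SD, reported as computed, not adjusted.

## Synthetic cohorts

`sample_cohort` parameterises each subject by truth (coupling x, EDV, V0) and
*derives* everything else, so the generated data are internally consistent by
construction: ESV = (EDV − V0)/(1 + x) + V0 makes SV/(ESV − V0) = x exact, and
ET = PEP·((x + 1)·Pes/Pad − 1)/k(x) inverts the coupling equation so the
noiseless beat solves back to x exactly. Defaults emulate a healthy
young-adult screening cohort: x ~ N(1.5, 0.6²) truncated > 0.2,
sBP ~ N(119, 10²), dBP ~ N(72, 6²) with sBP > dBP enforced,
PEP ~ N(97, 14²) ms, EDV ~ N(120, 20²) mL, V0 = 0. Truncated normals are
drawn by rejection; a configuration whose rejection rate exceeds 20% raises
an error instead of silently distorting the requested distributions. Note the
truncation shifts the coupling mean slightly above 1.5 (to ≈1.52); tests
compare sample means against the truncated distribution's own expectation.

Two kinds of measurement noise are modelled, both optional: additive echo
noise on the EF scale (default SD 4 percentage points, a plausible
repeatability figure rather than an estimate from any dataset) and additive
timing noise on the derived ET (default 0 ms, keeping ground truth exact).
Echo noise acts on EF directly, not on volumes — the simplest structure
matching how echo EF dispersion is usually reported; volume-level noise would
be a natural extension.

One identifiability subtlety: a truth x just above the 0.2 truncation bound
can be the *smaller* root of its own beat's residual (it lies on the
ascending branch when x ≤ p_k·(1 − Pad/Pes)/(1 − p_k)), and the solver's
larger-root convention then cannot recover it. The generator rejects such
draws — including a small margin excluding near-tangency truths, where the
merging roots amplify the residual tolerance into an x error — about 1.5% of
the mass at the defaults. Consequently every emitted subject satisfies the
exact round-trip guarantee.

What passing simulation tests show — and what they do not: the synthetic
cohorts validate the algebra, the solver, and the noise propagation of the
agreement statistics. They share the estimator's own structural assumptions
(linear ESPVR, exact coupling relation, Pad = dBP), so they cannot detect
model misspecification in real subjects; in particular they reproduce the
in-vivo positive echo-minus-estimate bias only if one injects it, and V0 > 0
moves the bias the *other* way.

## Numerical choices and degenerate inputs

- Solver tolerance 1e-10 on the residual; round-trip recovery is then ≈1e-9
  in x away from tangency.
- ESV = V0 raises a degenerate-loop error (infinite elastance); ESV < V0 and
  inverted cuff pressures are invalid inputs naming the offending field.
- Failed rows in batch processing are flagged in the output table (error text
  in the `warnings` column, `converged` false), never dropped; the CLI exits
  nonzero if any row failed.
- Result tables print floats at 6 significant digits (configurable); fractions
  are converted to percent only in files and logs.

## Problem sizes

The test suite uses cohorts of up to 2,000 subjects, 10,000 random PV loops
for the identity checks and 1,000 randomized beats for the solver/oracle
comparison; the full suite runs in a few seconds on one core. The headline
acceptance computation is a single deterministic beat solve.

## Known limitations

- Pad ≡ dBP and the Kappus Pes regression are approximations of convenience;
  their error propagates directly into x.
- No curvilinear ESPVR, no time-resolved elastance E(t), no beat detection
  from raw waveforms, no within-subject beat-to-beat variability.
- The k–coupling relation's constants (0.53, 0.51) are cohort-derived
  empirics; the package treats them as configurable defaults, and results
  obtained with other populations may need re-calibrated constants.
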