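# Methods

## The problem

Lazertinib, a third-generation EGFR inhibitor, is cleared by glutathione
S-transferase Mu 1 (GSTM1). Roughly half of patients carry a homozygous
*GSTM1* deletion ("null" genotype) and expose about two-fold higher on the
fixed 240 mg once-daily (QD) dose than patients with a functional enzyme.
Because the approved dose places most patients far above the proposed
efficacy trough threshold of 0.0568 mg/L, genotype-guided dose reduction in
null patients (160 mg QD, or 240 mg every other day, QOD) can lower toxicity
and cost without compromising effective exposure.

The regulatory population-PK model that quantifies this is not public; what is
public is its simulated output: geometric means (GM) and arithmetic %CVs of
steady-state trough (Ctrough) and average (Caverage) concentrations for four
genotype × regimen scenarios, in Monte Carlo cohorts of virtual patients
(log-normal body weight, GM 70 kg, 20% CV; 1:1 sex; non-Japanese,
treatment-naive). This package inverts that published exposure surface into a
working model, then re-runs the whole simulation study: virtual
bioequivalence (GMR within 0.80–1.25 and the one-sided "not >20% lower"
criterion), threshold attainment, and annual drug cost at $728 per dosing
day.

## Structural model

A linear two-compartment disposition model with first-order oral absorption
(no lag), in apparent (CL/F, V/F) parameterization with F fixed at 1 — only
dose-normalized parameters are identifiable from oral summary data. The
single-dose solution is a three-exponential macro-constant form; the exact
periodic steady state under any repeating schedule follows by summing each
exponential's geometric series, so no ODE integration or run-in is needed.
The engine is validated against an independent ODE oracle to <1e-6 relative
error, and a one-compartment mode (Q = 0) is retained as a tested limit.

Two compartments are not optional here: the three published trough/average
shape ratios (non-null QD 0.553, null QD 0.665, null QOD 0.557) are mutually
inconsistent under one-compartment kinetics — the best attainable
one-compartment fit leaves ~10% trough residuals (frozen as a test) — while a
distribution phase plus a long terminal phase reconciles them. The feasible
disposition set collapses to a slow-absorption ("flip-flop", ka ≈ 0.1–0.2
h⁻¹) regime with a deep peripheral compartment, along a V1–V2 tradeoff on
which the predicted exposure surface is invariant. Parameter values are
therefore working values, not estimates of the regulatory model's parameters;
only the exposure predictions are meaningful.

## Covariate and variability model

Individual parameters follow conventional allometry on the typical values
(exponent 0.75 on CL and Q, 1.0 on volumes; reference 70 kg), the GSTM1-null
genotype multiplies clearance by a fraction calibrated below, and log-normal
random effects act multiplicatively. Sex, ethnicity, and pretreatment enter
as multiplicative hooks fixed at 1.0: the study simulates only non-Japanese
treatment-naive patients and reports no effect magnitudes, so the 1:1 sex
split has no PK consequence. Body weight is log-normal with geometric mean
70 kg and arithmetic CV 20% (σ_log = √ln(1+0.20²)); the clinical dataset's
63.1 kg median is deliberately not used — the study simulates the 70-kg
European population.

Random effects and why they are where they are:

* **ω_CL** (clearance) — solved in closed form from the Caverage CV, since
  Caverage = dose-rate/CL exactly: ln(1+0.425²) = ω_CL² + 0.75²·ln(1+0.20²),
  giving ω_CL = 0.379, consistent with the reported ≈37% clearance IIV.
* **ω_Q** (inter-compartmental clearance) — carries the *shape* variability
  that troughs exhibit on top of Caverage variability. The published trough
  CVs (64.1% non-null QD, 56.2% null QD, 64.0% null QOD) exceed what CL,
  weight, and central-volume variability can produce in the calibrated
  flip-flop regime (numerically: trough CVs saturate ~8 points low and are
  essentially insensitive to ω_V1 there). Terminal-rate noise — IIV on Q —
  has exactly the right scenario dependence (it amplifies with clearance ×
  dosing interval, reproducing both the genotype and the QOD orderings)
  without touching the Caverage CV. ω_Q is fitted by Monte Carlo to the four
  trough CVs.
* **ω_V** (central volume) — retained in the model with a small ridge in the
  fit; in the calibrated regime the trough surface is nearly indifferent to
  it and it fits to ≈0.

## Calibration pipeline (deterministic given a seed)

1. **Clearances, closed form.** CL/F = daily dose/(24·Caverage GM):
   57.5 L/h (non-null) and 32.3 L/h (null); their ratio fixes the GSTM1
   clearance fraction at 1/1.78 = 0.561 (the Caverage-derived value, not the
   nominal "two-fold" figure).
2. **ω_CL, closed form** (above).
3. **Disposition (V1, Q, V2, ka), bounded multi-start least squares** on the
   logs of three typical-individual troughs: non-null 240 QD, null 240 QD,
   null 240 QOD. The null 160 QD column is excluded — it is dose-linear in
   the null 240 QD trough and reserved as a held-out prediction. Bounds:
   V1 ∈ [20, 1000] L, Q ∈ [1, 100] L/h, V2 ∈ [100, 50000] L,
   ka ∈ [0.05, 3] h⁻¹, with a weak penalty (weight 0.003 on log ka toward
   0.4 h⁻¹) breaking the one-dimensional degeneracy.
4. **Shape IIV (ω_V, ω_Q), Nelder–Mead on a common-random-number Monte Carlo
   objective** (n = 20,000): summed squared error against the four trough
   %CVs plus the ω_V ridge.
5. **Population-GM correction.** The trough is nonlinear in the random
   effects, so with substantial ω_Q the cohort GM sits 3–11% below the
   typical-individual trough. An outer loop rescales the typical-scale
   trough targets by (published GM)/(simulated population GM), damped by
   exponent 0.8, and refits disposition warm-started and anchored (weight
   0.02 in log space) to the previous solution so refits stay on the same
   branch of the feasible manifold. Two rounds of [IIV fit → GM loop] are
   run; further IIV refreshes only creep ω_Q upward with negligible CV gain
   while destabilizing the loop. Convergence requires every calibrated
   population trough GM within 0.5% of its published value; the final model
   must hold all four trough CVs within 5 percentage points (achieved: ≤2.2).

Calibration runs in ~25 s on one CPU and is bitwise reproducible given its
seed (all Monte Carlo uses fixed substreams of a single `SeedSequence`).
The serialized model records the targets hash, seed, residuals, optimizer
trace, and bound hits.

## Endpoint definitions

* **Ctrough**: minimum of the periodic steady-state profile, evaluated on a
  grid that includes the exact pre-dose times (where the minimum of an
  absorption–elimination profile lies), so troughs are not grid-limited. By
  periodicity this equals the weekly minimum.
* **Caverage**: the per-period time average, computed analytically as
  (dose per period)/(CL·period). For QOD dosing a literal 168-h arithmetic
  mean would differ (168 h = 3.5 periods; ~1.4% high for the calibrated
  shape), but the published values obey the exact halving 0.155 = 0.310/2,
  identifying the published Caverage as dose-rate/CL. The whole-period
  quadrature identity is asserted in tests.
* **%CV**: arithmetic sample CV (SD with n−1 / mean).
* **GMR**: ratio of geometric means across *independent* cohorts (cohorts
  are drawn per regimen, as in the study design; a paired mode exists but is
  off by default). Equivalence: 0.80 ≤ GMR ≤ 1.25; non-inferiority:
  GM_test ≥ 0.8·GM_ref.
* **Threshold attainment**: fraction of patients with Ctrough strictly above
  0.0568 mg/L (ties are measure-zero under the continuous model).
* **Cost**: $728 per calendar day with ≥1 dose (same-day tablet combinations
  cost one dosing-day price), 365 days/year — hence $265,720/year for any
  daily regimen and half that for every-other-day dosing.

## Study simulation

Each scenario simulates an independent cohort (default n = 10,000 rather
than the study's 1,000: the GM Monte Carlo error at n = 1,000, ~2%, is
material against two-decimal GMR targets; n = 1,000 remains available via
the CLI, which widens its reproduction tolerances by the √(10000/n) Monte
Carlo factor). The global seed expands into per-scenario substreams keyed by
scenario identity, so adding or reordering scenarios never perturbs the
others' draws.

## What the generator does and does not emulate

It reproduces the covariate distribution the study states (log-normal 70 kg
weight, 1:1 sex, fixed genotype per arm) and a variability structure
sufficient to match all eight published GM/CV cells. It does not emulate:
real covariate effects of sex/ethnicity/pretreatment (magnitudes unpublished),
renal/hepatic function or age, within-patient (inter-occasion) variability,
residual assay error, nonlinear or time-varying clearance, absorption lag or
transit compartments, or any amivantamab interaction. Passing tests
demonstrate faithful reproduction of the published simulation study, not
predictive validity for real patients.

One distributional caveat: with ω_Q ≈ 1.1–1.2 the trough distribution is
left-skewed relative to a log-normal with the same GM and CV, so the
closed-form attainment Φ(ln(GM/thr)/σ_log) overstates the simulated fraction
by ~2–3 points in the QD scenarios. The closed form is therefore used as a
cross-check in the log-normal regime (ω_Q = 0), not as an estimator.

## Numerical choices

* ka within 1e-6 (relative) of a disposition eigenvalue is perturbed by
  2e-6 with a warning — avoiding the removable singularity rather than
  implementing the confluent limit.
* Eigenvalues use the product form β = k10·k21/α, stable in the Q → 0 limit
  (verified against the one-compartment closed form to 1e-9).
* Profile grid default 0.1 h (0.25 h in the vectorized cohort path, where
  the trough is read at exact pre-dose points anyway).
* Dose amounts are validated positive; composability from 80/240 mg tablets
  (i.e. multiples of 80 mg) is a queryable property rather than a hard
  invariant, since the linear engine is exercised at arbitrary doses in
  property tests.

## Known limitations

* Disposition parameters are non-unique by construction; only exposure
  predictions are identifiable, and the reported V1/Q/V2/ka must not be
  quoted as lazertinib parameter estimates.
* The GSTM1 fraction is treated as exact (1/1.78); no uncertainty in the
  published table is propagated (none is published).
* Trough %CVs reproduce to ~2 points, not exactly; the residual pattern
  suggests the regulatory model carries additional variability structure
  (e.g. on absorption or bioavailability with a different disposition shape)
  that summary data cannot identify.
* Cost analysis is maximal-savings arithmetic (full dosing for a year), not
  a cost-effectiveness analysis.
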