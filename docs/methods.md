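# Methods

## The model

`tce_qsp` simulates the pharmacodynamics of B-cell-targeting T-cell
engagers — a CD20/CD3 full-length bispecific antibody given as
intermittent IV boluses ("mosunetuzumab" in the code) and a CD19/CD3
BiTE given as continuous infusion ("blinatumomab") — with an ordinary
differential equation model of B- and T-lymphocyte population dynamics
in peripheral blood (PB), spleen (SP), lymph nodes (LN), bone marrow
(BM), and an optional lymphoid-tissue-embedded tumor (TU).

State variables per compartment: resting (Tr), activated (Ta), and
post-activated (Tp) CD8+ T cells and CD19+CD20+ B cells; additionally
CD20− pro-B cells in the BM, tumor B cells in the tumor, and one serum
IL6 pool. Drug concentration is not a state: it enters as a forcing
function of time, either interpolated measured samples (preclinical
mode) or an analytic linear two-compartment model (clinical projection
mode), with tissue levels equal to the plasma level times a fixed
partition coefficient.

### Fluxes

All fluxes are first-order mass action with, where needed, saturations
and deficit/excess gates:

* **Activation.** Drug bridges T cells to target-expressing B cells.
  The per-cell activation rate is Michaelis–Menten in local drug
  concentration with a Vmax that saturates in the local target-B:T
  ratio `r`:
  `a(C, r) = Vmax_max · r/(K_BT + r) · C/(EC50 + C)`.
  The target pool is drug-specific: mature (CD20+) B plus tumor B for
  the CD20/CD3 antibody; those plus BM pro-B for the CD19/CD3 BiTE.
  This lumps synapse formation and downstream signalling into two
  saturating factors rather than modelling receptor occupancy
  explicitly. With no T cells present but targets remaining, `r → ∞`
  and the rate saturates at `Vmax_max · C/(EC50+C)`. Post-activated
  cells can be reactivated by the same signal.
* **Proliferation.** Activated cells divide at `k_prol`, each division
  adding one net cell, a fraction `phi` of progeny activated and
  `1−phi` post-activated. Deactivation returns activated cells to
  resting (`k_deact_rest`) or post-activated (`k_deact_post`) states;
  post-activated cells convert slowly to resting (memory);
  activation-related apoptosis removes activated and post-activated
  cells.
* **Trafficking.** Every T subset leaves PB at a subset-specific rate,
  distributed over tissues by partition fractions, and returns at a
  subset-specific rate. Activated cells exit faster and partition more
  strongly to tissue than resting cells (enforced as an invariant on
  the exit rates and exit/return ratios). PB exit of all subsets is
  transiently amplified after every administration by an
  injection-stress factor `1 + s·exp(−(t−t_dose)/τ_s)` (default
  τ_s = 0.25 d), which produces the margination dip in circulating
  counts. Only activated cells are given access to the tumor
  compartment (see "Tumor" below).
* **Homeostasis.** Restoring fluxes are gated linearly on deficit,
  `max(0, 1 − X/X₀)`, or excess, `max(0, X/X₀ − 1)`: thymic generation
  of resting PB T cells, excess apoptosis of resting T cells, BM→PB
  B-cell migration, PB→spleen/LN B replenishment, and normal-tissue B
  proliferation. All gates are exactly zero at baseline, so the
  pre-therapy state returned by `initialize_baseline` is an exact
  equilibrium of every normal pool (verified by the 100-day drug-free
  drift test, < 0.01%).
* **B-lineage production.** Stem-cell precursors generate pro-B cells
  in the BM; pro-B mature into CD20+ B cells; BM B cells undergo
  homeostatic apoptosis. The generation rate and BM apoptosis rate are
  derived from the baselines (`g = k_mat·pB₀`, `k_apo = g/B_BM₀`)
  unless supplied explicitly, in which case an inconsistent value
  raises a configuration error naming the violated balance. BM→PB
  migration is gated on the PB B deficit — trafficking restores
  diminished pools and is silent at baseline.
* **Killing.** Activated T cells kill target B cells at
  `k_kill · C/(EC50_kill + C) · (Ta/V) · targets`; the per-capita rate
  scales with the activated-cell *concentration*, which makes potency
  independent of compartment size. Target pools follow the drug
  selector (the CD20/CD3 antibody spares pro-B cells).
* **Tumor.** Tumor B cells proliferate constitutively with doubling
  time DT; everything else about them (activation targets, killing,
  IL6 signal) follows the normal B-cell rules. The tumor compartment
  volume follows from the burden via a packing density (10⁹ cells/mL).
* **IL6.** Production is proportional to the local activation signal
  times the number of activated cells, `S_c = a_c · Ta_c`, summed over
  compartments with tissue terms down-weighted by `f_tiss < 1` (only a
  fraction of tissue-produced IL6 reaches the blood):
  `P = k_prod·(S_PB + f_tiss·Σ S_tissue)`. Serum IL6 follows
  `dIL6/dt = P/V_serum + k_el·(baseline − IL6)` with first-order
  elimination at a 2-hour half-life (`k_el ≈ 8.3/d`) and a constant
  basal production maintaining the baseline. This reproduces the
  first-dose phenomenon without any desensitization mechanism: once
  circulating B cells are depleted, PB activation ceases and later
  peaks reflect only the `f_tiss`-weighted tissue signal.

### Numerics

`simulate` integrates with LSODA (fallback BDF, then Radau) at
rtol 1e−8 / atol 1e−3 cells by default; population-scale work uses
rtol 1e−6 (halving either tolerance changes every reported observable
by < 0.1%). Dose times, infusion ends, and PK-sample knots are hard
integration restart points. The output grid carries 0.5-h resolution
for 48 h after every dose so IL6 peaks are resolved. States are clamped
at zero only inside the right-hand side for ratio/flux computation;
an output state below −1e−9 of the baseline scale raises an error
rather than being clipped. Every mechanism can be disabled
individually, which the tests use to check single fluxes against
closed forms (exponential tumor growth, trafficking conservation,
constant-production IL6) and the assembled reduced model against an
independent fixed-step RK4 integrator.

## Reference parameterization

No published parameter table is reproduced; the reference virtual cyno
in `tce_qsp.reference` is the package's own calibration target, set
once so a 3.5-kg cyno under 0.01–1 mg/kg weekly dosing shows the
canonical study conditions: >95% PB B-cell depletion within 24 h at
all doses, a margination dip then over-baseline rebound of circulating
CD8+ cells, dose-dependent %CD69+ and IL6 first peaks with the IL6
peak 2–6 h post dose, collapse of later IL6 peaks when B cells stay
depleted, and recurrent peaks when they recover (weekly short BiTE
infusions). Key defaults: activation `Vmax_max = 100/d`,
`K_BT = 0.5`; EC50s chosen so the clinically explored concentration
ranges are sub-saturating (5000 ng/mL for the antibody against C1D1
doses of 1.6–20 mg ≈ 450–5700 ng/mL initial concentration;
1.0 ng/mL for the BiTE against infusion steady states of
0.2–2.4 ng/mL) — saturated EC50s would erase the dose ordering of
first peaks that the regimen comparison rests on;
`k_kill = 6e−8 L/(cell·d)`; `k_prol = 1.6/d`, activation-related
death 0.9/d and activated tissue return 0.5/d, so net stimulated
activated-T growth is ≈ +0.2/d — close enough to zero that the
3-fold cohort perturbation produces both expanding (curing) and
fading (progressing) effector responses. PK defaults are antibody-like
for the CD20/CD3 drug (CL 0.8 L/d, V1 3.5 L at 70 kg; terminal
half-life of days) and BiTE-like for the CD19/CD3 drug (CL 45 L/d,
~2 h effective half-life); clearances scale allometrically with
exponent 0.75, volumes linearly.

## Synthetic data

The generator emulates the *structure* of the study inputs, not their
numbers: a multi-dose cyno study (3 dose groups × 4 animals, weekly ×4,
per-animal lognormal parameter jitter CV 15%, multiplicative lognormal
measurement noise CV 25%, sampling pre-dose/2 h/6 h/24 h post dose then
twice weekly, necropsy tissue B:T at last dose + 7 d) with ADA-driven
exposure loss in 4/4, 2/4, 1/4 animals per ascending group, emulated
phenomenologically as a 10-fold clearance step-up from day 7; and
clinical NHL targets — an 18-patient waterfall drawn from a response
mixture (17% CR, 20% deep PR, 23% minor/stable, 40% progression,
giving ~37% of patients a >50% reduction) plus optional IL6 envelope
curves. What the synthetic data do *not* carry: real between-animal
covariance structure, assay censoring (BQL values), dropout, or any
digitized values from published figures — so green tests demonstrate
pipeline correctness and self-consistency, not agreement with the
clinical trial numbers.

## Calibration

Weighted least squares on log-transformed counts and IL6 (floored at
1% of each analyte's scale) and arithmetic-scale percentages /100;
multi-start bounded trust-region least squares (`scipy`'s `trf`) with
rate constants searched in log space and a finite-difference step of
1e−2 in the internal coordinates — large enough to see through
solver noise at rtol 1e−6. Observations are averaged only over the
animals whose exposure matches the dose group's PK forcing (the
ADA-negative animals, or the whole group where all seroconvert), which
keeps the zero-noise loss exactly zero at the generating parameters.
Zero-noise recovery of up to four free parameters (Vmax, EC50, k_kill,
k_prol) lands within 5% of the generating values; with 25% CV noise
and n=4/group, within 30% when the dose groups span the saturation
range. The IL6 module (`k_prod`, `f_tiss`) is scaled separately
against step-up-infusion IL6 curves only; the constant-infusion
regimen is held out for validation.

## Virtual cohort and NHL population

Cohort candidates are local log-uniform perturbations of the reference
(default 3-fold for drug potencies and the cytokine module, 2-fold for
proliferation/death/trafficking of activated cells), accepted when
every observable stays within envelopes built from the across-animal
min/max of the synthetic study (×2 margin, ≥80% of points inside,
all-or-nothing). Candidates whose simulation fails are rejected with
the cause recorded. Acceptance runs the three multi-dose groups; a
held-out single-dose regimen reports validation coverage.

NHL patients are cohort members translated to human physiology
(volumes and baseline counts swapped; per-cell and dimensionless
kinetics preserved, so baseline concentrations match the human targets
exactly) and crossed with sampled disease variability: burden
log-uniform 10⁹–10¹¹ cells, doubling time 20–100 d, tumor B:T ratio
10⁵–10⁷, activated-T tumor access fraction 10⁻⁶–10⁻⁴, PB B/T baselines
jittered 3-fold. The B:T and access ranges are the package's own
choices (set once so simulated 8-week-infusion outcomes span
progression to complete response); only effector T cells infiltrate
the B-cell-dense mass. Importance weights match the end-of-treatment
% tumor change distribution to the target waterfall by
equal-probability bins with complete responses (−100%) as their own
bin and the responder cut (−50%) pinned as an edge, so the weighted
responder fraction reproduces the target's. An empty non-trivial
target bin raises rather than silently reweighting.

## Endpoint metrics

IL6 and %CD69+ peaks are taken per dose window (dose time to next
dose, or +7 d) on the dense grid; continuous infusions use explicit
windows (weekly for the step-up; first-48-h vs later for the constant
infusion, which defines the "first peak to largest subsequent peak"
ratio). Day-84 tumor change is floored at −100% below a detection
limit of 0.1% of baseline; responders are >50% reductions. Population
summaries are weighted 5/50/95 percentiles computed by inverse
weighted CDF with midpoint convention.

## Problem sizes

The analysis drivers and the acceptance script run at desk scale on
one CPU: a 10-member cohort (≈150 draws), a 200-patient population,
regimen comparison and the C1D1 dose envelope on 40–60-patient
subsamples. The same code paths scale to thousands of patients by
raising `n_cohort`/`n_patients`; nothing in the workflow is specific
to the small sizes.

## Known limitations

* No receptor-occupancy/trimer mechanism: drug effects are lumped into
  the two saturating factors, so predictions outside the calibrated
  concentration range extrapolate those forms.
* Proliferation of activated cells is not resource-limited; parameter
  draws with stimulated net growth far above zero produce unbounded
  T-cell expansion and are culled by envelope acceptance, not by the
  model itself.
* IL6 is the only cytokine; elimination is first-order with a fixed
  half-life; no desensitization or exhaustion mechanisms.
* ADA is a phenomenological clearance step, not an immune mechanism,
  and is absent from clinical projections.
* The linear two-compartment PK ignores target-mediated disposition;
  measured-PK forcing is the preclinical ground truth instead.
* Tumor volume is fixed at its baseline packing volume during
  regression (cell density, not geometry, changes).
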