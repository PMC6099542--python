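# Methods

`petkin` quantifies brain uptake of a TSPO PET radioligand from ROI-level
dynamic time-activity curves (TACs) and arterial plasma samples. This note
documents the models, the defaults and why they were chosen, the numerical
machinery, and what the synthetic cohorts do and do not emulate.

## Kinetic model

Tissue kinetics follow the reversible two-tissue compartment model driven by
the metabolite-corrected arterial parent-plasma concentration Ca(t):

    dC_ND/dt = K1·Ca − (k2 + k3)·C_ND + k4·C_S
    dC_S/dt  = k3·C_ND − k4·C_S

with influx K1 (mL·cm⁻³·min⁻¹), efflux k2, and exchange rates k3, k4
(min⁻¹) between the non-displaceable and specifically bound compartments.
The tissue impulse response is a sum of two exponentials with eigenrates
α₁,₂ = [(k2+k3+k4) ∓ √((k2+k3+k4)² − 4k2k4)]/2; the discriminant
(k2−k4)² + k3² + 2k3(k2+k4) is non-negative, so the eigenrates are always
real. When they coincide the confluent t·e^(−αt) form is used.

TSPO is also expressed on the vascular endothelium, so the model adds a
vascular-trapping pathway: an irreversible compartment fed from whole blood
at rate Kb (min⁻¹), weighted by the blood volume fraction vB alongside the
whole-blood signal itself:

    C_model(t) = (1 − vB)·(h ⊗ Ca)(t) + vB·[Cwb(t) + Kb·∫₀ᵗ Cwb ds]

No equation for the trapping term is standardized in the literature (some
implementations add it at tissue level rather than inside the vascular
weight); the convention above was fixed as a package design choice. Because
the same forward model generates and fits the synthetic data, recovery
results are insensitive to this choice.

Macroparameters: VT = (K1/k2)(1 + k3/k4) and BPND = k3/k4. The irreversible
Kb pathway is excluded from VT by construction (an irreversible compartment
has no equilibrium volume).

### Parameter defaults

| parameter | default | rationale |
|---|---|---|
| vB | 0.05 (unitless) | typical cerebral blood volume fraction; held fixed during fitting to preserve identifiability of Kb |
| k4 (generator) | 0.05 min⁻¹ | only the k3/k4 ratio is reported for this tracer; any positive k4 preserves the ratio and VT, one value is pinned for reproducibility |
| whole blood / plasma ratio | 1.0 | no hematocrit or blood-to-plasma data available; configurable |
| fit bounds | [0, 10] on each rate | generous physiological envelope |
| fit starts | 0.01, 0.1, 1.0 (all rates) | deterministic log-spaced multi-start; an explicit initial guess replaces the start list |
| weights | frame duration, normalized | proxy for count-statistics precision (longer frames accumulate more counts) |

## Parent-fraction (metabolite) model

Only intact tracer follows the compartmental kinetics. The unmetabolized
fraction in each compartment is modelled with an integrated Hill curve

    PF(t) = 1 − a·tⁿ/(tⁿ + t50ⁿ)

which enforces PF(0) = 1, is monotone non-increasing, and plateaus at 1 − a.
This 3-parameter form is standard in PET metabolite modelling and can
interpolate the three measured plasma fractions (85% at 15 min, 60% at
30 min, 35% at 120 min) essentially exactly. The brain curve has only two
measured points (96% at 15 min, 77% at 120 min), so the exponent is pinned
at n = 2 and (a, t50) are solved. Calibration is nonlinear least squares
with a ∈ [0, 1] and positivity enforced by fitting log t50 and log n.

Brain TACs are corrected frame-by-frame: value × PF_brain(frame mid-time).
Plasma samples are corrected sample-by-sample before input-function
construction. Extraction recovery of the radio-HPLC workup is taken as
100% (an optional multiplicative recovery factor is exposed in code).
The plasma parent-fraction curve is treated as a population curve
(terminal arterial sampling precludes per-animal curves); per-subject
curves can be supplied through the same interface.

## Input function

The continuous Ca(t) is piecewise linear between corrected plasma knots,
with a (0, 0) knot inserted when sampling starts after injection, and a
mono-exponential tail beyond the last knot fitted by log-linear regression
on the last three knots (robust to single-sample noise). Measured cohorts
whose first sample is at 5 min — after the input peak — inherit a known
bias from the linear rise; the synthetic generator therefore includes early
knots at 0.25, 0.5, 1 and 2 min. No dispersion or delay correction is
applied.

## Numerics

* Internal time unit: minutes everywhere (rates are min⁻¹); CSV frame
  columns use seconds and are converted at the I/O boundary.
* The forward model is evaluated on a uniform grid with step 1/120 min
  (0.5 s). Every frame duration and sampling knot in the default design is
  a multiple of 0.5 s, so input-curve kinks and frame boundaries lie
  exactly on the grid; the step gives 10 points per 5-s frame.
* Exponential convolutions use an analytic piecewise-linear recursion
  (first-order IIR filter), which is exact for piecewise-linear inputs —
  no quadrature error in the convolution itself.
* Frame averages are computed from analytic running integrals: each
  convolution y obeys y′ = f − αy, so ∫y = (F − y)/α with F the exact
  integral of the piecewise-linear input; double integrals of the inputs
  use the exact per-cell formula. Halving the grid step changes frame
  values at the 10⁻⁶ relative level.
* Degenerate cases: k2+k3+k4 = 0 turns the tissue response into a pure
  integrator; k4 = 0 collapses one eigenrate to zero (handled as an
  integrator term); exact eigenrate coincidence uses the confluent form.
  All are continuous limits of the general case (tested by perturbation).
* The fitter is bounded trust-region least squares. Standard errors come
  from the scaled inverse Gauss–Newton Hessian,
  se² = diag[(JᵀWJ)⁻¹]·WRSS/(N − p); parameters in the numerical null
  space of J get infinite %SE (and therefore fail the quality filter).
  WRSS ties between starts are broken by the lowest K1.
* Goodness of fit is reported by machine checks (convergence flag, WRSS,
  Wald–Wolfowitz runs test on residuals) rather than visual inspection.

## Quality filtering and statistics

A subject is excluded when any of the five fitted parameters has
%SE = 100·se/|estimate| above the threshold (default 50%) or the fit did
not converge. Group comparisons use Welch's unequal-variance t-test:
one-sided (LPS > control, the study's directional hypothesis) for kinetic
parameters, two-sided for regional AUC, mirroring how each comparison is
conventionally reported. No multiple-testing correction is applied. AUC is
the trapezoid over frame mid-times (seconds) anchored at (0, 0), with the
last frame value held to the end of the acquisition so the full 7200-s
interval is covered; units %ID/g·s.

## Synthetic cohorts

The generator emulates a control vs. LPS mouse study: 8 control + 7 LPS
subjects; per-subject K1, k2, k3/k4 and Kb drawn from the published group
means and SDs via zero-truncated normals (kinetic rates are positive);
tissue TACs on the 25-frame, 120-min schedule (12×5 s, 4×60 s, 2×300 s,
7×900 s); a tri-exponential plasma curve rising to a peak near 0.4 min and
scaled so the control whole-brain TAC peaks near 3 %ID/g (the tracer's
reported 2–4 %ID/g brain extraction); measured TACs include the brain
metabolite signal (parent / PF_brain), so the correction stage is exercised
non-trivially; Gaussian frame noise with sd = noise_scale·√(value/duration)
approximates count statistics, with noise_scale = 0.19 chosen so the late
900-s frames have ~5% CV. Everything is deterministic given
(base_seed, subject index).

What the generator does **not** emulate: image reconstruction and
partial-volume effects, correlated frame noise, per-animal input-function
variability (a single population plasma curve is shared), regional
heterogeneity (one whole-brain region by default), radioactive-decay
bookkeeping (curves are assumed decay-corrected), and any LPS effect on
blood-brain-barrier permeability beyond what the published group parameter
distributions encode. Passing recovery tests therefore demonstrates
internal consistency of the estimation chain under realistic counting
noise — not robustness to the systematic errors of real imaging data.

A consequence of the declared conditions worth knowing: at the default
noise level the %SE filter excludes more synthetic subjects than the real
study excluded, because the control group's k3 (= 0.34 × 0.05 =
0.017 min⁻¹) is barely identifiable from a 120-min acquisition at ~5% late
frame CV. This is a property of the simulated design, not a bug in the
filter; real data evidently carried more information about the specific
binding compartment than the synthetic noise model grants.

## Known limitations

* k3 and k4 are fitted separately but only their ratio (BPND) and VT are
  well identified; per-subject k3, k4 estimates should not be interpreted
  individually.
* The optimizer, weighting and initialization of the original commercial
  analysis software are unpublished, so per-animal results from real
  studies are not expected to be bit-reproducible — only the method's
  self-consistency is testable.
* The exponential input tail assumes monotone late decay; non-decaying
  tails fall back to a flat extrapolation with a warning.
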