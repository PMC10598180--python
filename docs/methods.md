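# Methods

This note documents the model, the statistical machinery, the synthetic
study design, and the numerical choices made in `murinecv`, together with
their known limitations.

## The closed-loop model

**Sarcomere mechanics.** Each of the five heart walls (LA, LV free wall,
RA, RV free wall, septum) carries a lumped sarcomere. Sarcomere length
maps exponentially from the natural myofiber strain,
`L_s = L_s,ref exp(eps_f)` with `L_s,ref = 2.0 um`. A contractile element
of length `L_sc` shortens against a series elastic element:

    dL_sc/dt = ((L_s - L_sc)/L_s,iso - 1) v0,

so the series stretch rests at its isometric value `L_s,iso = 0.04 um` and
collapses at the unloaded shortening velocity `v0` (12 um/s ventricular,
24 um/s atrial). Activation `Gamma` integrates a calcium-like rise,
`Psi_rise = C_L(L_sc) F_rise(t)/tau_rise` with
`F_rise = 0.02 x^3 (8-x)^2 e^-x`, `x = min(8, t/tau_rise)` and the
length-dependence `C_L = tanh(4 (L_sc - L_sc,0)^2)`, plus a gated decay
toward the resting value `Gamma_rest = 0.02` whose logistic gate opens
around the length-dependent systole duration
`T(L_sc) = tau_sys (0.29 + 0.3 L_sc)`. Active stress is
`G_act = sigma_act Gamma (L_sc - L_sc,0)((L_s - L_sc)/L_se,iso)`; passive
stress is the sum of two power laws in the passive stretch
`lambda = (L_s,ref/L_s,pas,ref) exp(eps_f)` (extracellular-matrix exponent
10, titin exponent 6).

**Ventricular geometry (three-segment construction).** LV free wall,
septum, and RV free wall are spherical caps sharing a junction circle of
radius `y_m`; the septal cap volume `V_m,S` (signed, positive bulging
rightward) and `y_m` solve the axial and radial tension balance at the
junction. Cap kinematics follow the canonical spherical-cap relations
(`V_m = (pi/6) x (x^2 + 3 y^2)`, `A_m = pi(x^2+y^2)`,
`C_m = 2x/(x^2+y^2)`); the cap height is obtained in closed form
(Cardano), so the geometry itself needs no iteration. Strain is the areal
form `eps_f = 1/2 ln(A_m/A_m,ref) - z^2/12 - 0.019 z^4` with
`z = 3 C_m V_wall/(2 A_m)`.

*Tension convention.* The representative midwall tension is taken as the
membrane tension of the thin shell,

    T_m = (V_wall G / A_m)(1 + z^2/3 + z^4/5),

with junction components `T_x = T_m 2xy/(x^2+y^2)`,
`T_y = T_m (y^2-x^2)/(x^2+y^2)` and transmural pressure
`p_trans = 2 T_x / y_m = 2 T_m C_m`. This normalization is pinned by the
thin-shell limit: a uniformly stressed sphere reproduces the Laplace law
`p = 2 h G / r` (tested to 5% for h/r <= 0.1). Published variants of the
three-wall construction differ in where a factor of two sits between the
tension definition and the pressure law; the junction force balance is
invariant to that common factor, so only the stress-to-pressure gain is
affected, and the Laplace limit is the physically checkable anchor we
adopt. Atria are single spherical walls with the same sarcomere law on an
activation clock advanced by `tau_offset,A = 0.18 T` (atria contract
first).

**Pericardium.** All four chambers feel a common external pressure
`p_peri = exp(k_peri (V_heart/V_0,peri - 1))` kPa, with `V_heart` the
total *blood* volume of the four chambers. Using cavity volume (rather
than cavity plus wall) is required for internal consistency with the
published per-animal `V_0,peri` estimates (~0.15-0.18 mL): with wall
volume included, those values would either clamp the ventricles far below
physiologic end-diastolic volumes or drive the exponential to hundreds of
kPa. `k_peri` is treated as dimensionless with an implicit 1 kPa
prefactor.

**Circulation.** Eight compartments (four chambers; systemic and
pulmonary arteries and veins) exchange blood through linear resistors;
vascular pressures are `p = (V - V_un)/C`. The four cardiac valves and a
vena-cava inlet valve are diodes passing flow only down a positive
gradient. Flow is oriented upstream-minus-downstream throughout. The
closed loop conserves total blood volume exactly (the volume derivatives
telescope).

## Numerics

The 18 differential states (8 volumes, 5 contractile lengths, 5
activations) are integrated with a fixed-step classical Runge-Kutta
scheme, 800 steps per beat, recording 200 uniform samples per beat. The
two ventricular-geometry constraints are solved by a damped Newton
iteration inside every right-hand-side evaluation (absolute residual
tolerance 1e-9 kPa cm), warm-started across evaluations and carrying its
Jacobian forward with staleness control so that most solves need no fresh
finite differences.

Three efficiency devices, all validated against brute-force runs at 4x
the step count:

- **Systolic sub-stepping.** While any wall's activation exceeds 0.05 the
  step is subdivided (6x during atrial systole, 3x during ventricular
  systole): the series elastic element makes the cavity
  pressure-volume coupling stiff in systole, and the near-empty murine
  atria are the stiffest elements in the system.
- **Smoothed valves.** Diodes are clamped with the smooth surrogate
  `q = (dp + sqrt(dp^2 + eps^2))/(2R)`, `eps = 0.02 kPa` (0.15 mmHg);
  the hard clamp chatters under fixed-step integration during ejection.
  The surrogate is strictly positive, so the valve-flow non-negativity
  invariant holds at every sample.
- **Beat-map acceleration.** Beats are iterated to a periodic steady
  state (max relative change of the state at beat onset < 1e-4, at most
  100 beats). The slow mode is venous volume redistribution
  (`R_sys C_sv` ~ tens of beats), so an Aitken/secant extrapolation of
  the beat-onset map is applied along the dominant direction, and early
  transient beats run at half the step count. The convergence check and
  the recorded beat always use the full resolution.

Initialization places the vasculature at nominal operating pressures,
sizes the chambers from their reference areas inside the pericardial
budget, and assigns the volume balance to the systemic veins; the two
re-start fallbacks (cold start; doubled step count) make the Morris
corner cases robust.

For finite-difference sensitivities the periodicity tolerance is
tightened to 1e-5 (max 300 beats): at 1e-4 the steady-state detection
noise decorrelates nearly-collinear sensitivity columns and deflates the
Fisher-matrix condition number by about an order of magnitude.

## The synthetic study

Ground-truth "mice" take the three published per-animal calibrated
estimates for the 11-parameter identifiable subset and nominal values
elsewhere. Conditions with no reference value were fixed once, on
physiological grounds, and are recorded here:

- wall masses LA/RA 5 mg, LV+septum 62 mg (split 2/3-1/3), RV 17.4 mg;
- circulating volume `V_total = 1.25 mL`, period `T = 0.11 s`;
- hemodynamic summary for the nominal rules: CO 0.3 mL/s, systemic
  arterial peak 13.3 kPa, capillary pressures 2.0/1.33 kPa, venous means
  0.5/1.0 kPa, stressed volumes 0.10/0.05/0.03/0.05 mL;
- unstressed vascular volumes 0.10/0.44/0.03/0.05 mL (fixed).

The masses and blood volume were chosen so the baseline beat is
physiologic for an anesthetized mouse *and* consistent with the published
estimates: end-diastolic sarcomere length ~2.2 um, peak LV pressure
~75-90 mmHg, ejection fraction ~0.43, longitudinal shortening 8-13% in
all three ventricular walls, baseline pericardial pressure 2-4 mmHg. At a
1.0 mL blood volume the loop starves (CO ~0.1 mL/s, p_SA ~45 mmHg), which
is inconsistent with the published systemic resistance; at compressed
sarcomere lengths the activation length-dependence mutes the contractility
parameter, contradicting the reference sensitivity ranking. One known
idiosyncrasy is accepted: left-atrial pressures run high (~15-20 mmHg),
a consequence of the fixed valve-resistance rules and the small, stiff
atria at their tabulated reference areas.

The acquisition emulator replays the converged beat at 500 Hz over many
beats with multiplicative period jitter (CV 2%), adds independent
Gaussian noise per signal (pressures 0.13 kPa, arterial 0.27 kPa, volumes
2 uL), and delays the volume channels circularly by 3 samples
(conductance-catheter placement). What it does **not** emulate: baseline
drift, calibration bias, beat-to-beat contractility variation, catheter
whip, or any model discrepancy — the data generator and the fitted model
share the same physics, so passing recovery tests demonstrates pipeline
correctness, not robustness to model misspecification.

**Preprocessing.** Signals are smoothed with a unit-sum Gaussian window
(factor 0.05 of a few-beat segment, i.e. 11 points for typical murine
beat lengths, kernel sd (w-1)/5, reflective boundaries); beats are
segmented at smoothed LV-pressure minima (dominant period from the
autocorrelation); each beat's volume channels are rolled so maximal
volume meets the pressure upstroke (max dp/dt); beats are resampled to a
common 200-sample grid, anchored on their own upstroke (the segmentation
minima sit on a flat pressure segment, so their noise jitter would smear
the ensemble mean), and averaged pointwise. The averaged *calibration*
waveform is built from the raw segmented beats — smoothing drives only
the detection steps — because averaging already suppresses noise and a
smoothed product would correlate residuals (see Limitations).

**Observation operator.** Model beats are compared with data after
passing through the same acquisition chain: linear sampling at the
recording rate, resampling back to the beat grid, and phase profiling.
The segmentation phase of a measured beat is arbitrary, so the model beat
is rotated onto the data by circular cross-correlation of LV pressure
(sub-sample refined; smooth in the parameters, unlike an argmax anchor);
the volume channels, which carry their own catheter phase that the
pipeline re-anchors, are profiled the same way.

## Screening and identifiability

Morris screening uses the classic radial-trajectory design (4 levels,
step 2/3 in unit-scaled space, default 100 trajectories, seed 20230715)
over +/-20% bounds around the nominal values, in natural space. A time
series is scalarized per output stream as the beat-normalized L2 distance
between perturbed and base waveforms divided by the step; the combined
index is `M = sqrt(mu*^2 + s^2)` and a parameter is fixed when `M` falls
below the across-parameter mean for all five outputs. Trajectories
containing a failed simulation are dropped with a warning.

Local identifiability uses dimensionless centered differences at relative
step 0.01 on the log-parameters (each row scaled by the baseline output,
floored at 1e-6 of the stream range), stacked over the five streams;
`F = S^T S` approximates the Fisher information, and while
`cond(F) > 1e5` the parameter with the smallest sensitivity-column 2-norm
is fixed and the condition number recomputed on the remaining columns.

On the preset-1 synthetic mouse this pipeline fixes 19-21 of the 38 free
parameters (count varies slightly with the screening seed), always
retaining the full published 11-parameter subset; the retained-set
Fisher matrix is ill-conditioned (condition number ~1e7), and the
reduction terminates at exactly 11 parameters. One systematic
substitution relative to the published subset is observed: the
ventricular shortening velocity `v0_v` survives in place of the pulmonary
resistance `R_pulm`. In this realization the ventricles operate near
their shortening-velocity limit (making `v0` locally influential), while
pulmonary-venous pressure carries a larger share of pulmonary-arterial
pressure than in the reference animals (muting `R_pulm`); the two
column norms differ by less than a factor of two, so the substitution sits
on the margin of the removal rule.

## Calibration and uncertainty

The likelihood is the exact independent-Gaussian form with one error
variance per stream, `-LL = sum_i [(N_i/2) ln(2 pi sigma_i^2) +
RSS_i/(2 sigma_i^2)]`, minimized over natural-log parameters of the
subset. At fixed variances this is weighted nonlinear least squares,
solved by damped Gauss-Newton (Levenberg-Marquardt damping, line-limited
steps) with one-sided finite-difference Jacobians kept current by Broyden
rank-one updates and refreshed on stagnation; because reweighting changes
only the weights — never the model Jacobian — the Jacobian is reused
across the iteratively-reweighted outer loop (variance refresh
`sigma_i^2 = RSS_i/N_i`, floored at 1e-12 of the stream variance). The
outer loop stops when the log-parameters move by < 1e-6 and the variances
by < 1e-4 relative (max 20 iterations). A quasi-Newton (BFGS) inner path
is retained as an option; the Gauss-Newton path reaches the same optimum
in roughly a fifth of the model evaluations, which is what makes the
20-replicate study tractable. A failed forward simulation inside the
optimization returns a large-but-finite penalty so line searches back
away gracefully.

Asymptotic uncertainty follows the standard frequentist construction:
`C = (S^T Sigma^-1 S)^-1` with `S` the observed-model Jacobian with
respect to the log-parameters at the optimum, two-sided t quantile with
`N_tot - N_par` degrees of freedom; log-scale parameter intervals are
exponentiated (hence asymmetric in natural units); pointwise response
confidence bands use `s_t^T C s_t` and prediction bands add the sample's
stream variance, so the prediction band contains the confidence band
everywhere.

## Acute LV ischemia

Ischemia multiplies the calcium-driven activation rise of the LV free
wall by `gamma in (0, 1]`; the septum and RV are untouched (configurable).
`gamma` is calibrated by bisection on [0.01, 1] until the relative LV
ejection-fraction drop matches a target (tolerance 0.01). At the drop
matching the preset-1 animal (60%), the model reproduces the expected
qualitative picture of acute LV ischemia: LV dilation with a rightward loop shift, reduced
stroke work in both ventricles, an upward LA-loop shift of ~2 mmHg, a
pericardial pressure rise of ~2 mmHg, weakened LV strain with increased
septal strain, and an inversion of the LV pressure-sarcomere-length loop
orientation as `gamma` falls below ~0.2.

## Limitations

- **Parameter-interval coverage.** Across synthetic replicates the
  calibrated estimates scatter 2-4x wider than the asymptotic iid
  intervals predict, so nominal 95% parameter CIs cover the ground truth
  far below nominal. The causes are structural, not algorithmic:
  residuals on the beat grid are correlated (55 native samples per beat
  against a 200-sample grid; period jitter perturbs the averaged
  waveform coherently), so the iid information count overstates
  precision. Restart experiments confirm the optimizer sits at the
  optimum and that a fit started at the truth stays there. The package
  reports the intervals exactly as the asymptotic theory defines them and
  leaves the corresponding acceptance check red; the independence
  assumption is a documented limitation of this class of analysis.
  Prediction intervals, which are dominated by the estimated observation
  variance, cover held-out samples at close to their nominal level.
- Subset-selection composition is seed- and regime-sensitive near the
  below-mean cut and the removal margin (see the `v0_v`/`R_pulm`
  substitution above).
- The synthetic animals share the model's physics; no model-discrepancy
  term is included anywhere.
- Atrial nominal timing uses the tabulated rule `tau_decay,a = 0.005 T`
  verbatim, which yields an extremely fast (0.55 ms) atrial relaxation;
  the integrator resolves it by sub-stepping, but it is the stiffest
  element of the system.
- No baroreflex, remodeling, inertances, or regional infarct geometry.
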