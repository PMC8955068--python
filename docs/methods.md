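# Methods

This note documents the statistical procedures, the synthetic-data
generators and the numerical choices made where the design was open.

## Box–Behnken design and coding

The three-factor Box–Behnken design consists of the 12 permutations of
(±1, ±1, 0) — the midpoints of the factor-cube edges — plus replicated
centre points (5 by default, giving 17 runs). Generated designs store the
coded levels exactly as −1/0/+1 integers so orthogonality checks carry no
float drift; the canonical row order is lexicographic over (index of the
zero coordinate, signs of the active pair), centres last. Published run
tables arrive in arbitrary order, so design identity is checked as a row
set, not a sequence. Coding is affine: `coded = (actual − mid)/half-range`,
with its exact inverse; values outside [−1, 1] are permitted (extrapolation
is the caller's decision and `predict` guards at |coded| > 1.2).

## Response-surface models

Responses may be modelled on a transformed scale: identity, √y (variance
stabilisation for sizes), or 1/y (for percentage responses approaching an
asymptote). The transform is fixed per response — there is no Box–Cox
search. Ordinary least squares is delegated to `statsmodels.OLS` on the
coded model matrix; everything downstream of the coefficients is computed
in-package because the Design-Expert-style panel is not available there:

* **Type III ANOVA** — each term's F comes from the drop-one (partial) sum
  of squares at fixed remaining terms. On the orthogonal linear block of a
  Box–Behnken design these equal the sequential sums of squares, a built-in
  cross-check.
* **Lack of fit** — the residual SS is partitioned into pure error (within
  groups of runs sharing identical coded settings, computed on the
  transformed scale) and lack of fit, with df partitioned accordingly.
  Designs with no replicate groups report lack of fit as unavailable
  rather than zero.
* **R² family** — predicted R² uses PRESS via the leave-one-out identity
  `e_(i) = e_i/(1 − h_ii)` with the hat diagonal from the fitted model.
* **Adequate precision** — the signal-to-noise ratio
  `(max ŷ − min ŷ)/√(p·MSE/n)` over the *design points* (the fitted-value
  range, not the cube-corner range; the fitted-range definition reproduces
  the published panel value 64.30 for the size model).
* **%CV** — `100·SD/mean` of the *transformed* response, matching the
  transformed-scale diagnostics of the rest of the panel.

Model reduction is backward elimination: repeatedly drop the term with the
largest partial-F p-value above α (default 0.05), refitting after each
removal, never touching the intercept and preserving weak heredity (a
linear term cannot leave while its square or any interaction containing it
remains). On the embedded entrapment data this path removes the x2·x3 and
x1·x2 interactions and retains exactly the published reduced-quadratic term
set.

A closed-form oracle is exposed for linear fits on a Box–Behnken design
(`closed_form_linear_fit`): each linear column has sum of squares 8, so
`b_j = (Σy|x_j=+1 − Σy|x_j=−1)/8` and the intercept is the mean transformed
response. Tests require agreement with the OLS path to 1e−9.

## Desirability optimization

Individual desirabilities are one-sided Derringer ramps clipped to [0, 1]
and raised to a weight exponent (default 1); the overall score is the
geometric mean. Default anchors are each response's observed min/max over
the design — the convention of the originating software — and are
configurable because published analyses rarely state them. The zeta
potential is modelled but excluded from the objective (no factor affects it
significantly in the embedded study). The search is fully deterministic: a
41³ grid scan over the coded cube followed by a Nelder–Mead polish with
coordinate clipping and tolerance 1e−6. Ties in D break by smaller
predicted value of the first minimize-goal response, then lexicographic
coded point. Candidate points where the back-transform is undefined
(non-positive √y or 1/y predictions) score D = 0 and are logged.

On the embedded study this lands at oleic acid = 30 mg (its high bound)
with D = 0.811. The published optimum reports D = 0.84; evaluating the
published model equations at the published optimum yields ≈ 0.80 with
min/max anchors, so the residual gap reflects the original software's
undisclosed anchors/precision, not the search. Accordingly the tests pin
the high oleic-acid bound and a D band of [0.78, 0.86] rather than point
identity, and predicted responses at the published optimal point to within
1.5%.

## Release and permeation

Cumulative amount per area with sample replacement is
`Q(t_n) = [C_n·V_receptor + Σ_{i<n} C_i·V_sample]/area`; without
replacement the sum term is dropped. Steady-state flux is the least-squares
slope of Q versus t; the default window excludes only the first sample
(lag-dominated), and is configurable since "steady-state portion" is rarely
defined operationally. `P_app = J_ss/C0` requires the donor concentration
explicitly.

Two constants in the embedded permeation fixture are back-derived rather
than protocol-stated, because the published geometry is internally
inconsistent (a 2.5 cm² cell and 3 mg dose versus cumulative/percent pairs
implying 600 µg/cm²): the default configuration uses a dose per area of
600 µg/cm² (= 472.8/0.788) and a donor concentration of 1000 µg/mL (the
ratio common to both published J_ss/P_app pairs). Both are explicit,
overridable config fields, never silent assumptions.

## Non-compartmental analysis and targeting

AUC(0–t) uses the linear trapezoid over observed points with no
extrapolation beyond the last observation; an end time falling inside an
observed interval is handled by linear interpolation at that time, which is
what keeps the rule additive over adjacent intervals. The terminal rate K_e
is minus the slope of ln C versus t over the last n positive observations
(default n = 3, configurable — published analyses rarely state the window),
exact for noiseless mono-exponential decline on any grid; t½ = ln 2/K_e is
always derived from the unrounded K_e, since published K_e/t½ pairs are
typically inconsistent after rounding. Brain/blood concentration ratios are
taken at shared observation times only (no interpolation by default).

DTE% is the ratio of intranasal to intravenous brain/blood AUC quotients
× 100; DTP% subtracts from intranasal brain exposure the part predicted by
systemic redistribution, `Bx = (AUC_brain/AUC_blood)_IV · AUC_blood,IN`.
The identity `DTP = 100·(1 − 100/DTE)` holds algebraically and is asserted
in tests. Both statistics are invariant to a common rescaling of all
concentrations.

## Synthetic-data generators

**Formulation studies.** True response surfaces are specified by
coefficients on the transformed scale; Gaussian noise is added on that
scale (where the fitted model assumes homoscedasticity) and
back-transformed. Draws falling outside the back-transform's domain are
re-drawn with a warning, with a retry cap. At zero noise the fit recovers
the generating coefficients to machine precision.

**Pharmacokinetics.** A linear disposition model solved in closed form:
IV blood is a bolus mono-exponential `C = (D/V)·e^(−kt)`; IN blood is
first-order absorption (rate k_a) of the dose fraction not taken by the
direct pathway; brain follows `dB/dt = k_in·C_blood − k_out·B` plus, for
IN, a first-order input (rate k_d) of the direct-fraction (f_direct) depot.
Every signal is a sum of exponentials, so sampled profiles and exact AUCs
(to any horizon or infinity) come from closed form — a deliberate choice
over a generic ODE stepper so that zero-noise round trips are exact (for
f_direct = 0 the analytic AUC ratios give DTE = 100 identically). The
closed form requires pairwise-distinct rate constants; coincident rates
raise an error rather than switching to the degenerate `t·e^(−kt)` branch.
Concentration noise is multiplicative log-normal with mean 1 at a stated
CV, keeping levels positive.

Default parameters are illustrative, chosen to emulate the qualitative
pattern of the embedded study: a 1125 µg dose (5 mg/kg in a ~225 g rat),
blood elimination 0.017 min⁻¹ with k_a = 0.009 min⁻¹ (flip-flop kinetics,
so the IN terminal slope is the absorption rate, matching the published
route-dependent terminal slopes), k_out = 0.005 min⁻¹, and
k_in/V_brain set so the brain/blood AUC ratio is ≈ 0.24 for IV and > 1 for
IN at f_direct = 0.3. Sampling uses the study's 10/30/60/120/240/480 min
grid by default (configurable, since the original sampling scheme is
ambiguous between protocol and narrative). These defaults reproduce
orderings and magnitudes, not the published curves, which exist only as
figures.

What the simulators do **not** emulate: inter-animal variability beyond a
single noise CV, assay error structure (LLOQ censoring), nonlinear
clearance, or enterohepatic/mucociliary processes. Passing round-trip tests
therefore demonstrates correctness of the estimators under the stated
model, not predictive validity for real tissue data.

## Problem sizes and determinism

All analyses run in seconds: 17-run fits, 41³ grid scans, six-point PK
profiles, 200-replicate sampling-theory checks. Every stochastic component
takes an explicit integer seed (`numpy.random.default_rng`); identical
seeds reproduce tables bit-for-bit. CSV writers emit the shortest
round-trippable float form and readers parse with round-trip precision, so
write→read is lossless.

## Known limitations

* Only the 3-factor Box–Behnken family is implemented (no central
  composite, no blocking), and only one-sided desirability ramps (no
  target/in-range goals).
* AUC extrapolation to infinity from observed data, compartmental fitting,
  and release-kinetics models (Higuchi etc.) are out of scope.
* The reduced-model elimination path is the standard backward procedure;
  other software may reach a different retained set when p-values are
  near α.
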