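# Methods

## Structural model

The tumor is modeled as two compartments. The proliferative compartment
*P(t)*, identified with the 3-D bioluminescence signal (photons/sec), grows
logistically with proliferation rate *a* (day⁻¹) and carrying capacity *K*
(photons/sec); cells that lose the competition for space and nutrients move
to a necrotic compartment *N(t)* at the logistic loss rate *aP²/K*. Necrotic
tissue stops emitting light but keeps contributing to the caliper-measured
volume, so the total volume signal is *V = P + N*:

    dP/dt = a P (1 − P/K),   P(0) = P0
    dN/dt = a P² / K,        N(0) = 0

Both equations have closed forms:

    P(t) = K / (1 + (K/P0 − 1) e^{−a t})
    N(t) = K ln(1 + (P0/K)(e^{a t} − 1)) − P(t) + P0

validated in the test suite against adaptive numerical integration to 1e-6
relative over a ∈ [0.05, 1], K/P0 ∈ [10, 1e5], t ∈ [0, 60], together with the
mass-conservation identity N + P − P0 = a∫P. Since dV/dt = aP → aK, the
volume grows exponentially and then linearly. The plain log-curvature
d²(log V)/dt² is negative at all times under this model (N(1 − P/K) < P²/K
identically), so the biphasic shape is asserted on the curvature of log V
against log t, which is positive in the exponential phase, negative in the
linear phase, and changes sign exactly once (near day 13 at the default
typical values); `growth_model.growth_phase_transitions` counts these sign
changes.

*P0* is not estimated: it is the injected cell count (default 1.5×10⁵)
converted with the cells-to-light ratio, 1.326×10⁷ photons/sec by default.
The rate *a* is the primitive parameter; the doubling-time reading
τ = ln2/a is exposed only as the derived convenience `cell_cycle_days`.

All closed forms are evaluated in overflow-safe rearrangements (no direct
e^{at}; `logaddexp` in the necrotic form), because SAEM explores extreme
parameter proposals for which a·t can reach the hundreds.

## Unit conversions and λ

Signal converts to cell number with the calibration slope (88.4
photons/sec/cell by default) and to volume with the packing rule 10⁹ cells
≅ 1 cm³. The caliper-measured volume exceeds the cell-mass volume by a
dimensionless proportionality constant λ, estimated from the caliper data;
100·(1 − 1/λ) percent of the lesion is then attributed to stroma (λ < 1
is rejected as unphysical). Caliper readings themselves follow the
Carlsson formula V = l·w²/2; since operators record axes inconsistently,
swapped dimensions are corrected with a warning rather than an error.

## Calibration regression

Plate wells seeded at 100–10⁶ cells/well are regressed through the origin,
y = b·x (zero cells must give zero signal; no intercept is ever fit). The
reported r² is the uncentered convention for no-intercept models,
1 − SSres/Σy², which is the consistent definition when the origin is forced
— it is typically closer to 1 than the centered version and dominated by
the top seeding decade. The fit is delegated to an ordinary least-squares
solver without constant; the estimator equals Σxy/Σx².

## Population model and SAEM

Individual parameters are lognormal, θᵢ = θ_μ ⊙ exp(ηᵢ) with
ηᵢ ~ N(0, diag ω²); observations follow the proportional error model
y = f·(1 + ε), ε ~ N(0, σ²), fit on the natural scale (not log-additive).
ω is diagonal — the source results report only per-parameter CVs, and an
a–K correlation is not identifiable with confidence at n = 20 — and the
inter-animal CV of a parameter is 100·√(exp(ω²) − 1).

SAEM runs 300 exploration iterations (step size γ = 1, adaptive
random-walk proposal targeting ≈30% acceptance) followed by 200 smoothing
iterations (γ = 1/k), with 3 Metropolis–Hastings transitions per subject
per iteration; sufficient statistics (Σφᵢ, Σφᵢ², Σ squared proportional
residuals) have closed-form M-step updates. The run is bit-reproducible
given the seed. Initialization comes from a two-stage baseline: bounded
per-subject nonlinear least squares on log-observations (bounds
a ∈ [10⁻³, 5] day⁻¹, K ∈ [1.2·P0, 50·max y] — rates and capacities outside
these are not identifiable from a day-6–43 design, and unbounded fits
diverge for animals already at plateau at first imaging), pooled by
geometric mean and log-variance; subjects whose individual fit is
degenerate (e.g. flat signal, leaving a unidentified) are excluded from
the baseline with a warning. Floors of 10⁻⁸ on ω² and 10⁻⁶ on σ keep the
degenerate noiseless case well-posed.

λ is estimated **sequentially** by default (`joint_fit` offers a one-shot
(a, K, λ) alternative, at the cost of a single residual parameter shared
between the two instruments):
individual (aᵢ, Kᵢ) are frozen at their stage-1 conditional modes, each
animal's cell-mass volume trajectory is treated as known, and λ is fit as
a one-parameter lognormal population model with proportional error on the
caliper records, using the same SAEM engine.

Standard errors use the Louis identity: per subject, the observed
information is −E[H|y] − Cov[g|y] with complete-data score and Hessian in
(μ, ω², σ²), the conditional expectations estimated by post-hoc MH chains
(400 kept samples after 100 warm-up per subject) at the frozen optimum.
RSE of a fixed effect exp(μ) is 100·SE(μ) by the delta method. A singular
information matrix yields per-parameter NaN with a warning, never a crash.
The observed-data log-likelihood (used to check SAEM against the two-stage
baseline) is computed by Laplace importance sampling: a Gaussian proposal
at each subject's conditional mode with doubled covariance.

## Synthetic cohort generator

The generator emulates the study design: n = 20 mice, twice-weekly visits
concretized as days {6, 9, 12, 15, 18, 22, 25, 29, 32, 36, 39, 43} (the
source gives range and frequency, not exact days, so the schedule is
configuration), inoculum 1.5×10⁵ cells, generating values a = 0.399 day⁻¹
(CV 31.1%), K = 4.35×10⁹ photons/sec (CV 55.3%), λ = 2.25 (CV 10%). The
residual error σ is not reported in the source; both generator and fit
default to 0.15 (15% proportional), a typical optical-imaging
repeatability figure, independently for the two instruments since they are
different devices operated separately. Proportional Gaussian noise can go
non-positive at high σ; such draws are resampled (truncation, with the
count reported) rather than clipped, keeping values positive for
multiplicative modeling — the induced bias is negligible at σ ≤ 0.2. Kᵢ
draws at or below P0 are likewise resampled to respect the model's
constraint that the inoculum sits below carrying capacity. A
humane-endpoint utility censors all records after the first caliper
reading above a threshold (2.5 cm³ in the tests, the sacrifice criterion
for a 2.5 g lesion at unit density).

What the generator does **not** emulate: tomographic reconstruction error
structure, multi-site metastatic signals, occasion-to-occasion variability,
missed visits, or any a–K correlation. Passing recovery tests therefore
show that the estimation machinery inverts the assumed statistical model
at the study's design and noise level — not that the model is correct for
any particular real dataset.

## Problem sizes and numerical choices

Recovery checks use 20-mouse cohorts and five replicate seeds (medians of
fixed effects), the scale at which the variance components are already
informative while a full check run stays in the minutes range; the
tightest identity checks (closed form vs ODE) run at 1e-6 relative, unit
conversions at 1e-12. Acceptance bands are recovery-based (the source does
not print σ or the optimizer settings, so estimate-matching to the printed
table is not meaningful beyond its own uncertainty): the fixed effect of a
within 15% per cohort and 10% in the median, K within 25%/15%, λ within
10%, recovered CVs within a factor of 2 at n = 20, RSEs single-digit
percent for a and decreasing with n.

## Known limitations

- The diagonal-ω assumption ignores any a–K correlation; estimates remain
  consistent for the fixed effects but the joint individual distribution is
  simplified.
- Sequential λ estimation conditions on stage-1 conditional modes and so
  slightly understates λ's uncertainty relative to a joint fit.
- The Louis information uses Monte-Carlo conditional expectations; RSEs
  carry a few percent of Monte-Carlo noise at the default 400 samples.
- Variance components at n = 20 are weakly identified; only order-of-
  magnitude statements about CVs are supported at this sample size.
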