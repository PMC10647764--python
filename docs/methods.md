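# Methods

## The reaction model

Salt-dialysis reconstitution is modelled as one lumped reversible
second-order reaction between free octamer and free DNA:

    dN/dt = k(t)·(Q − N)·(S − N) − k′(t)·N

with N(0) = 0. *Q* and *S* are the total octamer and DNA concentrations
(mol/L), *N* the nucleosome concentration, and k(t), k′(t) the forward and
reverse rate constants along the dialysis ramp. Two reductions make the
model identifiable from endpoint measurements:

1. **Time collapses to θ.** For a constant ratio γ = k′/k, dividing the ODE
   by k(t) shows N(T) depends on the rate history only through
   θ(T) = ∫₀ᵀ k dt, parametrized as θ = k̄(α + εT) with k̄ the mean rate
   constant. This schedule invariance is property-tested: constant,
   linear-ramp and exponential-decay schedules with equal θ give endpoints
   agreeing to relative 1e−6.
2. **γ is a single effective constant.** The reverse channel enters only
   through γ (concentration units). None of the published fits require
   γ > 0, so it defaults to 0; the reversible machinery is exposed for
   completeness and oracle-tested.

### Closed forms

With roots N₋ < N₊ of (Q − N)(S − N) = γN, partial fractions integrate the
ODE exactly to

    θ = 1/(N₊ − N₋) · ln[ N₋(N₊ − N) / (N₊(N₋ − N)) ],

inverted analytically as N = N₊N₋(L − 1)/(LN₊ − N₋), L = exp(θ(N₊ − N₋))
(`efficiency_implicit`; the large-exponent branch returns the equilibrium
root N₋ with an exponentially small correction). We use the exact quadratic
roots rather than a first-order-in-γ expansion: the exact form is what
matches the ODE oracle to relative 1e−6, and it reduces algebraically to
the irreversible form at γ = 0. At γ = 0 (`efficiency_explicit`),

    N/S = (Q/S)(1 − e) / (1 − (Q/S)·e),  e = exp((Q − S)θ),

evaluated via whichever rearrangement keeps the exponent non-positive
(never overflows), with the analytic limit Qθ/(1 + Qθ) at Q = S (taken when
|Q − S| < 1e−9·max(Q, S)). When |Q − S|·θ < 1 and Q is small the linear
law N/S = Q·k̄(α + εT) applies (`efficiency_linear`); its leading relative
error is |Q − S|θ/2, which the limit tests exercise. `regime_check` reports
both regime flags; "γ small" uses γ/|Q − S| < 0.1 (the criterion is only
qualitative, the threshold is configurable and degenerate Q = S is flagged
rather than guessed).

### Numerical oracle

`simulate_assembly` / `simulate_competitive` integrate the one- and
two-species ODEs with adaptive RK45 (rtol 1e−9, atol 1e−15·S; the problem
is non-stiff at reaction-scale concentrations of ~1e−7 mol/L). Negative-N
excursions are clipped only below 1e−15·S, otherwise raised. A fixed-step
RK4 integrator provides an independent convergence cross-check in the
tests. The competitive form shares one free-DNA pool with independent
per-species on-rates and no interconversion between species — the minimal
coupling that yields the merged ratio law in the low-conversion regime,
which the tests confirm to within 2% below 5% total conversion.

## Estimation

All estimators are linear and closed-form:

* `fit_efficiency_slope` — through-origin least squares, slope = Σxy/Σx²,
  of N/S on Q. Replicates enter as individual points (no pre-averaging;
  the experiments report independent repeats, not means), and a single
  (0, 0) anchor is appended when absent, matching how the gel analyses
  anchor zero assembly at zero octamer. Standard error uses the
  through-origin residual form with n − 1 degrees of freedom; R² is
  uncentered, as appropriate without an intercept.
* `fit_slope_vs_time` — ordinary least squares of the per-time slopes on T,
  yielding the composites k̄α (intercept) and k̄ε (slope). α and ε are not
  separately identifiable from any single dialysis time, so only the
  composites are ever reported.
* `fit_competition_ratio` — zero-intercept fit of N_A/N_Z on Q_A/Q_Z over
  usable gradients; the slope estimates k̄_A/k̄_Z. Endpoint gradients
  (all-H2A or all-H2A.Z) have undefined or zero input ratios and are
  excluded from the fit but kept as flagged single-species controls.
* `compare_affinity` — templates (e.g. the CS1–CS6 panel) ranked by mean
  replicate slope; pairwise two-sided permutation tests on the replicate
  sets (exhaustive up to 2·10⁴ assignments, else 10⁴ seeded resamples with
  the observed assignment counted). A permutation test is used because
  nothing is known about the replicate error law; with single replicates
  the p-values are withheld rather than fabricated.

## Quantification

Gel: N/S = nuc/(nuc + free) per lane — "nucleosome DNA over total DNA",
invariant to lane loading. Blots: `standardize_blot` rescales one
antibody's series so its maximum is 1. Note that standardizing the H2A and
H2A.Z series each by its *own* maximum destroys exactly the cross-series
scale the ratio fit needs (under the linear model it forces the fitted
ratio to 1 identically), so the competition pipeline keeps the two series
on one shared per-assay scale, under which max-standardization is a common
rescale that cancels in every ratio. Melt curves: NF = (F − Fmin)/(Fmax −
Fmin) with the extrema taken inside 50–95 °C, so instrument warm-up
readings below 50 °C never set the scale; per-stage metrics over intervals
I = 55–75 °C (dimer release) and II = 76–87 °C (H3/H4-tetramer release)
report the NF rise, mean slope, and a transition midpoint defined as the
argmax of the derivative smoothed by a 5-°C moving quadratic
(Savitzky–Golay), parabolically refined below the 1 °C grid. Disassembly
time courses at fixed temperature are fitted as a single exponential
N/S(t) = A·e^(−λt) on the log scale — a comparative statistic chosen for
robustness, not a mechanism claim; non-decaying series return λ = 0 with a
flag.

## Synthetic data

The generator regenerates the published experimental designs: octamer
gradients 5–60 μg/mL in 5 μg/mL steps on 601 DNA (50 μg/mL) at dialysis
times 10/12/14/16 h with five replicates; competition series with
2.4/3/3.6 μg total octamer split over six gradients on 3 μg DNA in 60 μL;
and two-logistic melt curves on a 1 °C grid over 25–95 °C. Band
intensities are I₀·(N/S)·η and I₀·(1 − N/S)·η′ with I₀ = 1000 arbitrary
units (cancels in all downstream ratios, tested) and independent mean-one
log-normal factors η (σ² = ln(1 + CV²)); multiplicative noise is the
natural law for strictly positive band densitometry whose error scales
with signal. Replicate scatter was never published numerically; the
default CV of 10% is a configurable stand-in. Mass↔molar conversion uses a
registry of molecular weights back-derived from the published molarity
anchors (octamer 1.087e5 g/mol from 60 μg/mL ↔ 5.52e−7 mol/L; 601 DNA
9.823e4 from 5.09e−7 mol/L; CS DNA 1.082e5 from 4.62e−7 mol/L), which
reproduces the printed gradient endpoints to 3 significant figures; other
species can be registered with user-supplied weights. The two octamer
species default to equal molecular weights (their true difference is < 1%
of ~108.7 kDa), so input mass ratios equal molar ratios.

What the generator does *not* emulate: gel background and smearing,
saturating or nonlinear detector response, antibody cross-reactivity,
lane-to-lane loading correlation, and any salt-concentration-resolved
intermediate states (tetrasome/hexasome). Recovery results on synthetic
data therefore certify the estimators under the stated noise law, not the
full error structure of real densitometry.

## Problem sizes and determinism

Recovery studies use 200 simulations per setting (gradient: 60 lanes each;
competition: 4 usable gradients each), which resolves a median relative
error of ~0.5% with negligible Monte-Carlo uncertainty; the noisy
competition summary uses the median of 50 seeded fits. Every stochastic
routine takes an explicit integer seed (numpy `default_rng`; no global
state), and the CLI writes a manifest (config + seed + units) from which
any output is reproducible byte-for-byte.

## Known limitations

* The model is a single lumped reaction; it does not resolve assembly
  intermediates or salt-dependent rate structure, and k̄ is an effective,
  template-specific constant.
* Under the competition design's four usable gradients, a single CV-10%
  blot measurement per gradient propagates to a per-fit relative SD of
  ~12% on the fitted ratio (the largest input ratio, Q_A/Q_Z = 4, carries
  85% of the Σx² weight). The estimator is unbiased — medians over many
  seeds recover the truth to 4 digits — but any single fitted ratio at
  that noise level has wide error bars; replicated blots would be needed
  to certify single-fit accuracy much below ~10%.
* γ is exposed but untested against any published reversible-regime
  measurement, since none exists for this system.
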