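# nucleokinetics

Chemical-reaction-kinetics modelling of in-vitro nucleosome assembly by
salt dialysis, for canonical and H2A.Z-containing histone octamers — and of
the competition between the two when they assemble on the same DNA pool.

Nucleosome reconstitution experiments titrate histone octamers (total
concentration *Q*) against a fixed DNA template (*S*, e.g. the Widom 601
positioning sequence) and read out the assembly efficiency *N/S* — the
nucleosome-band fraction of total Cy3-labelled DNA on a native gel. This
package models that process as a single lumped reversible second-order
reaction,

    dN/dt = k(t)·(Q − N)·(S − N) − k′(t)·N,

whose forward-rate history enters only through the accumulated integral
θ(T) = ∫₀ᵀ k dt = k̄·(α + εT), with k̄ the mean rate constant and *T* the
dialysis time. Three nested closed forms of *N/S* are provided (exact
reversible, irreversible, and the low-conversion linear law
N/S = Q·k̄·(α + εT)), all certified against a numerical ODE oracle. In the
linear regime the through-origin slope of *N/S* versus *Q* estimates the
composite rate k̄(α + εT), and for two octamer species competing for one
DNA pool the per-species laws merge into the ratio law

    N_A/N_Z ≈ (Q_A/Q_Z) · (k̄_A/k̄_Z),

so a zero-intercept fit of blot-measured N_A/N_Z against the input mass
ratio Q_A/Q_Z yields k̄_A/k̄_Z, a single dimensionless measure of which
histone outcompetes the other (> 1: canonical H2A wins). The package also
quantifies thermal-shift melt curves (normalized fluorescence NF over
50–95 °C, per-stage dissociation metrics) and fixed-temperature
disassembly decay rates.

Audience: chromatin biochemists analysing reconstitution gels/blots and
modellers who need a tested forward model + estimator pair for assembly
kinetics. No raw densitometry from the original experiments is deposited
anywhere, so a first-class synthetic-data module regenerates every input
table from the forward models under the published designs.

## Worked example

Generate a synthetic 16-h octamer gradient (5–60 μg/mL, 5 replicates,
CV 5% band noise) plus a 3-μg competition series with injected
k̄_A/k̄_Z = 1.71, then refit both:

```bash
nucleokinetics synth --out-dir demo --seed 11 --noise-cv 0.05 \
    --slope 0.01461 --ratio 1.71
nucleokinetics fit-gradient demo/lanes.csv
```

```json
{
  "per_time": {
    "16": {
      "slope": 0.014632374973944567,
      "stderr": 4.696914856596493e-05,
      "r_squared": 0.9993821563712395,
      "n": 61,
      "unit": "per ug/mL"
    }
  }
}
```

The refitted slope 0.01463 per μg/mL recovers the injected composite rate
k̄(α + 16ε) = 0.01461 within its standard error; `n = 61` counts the 60
lanes plus the (0, 0) anchor (zero assembly at zero octamer).

```bash
nucleokinetics fit-competition demo/competition_lanes.csv demo/blots.csv \
    --total-mass 3.0
```

```json
{
  "kbar_A_over_kbar_Z": 1.6353587668589638,
  "stderr": 0.030082414244781155,
  "n_gradients": 4,
  "verdict": "A-stronger",
  "excluded_gradients": [1, 6]
}
```

The fitted rate-constant ratio 1.64 ± 0.03 recovers the injected 1.71 from
four usable gradients (the single-species endpoints 1 and 6 are excluded),
and the verdict states that canonical H2A is the stronger competitor.

The same functionality is importable: `nucleokinetics.efficiency_explicit`,
`simulate_competitive`, `fit_efficiency_slope`, `fit_competition_ratio`,
`melt_stage_metrics`, `generate_gradient_experiment`, etc.

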