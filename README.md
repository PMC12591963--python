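# rsmpso

Response-surface modelling and particle-swarm optimization for two-factor
food-formulation experiments.

The package implements the full analysis chain used to optimize a cooked
cereal formulation over bulgur amount (g) and water volume (mL):

- **`rsmpso.design`** — five-level, two-factor central composite designs
  (4 factorial + 4 axial + replicated centre runs, axial distance 1.41),
  with explicit coded-to-natural level maps that can override linear
  scaling (the published axial settings are rounded and inconsistent with
  ±1.41 × step).
- **`rsmpso.rsm`** — second-order polynomial surfaces stored as explicit
  term lists (duplicate monomials allowed and summed), OLS fitting in
  natural units, DoE ANOVA with adjusted sums of squares and a
  lack-of-fit / pure-error split, analytic stationary points with Hessian
  classification, a brute-force grid-search optimizer, and the
  percent-difference statistic.
- **`rsmpso.registry`** — the twelve published response polynomials
  (3 varieties × taste/color/smell/general acceptance) transcribed
  verbatim, anomalies included, plus the published 13-run response tables
  and optimum-validation rows as package data.
- **`rsmpso.pso`** — global-best particle swarm maximizer with linear
  inertia decay (defaults: swarm 10, 40 iterations, c1 = c2 = 0.10,
  w 0.90 → 0.30, 30 independent runs), component-wise position clamping,
  convergence traces and multi-run statistics.
- **`rsmpso.metrics`** — radical-scavenging percent inhibition and CIELAB
  chroma, hue angle (quadrant-correct, degrees) and ΔE.
- **`rsmpso.synthetic`** — synthetic sensory-panel generator (known
  quadratic truth + Gaussian noise, optional hedonic clipping/rounding)
  and coefficient/argmax recovery experiments.
- **`rsmpso.cli`** — a `click` CLI chaining design → simulate → fit →
  optimize → validate → report.

## CLI

```bash
rsmpso design --out design.csv
rsmpso simulate --variety firik --response taste --noise-sd 0.2 --seed 7 --out panel.csv
rsmpso fit --variety karakilcik --response taste --optimum 140 400
rsmpso optimize --variety firik --response taste --seed 0 --trace-out trace.csv
rsmpso validate --seed 0 --out validation.csv   # exits non-zero on oracle miss
rsmpso report --seed 1 --out-dir reports/
```

Global choices: `--bounds {reproduction,experimental}` selects the search
rectangle (X1 ∈ [135, 150] × X2 ∈ [375, 425], on which every published
optimum lies, versus the full factor region [130, 150] × [350, 450]);
`--registry {printed,merged,corrected}` selects the verbatim equations,
their duplicate-summed canonical forms, or the flagged typo-fix variant.
Commands also accept `--config <yaml/json>`.

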