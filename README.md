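# sympatric

Quantitative workflow for studying niche partitioning between two sympatric
small carnivores — a dominant jungle cat (*Felis chaus*) and a subordinate
leopard cat (*Prionailurus bengalensis*) in Southeast Asian dry deciduous
forest — along the three classic axes:

- **Diet** (`sympatric.diet_analysis`): scat item-volume data converted to
  frequency of occurrence, percent volume, and percent ingested biomass via a
  saturating biomass-correction model
  `CF = W_pred · (0.033 − 0.025 e^{−4.284 · W_prey/W_pred})`, with Levins
  niche breadth `B = 1/Σp²`, Horn's overlap
  `R0 = [Σ(p+q)ln(p+q) − Σp ln p − Σq ln q]/(2 ln 2)`, chi-square / Fisher
  exact comparisons, permutation prey-accumulation curves, and scat-diameter
  t tests.
- **Space** (`sympatric.camtrap_io`, `sympatric.cooccupancy_model`):
  camera-trap records collapsed to independent events (>30 min rule), tiled
  into 15-day-occasion detection histories with effort, and fitted with a
  Bayesian two-species occupancy model — logit-linear habitat covariates,
  dominant-presence effects on subordinate occupancy (η) and detection (b2),
  Metropolis-within-Gibbs sampling, Gelman–Rubin convergence checks, and
  Freeman–Tukey posterior-predictive Bayesian p-values.
- **Time** (`sympatric.activity_analysis`): event times anchored to the sun
  (sunrise → π/2, sunset → 3π/2), von Mises circular kernel densities with a
  plug-in concentration, the overlap coefficient Δ̂1 = ∫min(f̂₁, f̂₂) with
  smoothed-bootstrap confidence intervals, HIGH/LOW overlap classification at
  0.70/0.35, and a harmonic (sine/cosine) Poisson regression comparing the
  two species' diel cycles.

Because the underlying camera-trap locations are withheld for conservation
reasons, `sympatric.synthetic_data` generates ground-truthed stations,
detection histories, activity times and scat tables with the study's
structure (450 sites, 64% dry deciduous forest, nocturnal activity, 17 + 130
scats), so every estimator is testable end to end. The published
diet-composition table ships in `sympatric.reference_diet` as worked-example
input.

## Worked example

```python
from sympatric import diet_analysis as diet, reference_diet as ref

b = {k: diet.levins_niche_breadth(list(p["bio"].values()))
     for k, p in ref.PROFILES.items()}
r0 = diet.horns_overlap(ref.JUNGLE_CAT_TOTAL["bio"],
                        ref.LEOPARD_CAT_TOTAL["bio"])
p_hare = diet.fisher_category_test(2, 15, 0, 130)
cf = diet.biomass_per_scat(0.05, 5.0)
```

prints, via the obvious format strings:

```
Levins B (jungle cat):        5.09
Levins B (leopard cat):       3.33
Horn's R0 (between felids):   0.85
Fisher p (hare, 2/17 vs 0/130): 0.0127
CF (50 g murid, 5 kg cat):    0.04524 kg/scat
```

Read: the jungle cat's diet is the broader one (B ≈ 5.1 vs 3.3 over the
shared prey categories), yet the two diets overlap strongly (R0 = 0.85)
because both cats live mostly on small rodents; hares occurred in jungle-cat
scats significantly more often than in leopard-cat scats (p ≈ 0.013); and
one collectable scat of small-murid remains represents about 45 g of
ingested biomass for a 5 kg predator.

The full pipeline (simulate → history → diet → occupancy → activity) runs
from the shell:

```sh
sympatric report --seed 17 --out out/
sympatric simulate --seed 5 --out data/
sympatric activity --events data/events.csv --boot 10000 --seed 1
```

and writes plain CSV/JSON tables plus a manifest; reruns with the same seed
are byte-identical.

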