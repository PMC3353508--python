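# eelgrass-allometry

Tools for deciding whether the dry weight *w* (g) of an eelgrass
(*Zostera marina*) leaf can safely be inferred from its length *l* (mm)
through a constant weight-to-length ratio, or whether an allometric
power law is needed. The question matters to anyone using the
plastochrone method: it converts nondestructive leaf-length
measurements to biomass through a ratio *c*, and that conversion is
systematically biased when the true scaling is allometric.

The package fits and compares the two models

```
allometric:  w = a · l^b        (a > 0, b > 0)
isometric:   w = c · l          (c > 0)
```

for individual leaves and for shoot-level aggregates
(w_s = Σ_k a·l_k^b), and computes the closed-form diagnostics of their
deviation θ(l) = c·l − a·l^b (for b ≠ 1):

- **threshold length** l\* = (c/a)^(1/(b−1)), where the line crosses the
  curve — beyond it the ratio proxy under-predicts biomass when b > 1;
- **l_θm** = l\*·b^(−1/(b−1)), the length where |θ| peaks, always below l\*;
- **θ_max** = (c/(a·b))^(b/(b−1))·a·|b−1|, the largest disagreement
  inside (0, l\*);
- the percentage of a length sample below/above l\*, and the bias profile
  of the ratio proxy against observed weights.

Model selection runs the full battery: R², Lin's concordance
correlation coefficient, Gaussian AIC with the >4 / >10 evidence rule
on ΔAIC, a pure-error lack-of-fit F test on replicate length groups, a
paired test of observed vs predicted means, and residual
normality/homoscedasticity checks. A seeded synthetic-data generator
(right-skewed lengths, heteroscedastic power-law weights, shoot
aggregation) makes every stage testable without field data.

## Worked example

Simulate a survey-like dataset (1000 leaves, power-law weights with
multiplicative noise) and run the comparison:

```
$ cat sim.cfg
preset = san_quintin
seed = 42
n_leaves = 1000

$ eelgrass-allometry simulate --config sim.cfg --out leaves.csv
$ eelgrass-allometry compare --data leaves.csv --out report.json --table
model             params                                    R2     CCC    se_fit         AIC
--------------------------------------------------------------------------------------------
allometric_leaf   a=9.92958e-06±8e-07, b=1.40801±0.014   0.898   0.946   0.00489    -10637.0
isometric_leaf    c=0.000102106±9.4e-07                  0.807   0.872  0.006717    -10003.1

delta AIC (iso - allo) = 633.9  [strong; prefers allometric]
l* = 302.4 mm  (86% below / 14% above)   theta_max = 0.0039 g
ratio proxy underestimates 20% of observed weights; mean |relative error| = 37%
```

The generating parameters (a = 1e−5, b = 1.41) are recovered within
their standard errors; the ΔAIC of 634 is far past the "strong
evidence" mark of 10, so the ratio proxy is rejected even though its
R² of 0.81 looks respectable on its own — exactly the trap the
threshold diagnostics quantify. With fitted values a ≈ 9.93e−6,
b ≈ 1.408, c ≈ 1.02e−4 the models agree to within θ_max ≈ 0.0039 g
below l\* ≈ 302 mm (86% of this sample) and diverge beyond it.

Threshold diagnostics for an already-fitted triple need no data:

```
$ eelgrass-allometry diagnose --a 0.00001 --b 1.410012 --c 0.0001
{
  "display": { "l_star_mm": 274.8, "theta_max_g": 0.0035 },
  "l_star_mm": 274.75968275310595,
  "l_theta_max_mm": 118.85175204109292,
  "theta_max_g": 0.0034560446689725047
}
```

The same operations are available as a library
(`eelgrass_allometry.fit_allometric_leaf`, `compare_models`,
`threshold_length`, `generate_leaves`, …); see `docs/methods.md` for
the statistical conventions.

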