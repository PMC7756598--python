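# predtest

A prediction-based global hypothesis test for studies that measure many
correlated endpoints on few subjects.

Early-stage biomedical studies often collect a panel of outcome measures —
blood-flow readings in several brain regions, a battery of biomarkers — with
no single primary endpoint and a sample size too small for per-endpoint
testing with multiplicity correction. `predtest` tests the researcher's
*theory* instead: before seeing the data, the researcher predicts the
direction (increase or decrease) of each endpoint, and the test asks whether
those predictions are right more often than a hypothesized predictive ability
φ₀ would allow.

## The test

Given an m × m endpoint correlation matrix **C** (sample Pearson by default),
each endpoint receives the weight

    wᵢ = ( Σⱼ r²ᵢⱼ )⁻¹     (the sum includes r·ᵢᵢ = 1),

so wᵢ = 1 for an endpoint independent of all others and wᵢ = 1/m under
perfect pairwise association.  W = Σ wᵢ is the *effective number of
independent endpoints* (W = m for **C** = **I**, W = 1 for **C** = **J**).
With pᵢ = 1 iff the observed sample effect on endpoint i has the predicted
sign, the statistic is the weighted count of correct predictions

    Tₘ = Σᵢ pᵢ wᵢ ,        0 ≤ Tₘ ≤ W.

Under H₀ : φ ≤ φ₀ the pᵢ are iid Bernoulli(φ₀), so Tₘ is a weighted
Bernoulli sum.  Its null distribution is enumerated exactly over all 2ᵐ
prediction vectors (each contributing φ₀^Σp (1−φ₀)^(m−Σp) to the value
pᵀw), or approximated by Normal(φ₀W, √(φ₀(1−φ₀)Σw²ᵢ)) for large m.  H₀ is
rejected when the upper-tail p-value is ≤ α *and* Tₘ ≥ 1 — at least one
effective endpoint correctly predicted, so predicting linear combinations of
other endpoints earns no credit.

The package also provides O'Brien's OLS global test
(T_OLS = Σ t_k / √(1ᵀR̂1)) as the classical comparator, a vine (LKJ η = 1)
generator of random correlation matrices uniform over the positive-definite
space, and a Monte-Carlo suite for power, type-I error, weight-sensitivity
and normal-approximation-accuracy studies.

## Worked example

Summary data from a pre-post exercise-intervention study of cerebral blood
flow (arterial spin labeling) in six brain regions of 11 older adults: the
investigator predicted an increase in every region; four of six observed mean
differences were positive, giving outcomes p = [1, 1, 0, 1, 1, 0] with
published endpoint weights (0.46, 0.41, 0.68, 0.48, 0.39, 0.40).

```python
import predtest as pt

ex = pt.asl_example()
res = pt.prediction_test(ex["outcomes"], ex["weights"], phi0=0.5, alpha=0.05)
print(res)
```

```
Prediction-based global test
  endpoints (m)        : 6
  effective endpoints W: 2.82
  correct predictions  : 4
  statistic T_m        : 1.74
  null phi0            : 0.5
  p-value ( exact)     : 0.296875
  alpha                : 0.05
  T_m >= 1 gate        : on
  decision             : fail to reject H0
```

Correctly predicting 4 of 6 regions amounts to T_m = 1.74 of W ≈ 2.8
effective endpoints.  Under the null that directions are predicted at coin
flip rates (φ₀ = 0.5), 19 of the 64 equally likely prediction records reach
a statistic this large (p ≈ 0.297), so the data do not support a predictive
ability better than chance.

The same analysis from the shell, on a raw data table:

```sh
predtest gen-corr --m 6 --seed 11 --out corr.tsv
predtest gen-data --corr corr.tsv --scenario const --effect-size 0.5 \
    --n 12 --design two-group --seed 12 --out data.csv
predtest run --data data.csv --predictions preds.tsv --design two-group \
    --comparator ols --out report.json
```

which prints the same table (here all 6 simulated endpoints were predicted
correctly: T_m = W = 3.53, exact p = 2⁻⁶ = 0.015625, reject) plus
`O'Brien OLS comparator: T_OLS = 4.84579, one-sided p = 3.82922e-05`, and
writes a full-precision JSON report.  `predtest min-m --phi0 0.7` prints 9:
with fewer than 9 endpoints the null φ₀ = 0.7 can never be rejected at
α = 0.05, because even a perfect record has probability 0.7⁹ ≈ 0.04 under
H₀.

`predtest simulate {power,type1,sensitivity,gmae}` runs the Monte-Carlo
studies from a YAML config and writes tidy TSV.

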