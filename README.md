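# cgsurv

Sensitivity analysis for survival prognostic prediction under **dependent
censoring**, built on the copula-graphic (CG) estimator.

## The problem

Multi-gene prognostic indices are validated by splitting test patients into
good- and poor-prognosis groups and comparing their Kaplan–Meier (KM)
curves. KM assumes the censoring time U is independent of the survival time
T. In oncology cohorts that assumption is often wrong — patients who drop
out may be sicker than those who stay — and then KM (and any verdict about
the prognostic index built on it) is biased. Because the dependence between
T and U is not identifiable from censored data alone, it cannot be
estimated away; it can only be *varied*. `cgsurv` implements that
sensitivity analysis: repeat the group comparison under a sweep of assumed
dependence structures and see whether the prognostic separation survives.

## The model

Dependence between T and U is modelled by an Archimedean copula with
generator φ<sub>α</sub>:

P(T > t, U > u) = φ<sub>α</sub><sup>−1</sup>[ φ<sub>α</sub>{P(T > t)} + φ<sub>α</sub>{P(U > u)} ]

Three one-parameter families are supported, each with a closed Kendall's-tau
map:

| family | φ<sub>α</sub>(t) | Kendall's τ |
|---|---|---|
| Clayton (α > 0) | (t<sup>−α</sup> − 1)/α | α/(α+2) |
| Gumbel (α ≥ 0) | (−log t)<sup>α+1</sup> | α/(α+1) |
| Frank (α ≠ 0) | −log[(e<sup>−αt</sup> − 1)/(e<sup>−α</sup> − 1)] | 1 − (4/α)(1 − D₁(α)) |

Given a copula, the CG estimator of the survival function of a group of
size n with at-risk counts Ȳ(t) is

Ŝ<sup>CG</sup>(t) = φ<sub>α</sub><sup>−1</sup> [ Σ<sub>t<sub>i</sub> ≤ t, δ<sub>i</sub>=1</sub> { φ<sub>α</sub>(​(Ȳ(t<sub>i</sub>)−1)/n) − φ<sub>α</sub>(Ȳ(t<sub>i</sub>)/n) } ]

which reduces *exactly* to KM when φ(t) = −log t (independence; Gumbel
α = 0, or the α → 0 limit of Clayton/Frank).

Patients are stratified by a prognostic index PI = Σ<sub>j</sub> β̂<sub>j</sub>x<sub>j</sub>
(weights from a gene signature; two published 16-gene lung-cancer
signatures ship as fixtures), split at the training-median cutoff c into
good (PI ≤ c) and poor (PI > c) groups. Separation is measured by the
time-averaged difference of the two CG curves up to the shared horizon
τ = min(max t<sub>good</sub>, max t<sub>poor</sub>):

D = (1/τ) ∫₀<sup>τ</sup> { Ŝ<sub>Good</sub><sup>CG</sup>(t) − Ŝ<sub>Poor</sub><sup>CG</sup>(t) } dt

τ·D is the restricted mean survival time difference (RMSTD). The p-value
comes from a permutation test: the (time, status) pairs are reassigned to
subjects at random, D recomputed N times, and p = #{D<sub>r</sub> > D}/N.

## Worked example

The built-in 8-subject toy sample has times 1, 3, 5, 4, 7, 8, 10, 13 and
prognostic indices 8, 7, …, 1.

```python
from cgsurv import (ArchimedeanCopula, cg_estimate, permutation_test,
                    toy_sample)

sample = toy_sample()
copula = ArchimedeanCopula("clayton", 18.0)   # Kendall's tau = 0.9
print(cg_estimate(sample, copula).to_frame())
res = permutation_test(sample, cutoff=4.5, copula=copula,
                       n_permutations=10_000, seed=1)
print(res.D, res.horizon, res.rmstd, res.p_value)
```

prints the CG survival curve

```
 time  survival
  0.0  1.000000
  1.0  0.875000
  4.0  0.626246
  8.0  0.250009
 13.0  0.000000
```

(each row is the estimated survival probability just after that event
time; under strong positive dependence the curve drops faster than KM
because censored subjects are treated as being near death) and

```
D=0.300  horizon=5.0  RMSTD=1.500  p=0.1435
```

— the good group's curve averages 0.30 higher over the first 5 time
units, a 1.5-time-unit RMST advantage, not significant at this tiny n.

The same analysis from the shell, over the default 12-cell grid
(Clayton α ∈ {1, 2, 4, 15}, Gumbel α ∈ {0, 1, 2, 10}, Frank
α ∈ {−14, −5, 5, 14}):

```bash
cgsurv simulate --n 200 --copula clayton --tau 0.5 --seed 42 --out cohort.csv
cgsurv cg --input cohort.csv --copula clayton --alpha 18 --out curve.csv
cgsurv grid --input test.csv --pi-col pi --cutoff-file train_pis.csv \
            --nperm 10000 --seed 7 --out report/
```

`report/sensitivity_grid.csv` then holds one row per (family, α) cell with
τ, D, RMSTD and the permutation p-value; small p-values across the whole
grid mean the prognostic separation is robust to dependent censoring.

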