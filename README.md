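# metscate

Heterogeneous effects of a pandemic-year exposure on new-onset metabolic
syndrome (MetS), estimated from paired health-checkup records with an
X-learner.

Occupational health-checkup programmes produce yearly baseline/follow-up
pairs.  When an external shock — here, the first pandemic fiscal year —
lands between two checkups, the records whose follow-up fell in that year
form an exposed arm and earlier pairs an unexposed arm, with exposure
independent of anyone's baseline covariates.  `metscate` is for
epidemiologists and biostatisticians who want to ask not just *whether*
such a shock raised the incidence of new-onset MetS, but *for whom*: which
departments, ages, and risk profiles were hit hardest.

## What it computes

The estimand is the conditional average treatment effect (CATE), a risk
difference:

    tau(x) = E(Y^1 - Y^0 | X = x)

estimated by a two-stage X-learner:

1. arm-specific logistic outcome models `M0`, `M1` (feature sets chosen
   by 10-fold CV AUC);
2. imputed treatment effects `d1 = Y - M0(x)` (exposed), `d0 = M1(x) - Y`
   (unexposed), rescaled from [-1, 1] to (0, 1);
3. beta regressions `M2`, `M3` on the rescaled pseudo-effects (10-fold CV
   RMSE);
4. the blend `cate(x) = g * tau0(x) + (1-g) * tau1(x)` with the marginal
   exposure probability `g = n_exposed / n_total` standing in for the
   propensity score (exposure is calendar time).

Around the estimator: a Japanese-criteria (MHLW) MetS classifier with
principled missing-data handling, design-matrix preprocessing (median
imputation + indicators, one-hot with missing levels, square/interaction
expansions), stratified bootstrap confidence intervals and p-values,
subgroup/difference tables, CATE histograms and decile profiles with
standardized differences, LOWESS age curves — and a synthetic cohort
generator with a known ground-truth effect surface, so the whole pipeline
is testable without access to any real checkup data.

## Worked example

```python
import metscate as mc

cfg = mc.study_cohort_config(surface="table3", n_unexposed=600,
                             n_exposed=400, seed=3)
cohort = mc.generate_cohort(cfg)           # known true effect surface
conf = mc.PipelineConfig(featuresets=["original"], seed=3)
boot = mc.bootstrap_inference(cohort, conf, n_boot=200, seed=3)
print(boot.table.loc[["overall", "department=intensive_care"]].round(3))
```

prints

```
                              n  estimate  ci_lower  ci_upper  p_value
statistic
overall                    1000     0.012    -0.111     0.249     0.72
department=intensive_care    67     0.382     0.106     0.571     0.01
```

Reading: at this small cohort size the overall effect is indistinguishable
from zero, but the intensive-care department — the subgroup the generator
truly made worst-off (true tau 0.154 there, 0.044 cohort-wide) — stands
out with an interval excluding zero.  Its estimated level runs well above
the truth: the beta-regression second stage matches log-moments rather
than means and inflates rare-outcome effects roughly two-fold.
`docs/methods.md` derives this bias and explains why subgroup rankings
and null/non-null conclusions are the trustworthy outputs while absolute
levels are upper-end figures.  The `examples/` scripts walk through each
capability (generation, classification, base learners, estimation,
reporting) with printed, annotated output.

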