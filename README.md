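# vfrisk

Pooled household-survey analysis of risk factors for **vaginal fistula (VF)
symptoms** — an abnormal opening between the bladder or rectum and the
vagina that causes chronic incontinence, largely following obstructed
labour. Nationally representative DHS/MICS-type surveys ask women aged
15–49 whether they have ever experienced fistula symptoms; because the
outcome is rare (a few cases per 1,000 women) and self-reported, any
pooled regression must confront two problems at once:

1. **Confounding** — exposed and unexposed women differ in age, literacy,
   residence, gravidity and religion; and
2. **Outcome misclassification** — self-report has imperfect sensitivity
   (Se) and specificity (Sp) against the gold standard of pelvic
   examination, and with a rare outcome even a tiny false-positive rate
   (1 − Sp ≈ 0.001) dilutes the case pool enough to attenuate odds ratios
   substantially toward 1.

`vfrisk` implements the full analysis pipeline for epidemiologists and
global-health researchers working with such pooled survey data, plus a
synthetic-data generator so every stage can be validated against known
truth without access to the restricted microdata the design mimics.

## The model

After k:1 nearest-neighbour matching of unexposed to exposed women (on
sampling weight, continuous age and survey identifier), women are grouped
by covariate pattern *i* and the reported case counts are modelled with a
latent-class grouped-binomial logistic regression:

```
y_i ~ Binomial(N_i, p_i)
p_i = π_i·Se + (1 − π_i)·(1 − Sp)
logit(π_i) = α + β·x_i
```

where `π_i` is the probability of *true* lifetime VF symptoms and `p_i`
the probability of a positive *report*. Priors: `α, β ~ Normal(0, sd 20)`,
`Se ~ Uniform(0.9510, 0.9990)`, `Sp ~ Uniform(0.9985, 0.9995)` (the
credible ranges from a validation of fistula self-report). Posteriors are
sampled by a MAP-initialised adaptive Metropolis sampler (3 chains);
convergence is checked with the split-chain potential scale reduction
factor (R-hat). Effects are reported as posterior-median odds ratios with
equal-tailed 95% credible intervals. With `Se = Sp = 1` the model reduces
exactly to ordinary logistic regression, which anchors its correctness
against maximum-likelihood fits.

## Worked example

```python
import numpy as np
from vfrisk import (SimulationConfig, simulate_population, MisclassLogit,
                    McmcConfig, PriorSpec)
from vfrisk.harmonize import age_group

# a pooled world of 20 surveys: true OR 2, baseline prevalence 0.002,
# self-report with Se = 0.975, Sp = 0.999
cfg = SimulationConfig(
    n_surveys=20, women_per_survey=10_000,
    alpha_true=float(np.log(0.002 / 0.998)),
    beta_exposure_true=float(np.log(2.0)),
    beta_covariates_true={"age_std": 0.3, "literate": -0.3},
    exposure_field="fgm", exposure_prevalence=0.42,
    sensitivity_true=0.975, specificity_true=0.999,
    missing_rate={}, seed=1000,
)
df = simulate_population(cfg)
df = df.assign(exposed=df["fgm"].astype(bool),
               outcome=df["vf_reported"].astype(bool),
               age_group=age_group(df["age_years"]),
               urban=(df["residence"] == "urban"))

adjusted = MisclassLogit.from_dataframe(
    df, adjustment=("age_group", "literate", "urban"))
print(adjusted.fit(McmcConfig.test(seed=0)).or_estimate("exposed"))

naive = MisclassLogit.from_dataframe(
    df, adjustment=("age_group", "literate", "urban"),
    priors=PriorSpec.perfect_test())
print(naive.fit(McmcConfig.test(seed=0)).or_estimate("exposed"))
```

prints

```
exposed: OR 2.16 (95% CrI 1.68-2.87)
exposed: OR 1.67 (95% CrI 1.43-1.97)
```

The misclassification-adjusted interval covers the generating odds ratio
of 2, while the naive model (Se = Sp = 1 forced) is attenuated toward 1 by
the false-positive dilution — exactly the bias the latent-class likelihood
exists to remove.

The same analysis is available end to end from the shell:

```bash
vfrisk simulate --out women.csv --seed 1
vfrisk harmonize --in women.csv --factor short_stature --out analysis.csv
vfrisk match --in analysis.csv --ratio 4 --exact-survey --seed 1 \
             --out matched.csv --balance balance.json
vfrisk fit --in matched.csv --factor short_stature --mcmc test --seed 1 \
           --out draws.npz --diagnostics diag.json
vfrisk report --draws draws.npz --factor short_stature --out effects.csv
```

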