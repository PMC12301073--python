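# bathrisk

Two-stage analysis of the nonlinear association between daily outdoor
temperature and bath-related drowning mortality, for epidemiologists studying
cold-season bathing deaths (the winter-peaking fatalities recorded as
accidental drowning and submersion in a bathtub, ICD-10 W65) across
administrative units such as Japan's 47 prefectures.

**Stage 1** fits penalized-spline quasi-Poisson models to daily unit-level
death counts,

```
log E[y_id] = alpha + f(T_id) + b_i + log N_iy,      Var[y_id] = phi E[y_id],
```

with a cubic B-spline smooth `f` of daily mean temperature (second-order
difference penalty, REML-selected smoothing), unit random intercepts `b_i`
(national GAMM) or per-unit GAM fits, and the log annual population as
offset. Fitted risks become relative risks referenced at the minimum-risk
temperature within the 1st–99th exposure percentiles, and each unit × period
is summarised by its **peak RR** — the maximum-to-minimum fitted risk ratio —
with confidence intervals from coefficient simulation.

**Stage 2** regresses log peak RR on a within/between-decomposed unit
covariate with a mixed-effects meta-regression,

```
log(RR_ij) = beta0 + beta1 (x_ij - x̄_i) + beta2 x̄_i + u_i + eps_ij,
```

reporting the ratio of peak RR per one SD of the covariate between units
(`exp(beta2 sd_between)`) and within units (`exp(beta1 sd_within)`).

Because the underlying death-certificate data are restricted, the package
ships a **synthetic cohort generator** that reproduces the panel's
statistical structure (winter seasonality, quasi-Poisson overdispersion,
unit intercepts, population offsets, covariate-modified peak RRs) along with
ground truth for every unit-period, so estimator behaviour is testable end
to end. See `docs/methods.md` for the full model account.

## Worked example

```python
import numpy as np
import bathrisk as br

cohort = br.make_cohort(
    n_units=6,
    period_defs=[(1998, 2004), (2005, 2011), (2012, 2018)],
    modifier_effects={"insulation": float(np.log(0.76)),
                      "warmth": float(np.log(1.27))},
    seed=7,
)
cfg = br.AnalysisConfig(periods=((1998, 2004), (2005, 2011), (2012, 2018)),
                        n_sim=1000, seed=11)
res = br.run_two_stage(cfg, panel=cohort.panel, covariates=cohort.covariates)
c = res.national_curve
print(f"national peak RR {c.peak_rr:.1f} "
      f"(95% CI {c.peak_ci[0]:.1f}-{c.peak_ci[1]:.1f}) "
      f"at {c.peak_temp:.1f} C, reference {c.ref_temp:.1f} C")
```

prints

```
national peak RR 8.6 (95% CI 6.6-10.7) at 3.5 C, reference 31.9 C
```

i.e. on this six-unit cohort (generated with a true national peak RR of 9.7
at 1.8 °C and reference 30.3 °C) the risk of a bath drowning on a ~3 °C day
is estimated to be about 8.6 times the risk at the warm reference. The
stage-2 table from the same run,

```
 covariate  ratio_between_per_sd  between_ci_low  between_ci_high
insulation                 0.666           0.513            0.864
    warmth                 0.937           0.584            1.502
```

estimates that a unit one between-unit SD higher in the insulation-like
covariate has a peak RR about 0.67 times as large (true generating ratio
0.76 per SD); with only six units the intervals are wide — at the full 47
units the estimates concentrate around the generating ratios.

The same pipeline is scriptable from the shell:

```bash
bathrisk simulate --out-dir cohort/ --n-units 47 --seed 1 \
    --modifier insulation=0.76 --modifier warmth=1.27
bathrisk run --panel cohort/panel.csv --covariates cohort/covariates.csv \
    --out-dir results/ --seed 1
```

writing the peak-RR table, national RR curve, meta-regression results and a
JSON run manifest; identical seeds reproduce identical bytes.

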