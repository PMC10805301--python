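# edac — Emergency Department Avoidability Classification

Emergency departments see large volumes of visits that could have been
handled in subacute primary care (family practice, urgent-care clinics).
Quantifying that avoidable volume from routinely collected administrative
data requires a classifier with demonstrated criterion validity — i.e. one
whose labels agree with expert clinical judgement.

This package implements the **EDAC**, a deterministic decision table over
five chart variables, together with the complete criterion-validity study
pipeline used to validate it against blinded, paired emergency-physician
judgements.  It is written for health-services researchers and
epidemiologists who want to (a) classify their own ED visit tables, and (b)
rerun or extend the validation design on new data.

## The classifier

A visit is **avoidable** when all five criteria hold:

| criterion | avoidable | potentially avoidable |
|---|---|---|
| age (years) | 18–70 (inclusive) | 18–70 |
| triage acuity (CTAS) | 4 or 5 | 3 |
| specialist consulted in ED | no | no |
| main physician intervention | in the configured code registry | same |
| visit outcome | discharged | discharged |

Every other visit is **not avoidable**.  The registry of
subacute-manageable intervention codes (CCI-style) is user configuration —
a plain-text list, one code per line; a clearly synthetic registry ships
for simulation and testing.

## The validation pipeline

* `edac.design` — even cluster sampling by EDAC class; blinded dual-rater
  assignment (each visit to two distinct raters, fixed batch sizes with
  rotated 7/7/6 cluster composition); Monte-Carlo power for kappa criteria.
* `edac.agreement` — percent agreement, pooled-marginal Cohen's kappa
  κ = (p_o − p_e)/(1 − p_e) with p_e = p² + (1−p)² from the pooled two-slot
  marginal, Landis–Koch interpretation, confidence-score summaries,
  bootstrap CIs.
* `edac.association` — the 3×3 class × concordance table, tie-corrected
  Spearman ρ, a proportional-odds (cumulative-logit) fit by damped Newton
  iteration, closed-form headline odds ratios with Wald CIs, and Harrell's
  concordance index.
* `edac.precision` — rating-level accuracy/sensitivity/specificity with
  exact Clopper–Pearson CIs under three regroupings of the middle class.
* `edac.synthetic` — a cohort/judgement generator matching the reference
  marginals, and the frozen 160-visit reference concordance table.
* `edac.io` / `edac.cli` — CSV readers/writers, the `run_full_study`
  pipeline, and an `edac` command-line tool.

## Worked example

```python
>>> from edac import reference_fixture, pooled_kappa, reported_or, EDACClass
>>> table = reference_fixture()          # 160 dual-rated visits
>>> pairs = table.to_pairs()
>>> round(pooled_kappa(pairs).kappa, 2)
0.69
>>> orv, ci = reported_or(table, EDACClass.AVOIDABLE)
>>> round(orv, 1), (round(ci[0], 1), round(ci[1], 1))
(80.0, (17.1, 374.9))
```

Physicians agreed on 139/160 visits (86.9%); a pooled kappa of 0.69 means
substantial chance-corrected agreement, establishing paired physician
judgement as the criterion standard.  The odds that *both* physicians judge
a visit subacute-suitable are 80 times higher for EDAC-avoidable visits
than for not-avoidable ones.

The numbered drivers under `analysis/` narrate the full study:

```sh
python analysis/01_simulate_cohort.py --seed 1   # synthetic 54/53/53 cohort
python analysis/02_design_study.py   --seed 1   # blinded 320-rating plan
python analysis/03_agreement.py                 # kappas + interpretations
python analysis/04_association.py               # Spearman, ORs, c-index
python analysis/05_precision.py                 # middle-class regroupings
python analysis/06_power.py --seed 1            # power curve for the design
```

`analysis/05_precision.py`, for example, prints:

```
exclude_potential: accuracy 83.2% sensitivity 68.9% specificity 97.2% (n=214 ratings)
potential_as_avoidable: accuracy 82.8% sensitivity 68.9% specificity 89.7% (n=320 ratings)
potential_as_not_avoidable: accuracy 61.6% sensitivity 43.4% specificity 97.2% (n=320 ratings)
merging middle class downward: accuracy -21.6 pp, sensitivity -25.5 pp
```

— i.e. the potentially-avoidable class behaves like the avoidable one, not
like the not-avoidable one.

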