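# plgfcea

Within-trial cost-effectiveness analysis of placental growth factor
(PlGF) testing for suspected pre-eclampsia, built as a tested, reusable
Python pipeline.

## The problem

Around 10% of pregnant women are investigated for suspected
pre-eclampsia. Serum PlGF testing (categorised as normal >100 pg/ml,
low 12–100 pg/ml, very low <12 pg/ml) alongside a management algorithm
lets clinicians stratify surveillance, which changes how maternity and
neonatal resources are used. This package implements the economic
evaluation of that intervention as run alongside a stepped-wedge
cluster-randomised trial: eleven maternity units all start under usual
care and cross over to revealed PlGF testing one unit per 6-week step.

Because no individual-level trial data are public, the package ships a
first-class synthetic-data generator that emulates the trial's
structure (≈434 usual-care vs ≈571 revealed-testing women, the nine
PlGF × final-diagnosis subgroups, zero-inflated over-dispersed
resource-use counts with centre random effects and a secular trend,
and severe maternal adverse events at 5.4% vs 3.8%). Every stage also
accepts real data in the same delimited-text schema.

## The model

1. **Resource-use models** (`plgfcea.resource_models`). Each resource
   category (outpatient attendances; antenatal, labour-ward, postnatal,
   maternal ICU/HDU bed days; infant ICU/HDU and SCBU days) is fitted
   with a generalised linear mixed model: nine subgroup indicators, an
   arm × subgroup interaction, fixed linear time, and a random centre
   intercept integrated by adaptive Gauss–Hermite quadrature. The
   default family is the two-part (hurdle) model
   `E[Y] = Pr(Y > 0) · E[Y | Y > 0]` with a logistic use part and a
   zero-truncated negative binomial positive part; the family per
   category is chosen by AIC, with a logistic + linear fallback when
   nothing converges. Output: adjusted mean (and SE) per category ×
   subgroup × arm.
2. **Costing** (`plgfcea.costing`). Quantities × weighted unit costs
   (2016/17 GBP, activity-weighted across Healthcare Resource Groups;
   one weighted per-day cost for all neonatal admissions). Delivery is
   costed by mode but reported separately — bed-day reference costs
   already embed it, so adding it would double count.
3. **Probabilistic model** (`plgfcea.psa`). 5000 Monte Carlo iterations
   resample every adjusted mean from a zero-truncated normal, form the
   cost difference (PlGF − usual) per cell, weight cells by the observed
   subgroup mix to a per-woman figure, and draw per-arm adverse-event
   rates from mean-preserving Beta(r, n−r) distributions. Outputs: the
   probability that testing is cost-saving (fraction of iterations
   strictly below zero) for maternal / infant / combined costs with and
   without the £70 test, a £50–£200 test-price sensitivity sweep,
   events avoided per 1000 women, and the cost-effectiveness
   acceptability curve from net monetary benefit
   `NMB(λ) = λ·ΔE − 1000·ΔC` per 1000 women.
4. **Reporting** (`plgfcea.reporting`). Publication-shaped tables, CEAC
   points, and the national extrapolation
   `round(births × p_suspected × p_preterm) × per-woman saving`.

## Worked example

```sh
plgf-cea all --seed 1 --out-dir results/
```

prints (abbreviated):

```
all: seed=1 config=c58a4f03029d
all: simulated 1005 women -> results/records.csv
all: outpatient: family=two_part_truncNB fallback=False
...
all: p(saving|maternal)=0.998 p(saving|combined+test)=1.000 per-woman saving incl. test £2,904
all: wrote 8 artifacts under results/
```

Reading this: one synthetic trial of 1005 women was generated; AIC
selected the two-part truncated-negative-binomial family for every
category; and in this trial realisation the Monte Carlo model put the
probability that revealed testing saves money (test cost included) at
essentially 1, with a mean per-woman saving of £2,904. The per-woman
saving varies substantially between synthetic trial realisations
(different `--seed`) because neonatal lengths of stay are heavy-tailed
and centre effects are shared across arms — the PSA probabilities
quantify parameter uncertainty *within* one trial, not variation across
trials. The written artifacts include the cost-difference tables
(actual, weighted and percentage-cost-saving per subgroup cell), the
test-price sweep, `ceac.csv`, and `national_scaling.json`, which chains
the per-woman saving through 646,794 annual births × 10% suspected
pre-eclampsia × 30% preterm presentation = 19,404 eligible women.

Stages can also be run separately (`simulate`, `fit`, `psa`, `report`)
against the documented CSV schemas, and the whole pipeline is available
as library functions.

## Data and caveats

The packaged unit-cost table (`plgfcea/data/unit_costs_synthetic.csv`)
and the resource-use levels in the default configuration are synthetic
calibrations with realistic NHS magnitudes — they are not a published
cost schedule, so absolute cost outputs from the default configuration
illustrate the method rather than reproduce published totals. Supply
`--unit-costs` and a configuration file to run against real inputs.
See `docs/methods.md` for model details, assumptions and limitations.
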