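# pa-cea

Cost-effectiveness model of treatment strategies for primary aldosteronism
(PA) in hypertensive patients, from a healthcare-payer perspective in Japan.

PA is a curable cause of secondary hypertension: an aldosterone-producing
adenoma (APA) can be localized by adrenal venous sampling (AVS) and removed
by adrenalectomy or destroyed by radiofrequency ablation (RFA). Segmental
AVS (sAVS) samples the tributaries of the adrenal veins and localizes the
lesion precisely enough to guide ablation; conventional AVS (cAVS) samples
the central veins only. The package asks whether a comprehensive workup —
screening the whole hypertensive cohort, confirming PA, localizing with
AVS and treating APA by surgery or RFA — is worth its upfront cost compared
with treating everyone with antihypertensive drugs alone.

## Model

A decision tree resolves each of five strategies (comprehensive sAVS+RFA,
sAVS without RFA, cAVS with RFA, cAVS without RFA, medication only) into
weighted sub-cohorts with one-time costs, annual drug costs and a risk
profile. Each sub-cohort then runs through a four-state annual-cycle Markov
cohort model (hypertension → heart failure / stroke / death) over 32-year
(men) or 38-year (women) horizons with 2 %/year discounting. Outcomes are
expected costs *C* (JPY) and quality-adjusted life-years *E*; strategies are
compared by the incremental cost-effectiveness ratio

    ICER = ΔC / ΔE   [JPY per QALY]

against a societal willingness-to-pay (WTP) threshold λ = 5,000,000
JPY/QALY. Sensitivity layers provide a one-way tornado analysis, a horizon
(life-expectancy) sweep, and a Monte-Carlo probabilistic sensitivity
analysis (beta-distributed probabilities/utilities, gamma-distributed
costs, moment-matched). An independent individual-level microsimulation
validates the cohort engine.

## Worked example

```python
from pa_cea import default_parameters, compare_all

params = default_parameters()          # the published inputs
print(compare_all(params, "male")[["cost", "qaly", "incr_cost",
                                   "incr_qaly", "icer"]].round(3))
```

prints

```
                         cost    qaly  incr_cost  incr_qaly        icer
strategy
comprehensive    3440698.312  20.502  34130.317      0.058  591557.475
savs_no_rfa      3443326.564  20.502  36758.569      0.058  637111.162
cavs_rfa         3451848.120  20.495  45280.125      0.051  893065.787
cavs_no_rfa      3446167.914  20.500  39599.919      0.055  714646.429
medication_only  3406567.995  20.444        NaN        NaN         NaN
```

Reading: screening and treating costs a 50-year-old man ~34,000 JPY more
than medication alone over his remaining life but buys 0.058 QALYs, an ICER
of ~0.59M JPY/QALY — far below the 5M JPY/QALY threshold, so the
comprehensive strategy is preferred. The comprehensive strategy is also the
cheapest of the four workup variants; precise localization (sAVS) gains
QALYs at lower cost than cAVS, and ablation without segmental localization
(cavs_rfa) adds cost without benefit.

The same analyses are available from the command line:

```sh
pa-cea cea --sex both --out results.csv
pa-cea dsa --out tornado.csv --plot tornado.png
pa-cea sweep --out sweep.csv          # ICER vs horizon; prints the crossing
pa-cea psa --n 10000 --seed 1 --out psa.csv
pa-cea validate --strategy comprehensive --n 100000 --seed 7
```

Custom inputs go in a YAML file (any subset of parameter ids; the rest fall
back to the shipped defaults) passed with `--params`, or via
`ParameterSet.with_values` in Python.

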