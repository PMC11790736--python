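# Methods

## Scope and structure

The package evaluates five management strategies for a cohort of 50-year-old
patients with stage I–III hypertension, 10 % of whom have undiagnosed
primary aldosteronism (PA):

1. **comprehensive** — screen everyone (aldosterone/renin ratio + loading
   tests), CT + segmental adrenal venous sampling (sAVS) for confirmed PA,
   adrenalectomy for surgical PA (APA), radiofrequency ablation (RFA) for
   the subset of APA judged ablatable (8.5 %);
2. **savs_no_rfa** — as (1) but all APA go to surgery;
3. **cavs_rfa** — conventional (central-vein) AVS, with RFA;
4. **cavs_no_rfa** — conventional AVS, surgery only;
5. **medication_only** — antihypertensive drugs for everyone, no workup.

The model is a decision tree (diagnosis/treatment phase) feeding a
four-state annual-cycle Markov cohort model (long-term phase) with states
hypertension (HTN), heart failure (HF), stroke, and death. HF and stroke
are chronic: their only exit is death. The analysis takes a healthcare-payer
perspective; all costs are in JPY, effectiveness in QALYs, and both are
discounted at 2 %/year. Horizons are 32 years (men) and 38 years (women),
the remaining life expectancy at age 50.

## Decision tree

The whole cohort incurs the screening cost. Confirmed PA (prevalence 0.1)
additionally incurs CT + AVS. Among successful AVS (success 1.0 at the
point estimate; the failure branch exists and activates in sensitivity
analyses), a fraction has surgical PA — 0.48 under sAVS, 0.461 under cAVS,
reflecting localization quality — and the remainder (bilateral hyperplasia)
stay on medication. Treated APA splits into clinical-success tiers per the
standardized surgical-outcome criteria: drug-free success (no annual drug
cost), success on reduced drugs, and lack of clinical success (full PA drug
cost). Sub-cohort masses multiply along branches and always sum to 1;
upfront costs add along branches and are charged undiscounted at model
start.

Three structural conventions here are not fixed by the source material and
are exposed as switches on `ModelConfig`, with defaults frozen by
calibration against the published strategy table (see *Calibration*):

- `treated_pa_risk` (default `"pa"`): medically managed PA — bilateral
  hyperplasia, AVS failures, failed ablations — keeps the elevated
  untreated-PA complication risk rather than the essential-hypertension
  (EHT) risk. Medication controls blood pressure but not the
  aldosterone-specific organ damage.
- `excision_failure_risk` (default `"cured"`): patients whose adenoma was
  surgically removed follow cured-PA transition probabilities even when
  blood-pressure outcome is classified "lack of clinical success"; the
  outcome tiers then drive medication costs only. The alternative
  (`"treated"`) routes them to `treated_pa_risk`.
- `rfa_requires_segmental` (default `True`): ablation guided by
  conventional AVS cannot be targeted (the side is known, the segment is
  not) and yields no clinical success; the lesion is left intact, so those
  patients follow `treated_pa_risk`. Ablation guided by sAVS succeeds and
  leaves patients drug-free (point estimates 1.0).

## Markov engine

Per cycle, the HTN occupancy transitions to HF / stroke / death with
risk-profile-specific annual probabilities (cured / pa / eht rows of the
input table); HF and stroke decay only by their own death probabilities;
death is absorbing. Rewards: the HTN state pays the sub-cohort's annual
drug cost at utility 1.0; HF and stroke pay their follow-up costs at
utility 0.9 (their follow-up costs replace, not supplement, the drug cost —
`drug_in_event_states=False`); one-time event costs (HF 3,463,446 JPY,
stroke 298,855 JPY) are charged to the mass newly entering those states in
the cycle of entry.

Two timing conventions are configurable and calibrated:

- `reward_timing` (default `"start"`): cycle rewards use state membership
  at the start of the cycle; `"end"` uses post-transition membership, and
  `"half"` averages the two (the usual half-cycle correction).
- `discount_start_cycle` (default `1`): the first cycle's rewards are
  discounted by 1/1.02; `0` leaves them undiscounted.

There is no age trend in mortality, no tunnel states and no second events;
the inputs are constant annual probabilities.

## Cost-effectiveness layer

Strategies are compared pairwise against medication-only:
ICER = ΔC/ΔE in JPY per QALY, with standard dominance classification
(cheaper-and-better = dominant, costlier-and-worse = dominated, ΔE = 0 →
no ratio). Preference uses a 5,000,000 JPY/QALY willingness-to-pay
threshold, inclusive at the boundary (immaterial in practice). ICERs are
reported unrounded. No efficiency-frontier sequencing is attempted beyond
the pairwise comparisons.

## Sensitivity analyses

**One-way DSA (tornado).** Each parameter in turn moves to the ends of its
range — ±20 % for costs, ±8 % for utilities, ±30 % for probabilities
(clamped to [0, 1]), 0–4 % for the discount rate — and the full pipeline is
re-run at each endpoint; parameters are ranked by the induced ICER spread.
The published tornado covered 26 parameters; the enumeration that counts
exactly 26 from the input table is: the six one-time diagnosis/treatment
costs, the eight decision-tree probabilities, the eleven transition
probabilities and the discount rate (annual medication costs and utilities
excluded). That set ships as `TORNADO_PARAM_IDS` and is the default for
the acceptance surface; `tornado()` can vary any parameter set. Over the
enumerated 26 the discount rate has the largest spread and every endpoint
ICER stays below 5M JPY/QALY; over all 35 non-cycle parameters the stroke
and treated-hypertension utilities would outrank the discount rate, because
the untreated-PA profile accumulates substantial stroke-state occupancy.

**Horizon sweep.** The model horizon stands in for remaining life
expectancy. ICERs are computed at every integer horizon from 1 to 50
years; the fractional crossing of the WTP threshold is located by linear
interpolation between adjacent integers at 0.01-year resolution, after
checking monotonicity (all crossings are reported if the curve is not
monotone). At the default inputs the ICER falls below 5M JPY/QALY at a
horizon of 8.88 years.

**PSA.** Each of 10,000 draws jointly samples all non-fixed parameters
independently: beta distributions for probabilities (sd = 10 % of the mean)
and utilities (sd = 5 %), gamma for costs (sd = 10 %), all fitted by method
of moments ("standardized difference" is read as the coefficient of
variation — the only reading that yields well-defined beta/gamma fits for
every input). Parameters at the boundary (probabilities and utility equal
to 1.0) are held fixed, as are the discount rate and cycle counts.
Competing-risk rows whose sampled exit probabilities exceed 1 are rejected
and redrawn as a whole row; the redraw count is reported (zero in practice
at these variances). Draws are reproducible under a fixed seed; both sexes
can share draws because they differ only in horizon. The full pipeline is
evaluated per draw; ~99 % of draws fall below the WTP line at the default
conditions.

## Validation oracle

`microsimulate` is an independent individual-level implementation: it
routes each simulated patient through the decision tree by categorical
sampling and steps them through the Markov chain year by year with the same
reward and discount rules, implemented as per-individual state stepping
rather than occupancy-vector propagation (no shared stepping/accounting
code). The cohort engine's expectations agree with microsimulation means
within 3 standard errors at n = 100,000 across 20 randomized valid
parameter sets — the central correctness property of the package.
`random_parameter_set` draws valid inputs (feasible competing-risk rows,
probabilities in [0, 1], positive costs, horizons 1–60) for property tests.

The microsimulation and the random-parameter generator are test
instruments: they emulate the model's own stochastic assumptions, not
clinical reality, so agreement demonstrates internal correctness of the
cohort arithmetic, not external validity of the inputs.

## Calibration of the frozen conventions

The switch combination shipped as `DEFAULT_CONFIG` was selected by grid
search against the published strategy table. The decisive evidence is in
the QALY increments, which are insensitive to the (shared) EHT background:
under start-of-cycle rewards with discounting from cycle 1 and the
excised-APA-cured reading, the per-cured-patient QALY gain is 1.2020
(male) and 1.2698 (female) against 1.1908 / 1.2660 implied by the published
incremental QALYs (0.9 % / 0.3 % apart), and the published QALYs of the
cAVS-without-RFA arm reproduce exactly to the printed precision. The
failed-ablation-under-cAVS convention is forced by the published cost
ordering of the suboptimal strategies, which is otherwise impossible
(ablation is cheaper than surgery and would dominate if it cured).

## Known limitations

- **The printed inputs do not reproduce the printed absolute levels.**
  Under every convention combination in the documented switch space, the
  absolute expected costs come out 21–29 % above, and absolute QALYs 1–3.6 %
  below, the published per-strategy values; back-solving the published
  table per risk profile indicates the published EHT background behaves as
  if its HF incidence were ~0.001/yr rather than the printed 0.0266/yr, and
  the published cost increments imply ~20 % larger per-cured savings than
  the printed inputs generate. The package computes what the inputs imply;
  the comprehensive-vs-medication ICER at the shipped inputs is ~592k
  (men) / ~435k (women) JPY per QALY rather than the published 201,482 /
  3,399 — on the same side of the WTP threshold and leading to the same
  decision, but not numerically coincident. Relative results (orderings,
  tornado ranking, WTP-crossing horizon, PSA share below WTP) reproduce.
- One-year cycles without half-cycle correction by default; event costs at
  the cycle of entry.
- No procedural complications of AVS/RFA, no recurrence after cure, no
  second cardiovascular events, no age-dependent background mortality, no
  non-healthcare costs, no currency/inflation adjustment.
- PSA samples parameters independently; no correlation structure.
- HF and stroke exit probabilities are low (1.54 %/yr and 0.505 %/yr), so
  event states accumulate occupancy over long horizons; results are
  correspondingly sensitive to the stroke-state utility and follow-up cost.
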