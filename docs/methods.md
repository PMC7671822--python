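# Methods

## Model structure and conventions

The model is a six-month decision tree feeding a Markov cohort model in
3-month cycles from month 6 to a 15-year horizon (58 cycles). All costs are
2016 GBP from a UK NHS perspective; costs and QALYs are discounted at 3.5%
per annum. The structure follows the established NHS spinal-cord-stimulation
appraisal model: response status is fixed at month 6 and implanted patients
leave it only by device explant, death, or the transient with-complication
toggle.

Decision tree (months 0–6). A screening trial (up to 14 days; its duration
is below cycle resolution and accrues no QALYs) succeeds with the arm's
trial-success probability; failures pay the trial and electrode-removal
costs and join CMM alone. Implanted patients explant early with the
half-year share of the Year-1 explant rate, 1 − (1 − p₁)^0.5, under a
constant within-year hazard; early explants are treated as occurring before
response classification and receive the full six months of CMM-alone
therapy cost (a simplification of negligible magnitude). Response and
complication status are drawn independently — only marginal probabilities
are available. Every branch accrues six months of the applicable therapy
cost and half a year of state utility, and the whole block is discounted at
the mid-period factor (0.25 years). Mortality is not applied inside the
tree: six-month all-cause mortality is ≈0.4% and the pathway has no death
branch.

Markov model (months 6–180). Annual probabilities are converted to
per-cycle probabilities as 1 − (1 − p)^h (constant hazard, h = 0.25 years).
The explant rate in force is the Year-1 rate for cycles before month 12
(its first half was consumed by the tree), the Year-2 rate for months
12–24, and the common 3.2%/year thereafter. Explanted patients join CMM
alone, reaching optimal relief once on entry with the CMM response
probability (9.3%). Patients with no perceived relief may receive spinal
surgery (reoperation) in **any** cycle — 5% per cycle, of whom 19% achieve
optimal relief — the only route out of the no-relief state besides death.
We model reoperation as a recurring per-cycle opportunity rather than a
one-off branch because the source describes it among the events that can
change a patient's state "during each 3-month cycle", and because the
recurring reading is the only one that reproduces the published 15-year
QALY totals (the one-off reading under-predicts them by 6–10%). The CMM
reoperation cost is not printed in the source cost table and defaults to
£0 (configurable as `shared.cost_reoperation`).

Non-serious complications beyond month 6 are transient one-cycle events:
the affected fraction pays the complication cost and carries the
with-complication utility for that cycle, reverting unless re-drawn. The
beyond-6-month complication probabilities (3.7% for 10 kHz, 12.8% for
low-frequency devices) are interpreted as covering the trial's 18-month
observation window (months 6–24) and spread per cycle as
1 − (1 − p)^(h/1.5). Under this reading the model's device-related
adverse-event cost category matches the published £387 / £712 within 10%;
reading the same numbers as annual probabilities overshoots both by
13–21%. (The source annualises explant rates explicitly but never says the
complication figures are annual.)

Mortality (0.81%/year, flat, state-independent) is applied first within
each cycle; death is absorbing. Device replacement falls at integer
multiples of the device longevity strictly inside the horizon, rounded to
the nearest whole cycle, and is always accepted, never fails, and does not
reset explant hazards; the surviving implanted mass pays the reimplantation
cost (equal to the implantation cost in the base case). Utilities and
therapy costs accrue on the end-of-cycle occupancy and all within-cycle
accruals are discounted at the cycle midpoint; no additional half-cycle
correction is applied. CMM responders carry the optimal-relief utility
(0.598); the source does not state a separate utility for them.

## Parameters

All inputs live in `src/scs_cea/config/default_config.json` (schema
version 1): per-arm clinical probabilities (the two low-frequency arms
share one clinical block), device costs and longevities, shared CMM/cost
parameters, utilities, and run settings (3.5% discount, 15-year horizon,
0.25-year cycles, £20,000/QALY). Each sampled entry records a 95% CI (or
plausible range) and a sampling family. Key defaults: trial success
92.8%/88.0%; optimal relief at 6 months 80.9%/54.4% (CMM 9.3%); explant
rates 4.4–4.7%/year (10 kHz) vs 9.7–11.1%/year (LF) in years 1–2, 3.2%
both thereafter; device longevity 10 y (10 kHz, RLF) vs 4 y (NRLF); implant
costs £16,648 / £11,281 / £17,422.

## Uncertainty analyses

One-way analysis sets each bounded parameter to its lower and upper 95%
confidence limit; entries are ranked by outcome span (incremental cost, or
incremental net monetary benefit for the cost-utility view, which stays
finite under dominance) and the top ten form the tornado diagram.
Threshold analysis bisects a single parameter until the objective residual
(incremental cost, or incremental NMB at £20,000/QALY) is within £1;
non-bracketing objectives return a "no threshold within range" result
rather than an error. Packaged scenarios: equal explant rates of 3.2%/year
for every device, equal non-serious complication rates (all devices at the
higher low-frequency rates — conservative against 10 kHz), the
alternative equal-price system-costing scenario (replacement systems
£14,201 / £10,499 / £14,201), and `horizon_<N>y`.

PSA. Probabilities and utilities are drawn from beta distributions and
costs and device longevity from gamma distributions, moment-matched to the
printed intervals with SE = (CI width)/3.92; beta fits whose interval is
too wide to match fall back to a uniform draw on the interval. Sampling is
keyed per (seed, draw, quantity) substream, so results are independent of
evaluation order and bit-reproducible. Two deliberate joint-sampling rules
encode how the source constructed its inputs: parameters printed as the
*same assumption* (identical value, interval and family — the Year-3+
explant rate, the 10-year longevity of the 10 kHz and RLF devices, the two
sub-optimal utilities) are one uncertain quantity drawn once; and the
implant costs, whose intervals were constructed by a common proportional
difference, share one relative gamma deviate (relative intervals are
quantised at 0.1%, within the pound-rounding of the printed values). These
rules reproduce the published PSA dispersion (our Δcost standard deviations
≈£14.0k / £8.9k against ≈£14.5k / £8.6k implied by the published CIs of
the mean); fully independent draws give £16.7k / £18.0k and a much too low
probability of cost-saving against RLF. Utilities are sampled although the
source names only probabilities, costs and longevity; their independent
draws may occasionally invert the with/without-complication ordering, which
is accepted for sampled sets and enforced only for explicitly configured
ones. Sampled longevity is floored at one cycle. Default 5000 draws; the
normal-approximation CI of the mean cost difference is the headline, with
a percentile interval alongside.

## Synthetic trial data

`trial_synth` simulates patient-level records with the structure the
clinical inputs were estimated from: Bernoulli screening success, and for
implanted patients Bernoulli responder/complication indicators plus an
explant time over 24 months from a two-piece constant-hazard model matching
the Year-1 and Year-2 annual probabilities. Explant reasons are
paresthesia-weighted in year 1 and ineffective-pain-weighted in year 2
(weights 0.55/0.25/0.20 and 0.20/0.60/0.20 for paresthesia / ineffective
pain / other — chosen to mirror the reported qualitative pattern; the
source gives no numeric split). Estimation uses simple proportions with
Wald 95% CIs (the printed inputs carry symmetric CIs): denominators are all
implanted patients, except the Year-2 explant rate which uses patients
still implanted at month 12; zero denominators yield an undefined estimate,
not zero. What this generator does *not* emulate: VAS trajectories, opioid
use, within-patient correlation between outcomes, loss to follow-up, and
site effects — so passing recovery tests shows estimator/model consistency,
not robustness to those real-data features. At 100 patients per arm the
aggregate Wald coverage across the twelve re-estimated inputs is ≈93%
(Wald intervals under-cover for the rare explant outcomes); at 10⁵ patients
per arm the recovered inputs reproduce the deterministic totals to <0.1%.

## Numerical choices and problem sizes

The cohort engine validates row-stochasticity to 1e−12 and conserves state
mass to 1e−12 per cycle; totals equal trace sums to 1e−9. Monetary outputs
are rounded to the nearest pound only at the reporting edge. Dominance is
classified on strict inequalities; exact ties report a signed-infinite or
zero ICER with a tie flag. Test-suite problem sizes: 10⁶ patients for the
decision-tree oracle, 2×10⁵ for the Markov oracle (agreement within 3
Monte-Carlo SEs), 500 replicates for interval coverage, 5000 PSA draws.

## Known limitations

- Response status cannot improve or deteriorate spontaneously after month
  6; no later SCS re-trial is offered to CMM patients.
- Mortality is flat (not age-dependent) and independent of health state.
- The recurring reoperation opportunity implies a patient can undergo
  several reoperations over 15 years; with a £0 reoperation cost this
  affects only QALYs, where it calibrates the no-relief pathway to the
  published totals.
- PSA parameters are otherwise independent: no correlation between
  response and explant rates, and no parameter uncertainty on structural
  conventions (cycle length, hazard shapes).
- The published PSA mean cost-saving against RLF (£3,552) sits 26% below
  the published deterministic increment (£4,795) while the NRLF figures
  differ by only 5%; since both comparators share every clinical parameter,
  no sampling structure over the printed inputs reproduces that asymmetry,
  and this model's RLF PSA mean stays close to its deterministic value
  (≈£4.4–4.8k).
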