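# Methods

## The model

`cowvalue` implements a bio-economic replacement-decision model for dairy
herds. A cow's life is a discrete-time Markov chain with monthly steps over
states

> (parity *p*, month in milk *m*, month in pregnancy *g*),

with *g* = 0 for open cows and a single absorbing CULLED state. Default
bounds are *p* ≤ 12 and *m* ≤ 24; enumeration allows every *g* ≤ min(9,
*m* − 1). From any live state at most three things can happen in a month:
the cow is culled (cause-specific hazard), an eligible open cow conceives,
or she advances deterministically — open cows age one month in milk,
pregnant cows advance gestation, and at *g* = 9 the cow calves into
(*p* + 1, 1, 0). Two boundary rules make the chain absorbing with
certainty: open cows at the month-in-milk ceiling are culled, as are cows
whose next calving would exceed the parity ceiling. Conception is eligible
from month in milk 2 and only while a full 9-month gestation still fits
inside the grid (*m* ≤ *m*<sub>max</sub> − 9), so a conception in month
*m* leads to a calving 10 grid-months later and the shortest calving
interval is 11 months.

Each cow-month is priced by a monthly contribution margin (MCM):

> MCM = (milk + calf + cull income) − (feed + veterinary + insemination +
> replacement cost).

Expected milk yield follows Wood lactation curves *y*(*m*) = *a m*^*b*
e^(−*c m*) fitted per parity class {1, 2, 3+} by least squares on the
log-linearised model; an individual cow enters as a multiplicative effect
(her mean test-day ratio to the herd curve), which is stable on few test
days where per-cow Wood fits are not. Cows are dry (zero milk) in the two
months before an expected calving. Milk is component-priced with linear
fat/protein surcharges around reference contents. Feed cost uses a
net-energy balance — maintenance ∝ metabolic weight, 3.14 MJ NEL per kg
energy-corrected milk, a late-gestation surcharge in pregnancy months 7–9
— covered by roughage up to a maximum dry-matter intake and by concentrate
beyond it. Veterinary cost is a flat monthly average; insemination is
charged to open cows from month in milk 3; a culled cow's terminal month
is credited carcass income (or a live-sale value for cows sold alive).

The engine computes expected quantities exactly from the fundamental
matrix of the absorbing chain: with transient kernel Q, the expected
remaining months N, expected future calvings and expected total cash all
solve sparse systems (I − Q)x = rhs; (I − Q) is factorised once per herd
and reused for every cow. The average MCM of a stream is expected total
cash divided by expected remaining months (all pre-absorption months count
in the divisor, dry months included; no discounting), and

> cow value = avg MCM(cow) − avg MCM(replacement heifer),

where the replacement starts at (1, 1, open), performs at the herd-average
curve, and is charged the heifer acquisition cost in her first month. With
a free, identical replacement the cow value of a fresh first-parity cow is
exactly zero — a structural identity the tests assert. A vectorised
Monte-Carlo path simulator over the same kernel provides an independent
oracle for every analytic expectation.

What-if scenarios modify only the cow stream: a yield multiplier scales
her expected milk; a one-time health cost is charged at month offset +1
weighted by the probability of surviving to it (reducing expected total
cash by exactly cost × survival — an identity tested at 1e-9); a pregnancy
override re-seeds the start state. The health shock is a pure cost — it
does not raise the culling hazard, which would require parameters the
model does not have.

## Estimation from herdbook records

Monthly state paths are reconstructed per cow: parity from calvings, month
in milk from the last calving, pregnancy backdated exactly from the next
calving inside completed lactations. The final lactation is right-censored
(by culling or by the period end), so its pregnancy status is inferred
from the insemination non-return rule: the cow is presumed to have
conceived at her last recorded service if no return to service follows
within the observed window. This matters: without it every cull is
attributed to an open state and open-state hazards are badly inflated,
because truly pregnant exposure leaks into the open cells.

Transition probabilities are maximum-likelihood cell frequencies with a
back-off hierarchy for sparse cells — state → pooled over parity → pooled
over month in milk → global — entered whenever a cell holds fewer than 20
observations. Structural zeros (no conception outside eligibility, forced
calving at *g* = 9, forced boundary culls) are imposed on top.

The decision audit evaluates every cow at her last observed month,
classifies the sign of her cow value against the farmer's actual decision
into four quadrants (replaced too soon / correctly culled / retained OK /
retained too long; a value of exactly zero counts as retain-optimal), and
aggregates losses: `replaced_loss` books the (negated) positive values of
prematurely culled cows, `not_replaced_loss` the negative values of cows
kept too long; both are reported ≤ 0. The replacement rate divides annual
cullings by the average monthly herd size.

## Synthetic data

The generator simulates each cow month by month from a ground-truth
kernel and emits exactly the record types a herdbook export contains
(calvings, monthly test days, inseminations, culling events with coded
reasons), so every downstream stage can be validated against known truth.
Defaults describe a Swiss-style commercial herd:

| parameter | default | note |
|---|---|---|
| monthly conception probability | 0.40 / 0.35 / 0.31 by parity class | eligible open cows, flat over months in milk |
| monthly all-cause culling hazard | 0.012 / 0.020 / 0.032 by parity class | annual replacement rate in the low-to-mid twenties (%) |
| hazard cause mix | fertility 26%, udder 23%, sold alive 14%, performance 10%, … | the removal-reason profile of Swiss field herds |
| Wood (a, b, c) | (620, 0.18, 0.035) / (700, 0.22, 0.045) / (750, 0.25, 0.050) | kg/month scale; ~6,500–7,500 kg lactations |
| test-day noise | lognormal, σ = 0.1 | strictly positive yields |
| between-cow effect | lognormal, σ = 0.1 | multiplicative |

Test-day milk is rounded to 0.01 kg so a write/read round trip is
byte-exact, and identical (truth, months, seed) inputs reproduce identical
herdbooks. All initial cows calve in the first simulated month (a startup
herd) and culled cows are replaced by fresh heifers the following month,
holding herd size constant; heifer rearing time is not modelled because
the economics charge an acquisition cost, not a rearing lag. Multi-farm
studies draw per-farm herd sizes (20–100 cows) and lognormal farm effects
on hazards, conception and milk scale.

What the generator does *not* emulate: seasonal calving patterns
(year-round calving is assumed), genetic trends or selective breeding,
within-lactation hazard shape beyond the parity-class level, missing or
miscoded records (the reader handles those, but the generator emits clean
data). Passing recovery tests therefore show estimator correctness under
the model's own assumptions, not robustness to real-world data defects.

## Economic defaults

Dataset-average prices (CHF): milk 0.797/kg, veterinary 977.20/cow/year,
insemination 66.80/service, heifer 3,123.33, roughage 0.409/kg DM,
concentrate 0.88/kg DM, slaughter 3.69/kg carcass, calf 7.33/kg live
weight. Quantities the price set needs but the source data do not fix are
set to Swiss-typical values and are all config-exposed: live weight 650
kg, dressing fraction 0.54, calf sale weight 75 kg, live-sale value 1,800
CHF for cows sold alive, fat/protein references 4.0%/3.3% with surcharges
0.03/0.05 per percentage point, NEL densities 5.5 (roughage) and 7.0
(concentrate) MJ/kg DM, maximum roughage intake 16 kg DM/day, maintenance
0.293 MJ NEL per kg metabolic weight per day, gestation surcharges
13/18/26 MJ/day in months 7–9.

## Numerical choices

Row-stochasticity is enforced at 1e-12. Expected values use sparse LU
solves (exact up to float error); the iterative occupancy trajectory stops
when unabsorbed mass falls below 1e-9, with a hard horizon of
*p*<sub>max</sub> × *m*<sub>max</sub> months and a truncation warning at
residual ≥ 1e-6. The Monte-Carlo oracle's average-MCM estimator is the
ratio of path-summed cash to path-summed months (matching the analytic
ratio-of-expectations definition) with a delta-method standard error.
Wood fits require ≥ 6 test days over ≥ 4 distinct months; below that the
caller falls back to the pooled herd fit. When fit groups (cow ids) are
supplied, parameter standard errors are cluster-robust by cow, since test
days of one cow share a cow effect and naive errors would be several times
too small. Zero cow value classifies as retain-optimal; unknown culling
reason strings map to "others" with a warning; herdbook reads abort only
when more than 10% of rows fail validation.

## Known limitations

* A one-time health cost dilutes over the cow's whole expected remaining
  life (~40 months for a young cow), i.e. to roughly 800/40 ≈ 20 CHF per
  month of average margin — *less* severe than a persistent 10% yield loss
  (≈ 25–30 CHF/month at Swiss margins). Published scenario grids that rank
  a one-off 800 CHF event as the worst case imply a much shorter effective
  decision horizon than the remaining-lifetime averaging used here; with
  this model's definitions that ordering reverses, and the package does
  not attempt to reproduce it.
* The bundled 29-farm summary table is internally inconsistent as
  published: the per-farm "replaced" column sums to −1,079.77 (one farm
  carries a positive entry) while the printed sum row says −1,101, and the
  two printed loss totals add to 4,658 rather than the stated 4,608. The
  package stores the per-farm rows exactly as printed and reports computed
  sums; it does not adjust rows to match the printed totals.
* Transitions carry no covariates (breed, season, herd); the replacement
  heifer is assumed to perform at the herd average; contribution margins
  exclude labour, housing and other fixed costs; no discounting.
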