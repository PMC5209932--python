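# Methods

`marketce` implements a marginal ("savings-ordered") cost-effectiveness
framework for deciding in which order an expensive new therapy should take
over the market cells of its rivals, and what that order costs a
single-payer budget. The built-in case study is the 2015 Croatian market
for chronic hepatitis C genotype-1 (GT1) therapy at the moment the
interferon-free OBV/PTV/r/DSV combination entered against pegIFN-based
regimens (dual pegIFN, BOC, TPV, SIM triple therapies).

## Model

Effectiveness is measured solely as sustained virological response (SVR);
the horizon is one year; only direct drug costs (EUR 2015, VAT included)
enter. There is no discounting, no utility weighting (QALYs), and no
health-state transition model — the payer modelled here decides on budget
impact, not utility-based allocation.

The unit of cost-effectiveness is the **cost per SVR** of therapy *t* in
patient subgroup *g*:

    CPS_{t,g} = C_{t,g} / p_{t,g}

with *C* the full-course cost and *p* the SVR probability. Subgroups form
a 4 x 2 x 2 lattice: treatment history (naive, relapser, partial
responder, null responder) x GT1 subtype (1a, 1b; mixed/unknown infections
are folded into 1a) x cirrhosis (none, compensated). The twelve non-naive
("experienced") cells form the population the market scenarios act on;
naive patients keep dual pegIFN as standard of care and appear only in the
cost-effectiveness tables.

### Sampling model

Published SVR rates are literature *ranges*. Each Monte Carlo draw takes

* SVR ~ Uniform(low, high) per (therapy, subgroup) cell — the
  maximum-entropy choice on a bounded interval; the sampler is pluggable
  (`sample_svr(..., sampler=)`) for anyone preferring e.g. a Beta;
* course cost: the single printed cost, or for response-guided protocols
  with a short and a long course, one of the two printed costs with equal
  probability (`AnalysisConfig.cost_variant_prob`, default 0.5 — no
  response-guided split is published).

**Savings per SVR** of the new entrant against rival *r* in cell *g* is
the per-run difference `CPS_{r,g} - CPS_{new,g}` on common random numbers
(same draw index per cell), so the reported savings range reflects joint
variation. Reported minima/maxima are empirical Monte Carlo extremes;
analytic support bounds are available as a cross-check
(`analytic_cost_per_svr_bounds`).

For intervals with `low > 0` the mean cost per SVR has the closed form
`E[C] * ln(high/low)/(high - low)` (`E[C]/low` for a point estimate),
implemented as `analytic_mean_cost_per_svr` and used as an independent
oracle in the tests — it is never the production path. Intervals touching
zero (BOC in cirrhotic null responders, 0–34 %) have no finite expectation;
their simulated mean is heavy-tailed and unstable by nature, which is why
the corresponding published table cell is blank. Draws with SVR exactly 0
(probability zero under continuous sampling; only attainable for a
degenerate [0, 0] interval) are excluded from summaries with a logged
count. A point SVR with a single cost short-circuits to the exact ratio
with sd exactly 0.

### Takeover tiers and scenarios

Each eligible experienced (subgroup, rival) cell is assigned a tier from
its savings summary *S*:

| tier | rule | reading |
|------|------|---------|
| 1 | min *S* > 0 | new entrant cheaper per SVR in **every** run |
| 2 | mean *S* > 0, min *S* <= 0 | cheaper on average, with downside risk |
| 3 | −threshold <= mean *S* <= 0 | dearer on average by at most EUR 10 000 |
| 4 | otherwise | clearly dearer per SVR |

The tier-3 threshold (EUR 10 000) is the case study's own boundary; the
boundary is inclusive at exactly −threshold. Scenario *k* (k = 1..4)
reassigns to the new entrant the pre-entry shares of every cell with tier
<= *k*; scenario 0 is the pre-entry market and scenario 4 full takeover.
Takeover sets are nested by construction.

The pre-entry market mix is **not** an observable input. Two stylised
strategies are provided: `cheapest_per_svr` (default; each subgroup's
whole share on the rival with lowest mean cost per SVR, ties alphabetical
— a rational-payer assumption) and `equal_eligible` (equal shares across
eligible rivals) for sensitivity. Every scenario-level result depends on
this choice.

### Outcome simulation

Each of the `n_runs` (default 10 000) paired runs draws

1. an annual experienced population: total ~ discrete-uniform on
   90–100, allocated over the twelve cells by one multinomial draw with
   cell probabilities `history x subtype x cirrhosis` (independence
   assumption);
2. one (SVR, cost) pair per (therapy, subgroup) cell — shared by all
   scenarios (common random numbers);
3. per scenario and subgroup, patients apportioned to share-holding
   therapies by largest-remainder rounding (remainder ties favour
   therapy-name order, so conservation is exact);
4. block successes ~ Binomial(block size, drawn SVR), inverted from a
   per-cell uniform shared across scenarios (inverse-CDF coupling):
   scenarios treating a block identically get identical successes, and a
   scenario compared with itself differs nowhere. An `expectation` mode
   (successes = size x SVR) is provided for variance-free validation.

Outputs per scenario: total cost, treated count, SVR count per run; from
the paired runs, budget impact (`Δcost` vs scenario 0, plus percent
increase), percent achieving SVR, expenditure per achieved SVR, and the
ICER

    ICER_k = mean(Δcost) / mean(ΔSVR)

as a **ratio of paired-run means** — per-run ratios are unstable when the
SVR gain is small; ratio-of-means is the standard health-economics
convention. A non-positive mean SVR gain yields a tagged
undefined/dominated result rather than an exception.

### Random-number architecture

All streams are named children of one master seed
(`SeedSequence(master_seed, spawn_key=sha256(name))`): one per quantity
per (therapy, subgroup) cell, one for population totals/allocation. Stream
identity depends only on the name, never on creation order, so adding an
analysis perturbs nothing, results are bit-reproducible, and the same cell
sees the same draws in the cost-effectiveness table, the savings table and
the outcome simulation (which is what makes the savings mean decompose
exactly into the difference of cell means).

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `n_runs` | 10 000 | Monte Carlo runs (also used by the acceptance script) |
| `master_seed` | 20 150 | seed of every derived stream |
| `tier3_threshold` | EUR 10 000 | scenario-3 takeover boundary |
| `baseline_strategy` | `cheapest_per_svr` | pre-entry market mix assumption |
| `reporting_rounding` | EUR 100 | display granularity; internals stay unrounded |
| `cost_variant_prob` | 0.5 | probability of the first response-guided course |
| population `total_range` | 90–100/yr | experienced GT1 patients (expert estimate) |
| `subtype_props` | 1a 0.36 / 1b 0.64 | published (22 % 1a + 14 % mixed folded into 1a) |
| `history_props` | 0.40/0.30/0.30 | relapser/partial/null — **assumption, not published** |
| `cirrhosis_prop` | 0.30 | compensated cirrhosis share — **assumption, not published** |

The history and cirrhosis splits are calibration knobs: no composition of
the 90–100 experienced patients across cells was ever published. They are
surfaced in the input bundle and should be swept in any serious
sensitivity analysis; all scenario-level aggregates (percent cured, budget
impact, ICER) move with them, while per-cell cost-per-SVR results do not.

## Synthetic data

`synth.generate_inputs` produces structurally valid random input sets:
per-cell uniform SVR intervals (floored at 0.01 so the closed-form oracle
exists; `allow_zero_floor` lifts this to exercise the exclusion path), one-
or two-variant costs, product-form populations. `new_dominates` forces the
new entrant's SVR interval strictly above every rival's with a cost at or
below the cheapest rival — provably tier 1 everywhere; `new_dominated`
forces the reverse (never tier 1/2). `generate_degenerate_inputs` makes
every quantity closed-form (point SVRs, single costs, one populated cell,
fixed total of 60), enabling exact end-to-end checks in expectation mode.
What the generator does **not** emulate: correlation between axes of the
composition, multi-year uptake dynamics, price–volume agreements, or any
real epidemiology; passing tests on synthetic data certify the machinery,
not the realism of any particular market.

The number of active cells (`n_subgroups`) is factored over the lattice
axes (1, 2, 3, 4, 6 or 12 cells); other values cannot be expressed under
the product-form composition and are rejected with a diagnostic.

## Numerical choices

* Monetary values are stored unrounded; rounding to EUR 100 happens only
  in reports (`round(x/100)*100`, banker's at .5 — never hit by the case
  study values).
* Summary invariant `min <= mean <= max` is checked with a 1e-9 relative
  tolerance to absorb accumulation round-off over 10 000 identical values.
* Largest-remainder apportionment adds 1e-12 before flooring to absorb
  `n * (1/n)` round-off.
* Percent-to-fraction conversion of table values rounds to 12 decimals so
  the stored double equals the parsed decimal literal (exact IO round
  trips).

## Known limitations

* The scenario-level acceptance band is dominated by the two unpublished
  composition assumptions and by the pre-entry market mix. Under the
  default (`cheapest_per_svr`) baseline the first expansion step takes
  over only SIM-held cells (all non-cirrhotic null responders and
  cirrhotic GT1b null responders), giving an ICER of ~EUR 15 700 per
  additional SVR for *any* composition — the published case-study value
  (~EUR 21 000) appears to assume a mixed pre-entry market, which however
  would push the pre-entry cure rate well below the published 69 %. No
  single baseline assumption reproduces both; we keep the default and
  report the discrepancy in the reproduction report rather than tuning.
* Likewise, whether full takeover raises or lowers expenditure per SVR
  relative to the pre-entry market is composition-sensitive; the default
  assumptions give a slightly lower value, the published analysis reports
  a slightly higher one.
* One published per-SVR average (new entrant, naive/GT1a/cirrhosis,
  printed 95 200) is not reproducible from the printed inputs: direct
  division gives 90 000/0.946 = 95 137 → 95 100 at EUR 100 rounding. The
  computed value is reported and the discrepancy documented.
* Cells whose SVR interval touches zero have heavy-tailed cost-per-SVR
  distributions with no finite expectation; their simulated means and
  maxima are reported but should be read as "effectively unbounded".
* Statistical post-processing of simulation output (ANOVA, post-hoc
  contrasts) is out of scope; the run-level CSVs feed any standard tool.
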