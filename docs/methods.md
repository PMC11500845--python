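# Methods

## Cohort model

A deterministic Markov cohort model follows the fractional occupancy of
a screening-naive cohort from `start_age` (default 35) to `end_age`
(default 100 — a conventional lifetime cap; "lifetime horizon" is
otherwise unquantified) in one-year cycles.  Recorded states are
`no_ht`, `undiagnosed_ht`, `wcht_transient`, `ht_controlled`,
`ht_uncontrolled`, `cvd`, `dead`.  Two further clinical states — "new
HT diagnosis" and "temporary WCHT" — are tunnels resolved within the
cycle they are entered: a true-positive screen routes to
`ht_uncontrolled`, a false positive to `wcht_transient`, before the
cycle's vector is recorded.

### Event order within a cycle

The source narrative fixes the state graph but not the within-cycle
event order, so the engine commits to one and documents it:

1. **Incidence** — a fraction `ht_incidence[band(age)]` of `no_ht`
   develops latent hypertension.
2. **Screening** — the pool not yet carrying a diagnosis (`no_ht`
   survivors, the cycle's latent cases, and `undiagnosed_ht`) is
   screened every year (annual campaign; previously diagnosed people,
   including WCHT, are never re-screened).  The split is
   π·Se / π·(1−Se) / (1−π)(1−Sp) / (1−π)·Sp with π the pool's
   true-hypertension fraction.  Screening before CVD/mortality lets the
   test detect both prevalent and incident cases in the year they
   arise.
3. **WCHT progression** — people occupying `wcht_transient` at cycle
   start develop true hypertension at the general incidence rate and
   move to `ht_controlled` (they are already under treatment); the
   cycle's new WCHT entrants start progressing the following year, so
   no one undergoes two screening-classification events in one cycle.
4. **Control switching** — `ht_controlled` ↔ `ht_uncontrolled` at the
   configured annual probabilities, including the cycle's new
   diagnoses (they pass through the tunnel before this step).
5. **CVD incidence** — first events from `undiagnosed_ht` (at
   uncontrolled-group risk, reflecting untreated disease),
   `ht_uncontrolled`, and `ht_controlled` (lower risk).
6. **Mortality** — competing risks applied sequentially, each
   probability conditional on surviving the previous event: CVD case
   fatality (0.00699/yr below age 45; 0.0853/yr at 45 and older — the
   boundary age belongs to the older stratum) on all CVD occupants,
   then background non-CVD mortality on every alive state.

No half-cycle correction is applied.  Occupancy is conserved to 1e-12
per cycle and `dead` is absorbing; both are enforced, and a transition
pushing any occupancy negative raises an error naming the state and
age.  People with undiagnosed hypertension who suffer a CVD event enter
`cvd` and are thereafter managed as patients (the event reveals the
disease).

### Serial test composition

CBPM and HBPM errors are assumed conditionally independent given true
status — the only assumption under which a serial test's Se/Sp is a
function of the components'.  Confirmation of positives (Serial1)
multiplies sensitivities and complements-multiplies specificities;
testing of negatives (Serial2) does the dual.  Both formulas are
property-tested against brute-force enumeration of the four joint test
outcomes.

## Economics

Costs (2021 Thai baht, societal perspective: direct medical plus direct
non-medical; productivity losses excluded) and QALYs are discounted at
3%/yr, cycle 0 undiscounted.  Mapping per person-year:

| state / event        | medical cost            | non-medical cost     | utility |
|----------------------|-------------------------|----------------------|---------|
| no_ht                | —                       | —                    | 1       |
| undiagnosed_ht       | — (untreated)           | —                    | 0.95    |
| wcht_transient       | controlled-HT cost      | 4 visits             | 1       |
| ht_controlled        | controlled-HT cost      | 4 visits             | 0.95    |
| ht_uncontrolled      | uncontrolled-HT cost    | 8 visits             | 0.95    |
| cvd (incident event) | acute admission cost    | 9.83 inpatient days  | 0.62    |
| cvd (prevalent)      | chronic annual cost     | 8 visits             | 0.62    |
| dead                 | —                       | —                    | 0       |

WCHT persons are managed as (needlessly) treated hypertensives: they
accrue the controlled-HT cost with utility 1 — this is precisely the
economic harm of a false positive.  The CVD utility 0.62 is the
stroke/CAD case-mix weighting (0.55×0.64 + 0.75×0.36); the
hemorrhagic/ischemic split enters only through inputs, never as a
separate state.  Screening cost per cycle is screened mass × the
strategy's expected per-person cost, with the serial second-stage
routing fraction recomputed each cycle at the screened pool's current
true-HT fraction.

**Life years.** The published comparison table pairs lifetime LY totals
near 40 with QALY totals near 22 under a 3% discount — consistent only
with undiscounted LYs alongside discounted QALYs.  `EconomicResult`
therefore carries both `total_ly` (discounted) and `total_ly_undisc`;
the report table and LY-based ICERs use the undiscounted totals to
mirror that presentation.

ICERs are Δcost/ΔQALY with an explicit dominance class (dominant /
dominated / NE trade-off = cost per QALY gained / SW trade-off = cost
saved per QALY lost); ΔQALY = 0 leaves the ratio undefined rather than
dividing.  Report tables round costs and ICERs to whole baht and
LY/QALY to 4 decimals; internal arithmetic is full precision.

## Sensitivity analysis

**One-way (tornado).** Each varied parameter is set to its (low, high)
bound — from the parameter file, defaulting to ±25% of base clipped to
[0, 1] for probabilities/utilities, since the source prints no ranges —
with the full model rerun at each bound; entries sort by ICER swing.
Ranges are validated against every parameter invariant before any
model run.

**PSA.** Health-economics convention: beta distributions for
probabilities and utilities, gamma for costs, method-of-moments from
(mean, SE); the source states only that draws follow "probability
distributions".  The synthetic default dispersions are SE = 10% of the
mean for probabilities/utilities (capped for beta feasibility near 0
and 1) and 20% for costs.  Structural quantities (discount rate, visit
counts, admission length, the utility anchors 0 and 1) are held fixed.
Complementary fraction pairs (stroke/CAD, hemorrhagic/ischemic) are
drawn once and closed to sum to 1, so every draw is itself a valid
parameter set.  All strategies are evaluated on the same draw (common
random parameters) with `default_rng([seed, replication])`, making each
replication reproducible in isolation.  The default 1000 replications
complete in well under a minute.

**CEAC.** At each willingness-to-pay value on the grid (0–500,000 baht
in 10,000 steps, always containing 160,000) a strategy's probability is
the fraction of replications in which it attains the maximum NMB; exact
ties split the mass equally, so probabilities sum to 1 by construction.

## Calibration

Targets are hypertension prevalence (undiagnosed + controlled +
uncontrolled among the alive, averaged over each band's cycles) by age
band.  Each incidence band overlapping a target band (and, optionally,
each background-mortality band) receives a multiplicative scalar fitted
by coordinate-wise bounded scalar minimisation (`minimize_scalar`,
derivative-free and deterministic) of the sum of squared prevalence
residuals, with the full model rerun per evaluation under the CBPM
strategy (true prevalence is insensitive to the screening test).
Scalars are bounded so probabilities stay in [0, 1]; binding bounds are
reported as clipped.  Adjacent-band scalars are collinear (earlier
incidence raises all later prevalences), so convergence needs multiple
sweeps; the default is 25, and the objective is non-increasing across
accepted moves.  On synthetic-truth fixtures the search recovers known
band-wise perturbations to well within 5% relative error.

## Synthetic data

The published model's full calibrated parameter table is not publicly
available, so `synthetic_data.default_parameter_set` emulates its
structure: all values printed in the source literature are embedded
verbatim (provenance `paper`), and unprinted values take documented
stand-ins (provenance `stand-in`) at realistic Thai-adult magnitudes —
hypertension incidence rising from ~1.5%/yr at 35–39 to ~4.5%/yr at
60–79; CBPM Se/Sp 0.74/0.79 and HBPM 0.86/0.62 (meta-analytic
magnitudes against ambulatory monitoring, giving Serial1 the highest
specificity and Serial2 the highest sensitivity, as expected);
life-table-shaped background mortality; HT care costs of a few
thousand baht/yr and an acute CVD admission of 60,000 baht.
Generation is deterministic; the seed only labels emitted files.

What this means for test evidence: the suite demonstrates structural
correctness (conservation, absorption, oracle equivalence, composition
algebra, discounting, recovery of known calibration truths) and exact
reproduction of the published derived arithmetic from its printed
operands.  It does *not* certify the published headline totals, which
depend on the unavailable calibrated inputs; with the stand-ins the
model nonetheless lands in the same qualitative regime (Serial1
cost-saving with a small QALY loss and ~100% acceptability at 160,000
baht/QALY; HBPM and Serial2 not cost-effective).  The generator also
omits real-world features the source flags as limitations: imperfect
screening adherence, within-week HBPM reading schedules, and secular
trends in costs.

## Numerical and interface choices

* Problem sizes: 65 annual cycles per lifetime run (35→100); test and
  acceptance calibration runs use a 35→80 horizon, and the acceptance
  PSA uses the full 1000 replications.
* Parameter file: one `key: value` header (structural settings) plus a
  CSV table with per-parameter value, PSA family/SE, OWSA bounds and
  provenance; round-trip (save→load) is exact, and validation reports
  *all* invariant violations, each naming parameter, value and rule.
* Age bands default to 35–39, 40–49, 50–59, 60–69, 70–79, 80–99
  (decadal, matching how age-specific results are quoted in the field).
* Prevalence summary: both time-averaged (headline) and terminal
  prevalence are exposed, since summary definitions vary between
  reports.
* Plotting is intentionally out of scope: tornado, CE-plane and CEAC
  exports are plot-ready delimited tables.
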