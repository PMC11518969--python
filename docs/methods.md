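# Methods

## Scope and purpose

`simpop` simulates a population of individual agents ("simulants") living in
residential households and group quarters (GQ), evolving under discrete-time
demographic and economic events, and observed through simulated
data-collection systems. Its purpose is to produce linked, privacy-free test
data for entity-resolution research: the observed tables expose the fuzzy
identity fields real linkage runs on, while a ground-truth simulant id makes
evaluation exact. It is a desk-scale re-implementation of the modeling
approach used for production synthetic-population datasets of hundreds of
millions of simulants; everything here runs in seconds to minutes at
populations of 10²–10⁵.

The record-corruption layer (typos, OCR errors, blanks, nicknames) that such
benchmarks usually add on top is deliberately out of scope, as are survey
weighting, census undercount, cause-specific mortality, retirement, multiple
simultaneous jobs, and business dynamics (openings, closures, renames,
mergers).

## Clock

The simulation starts at `start_date` (default 2019-01-01) and advances in
`step_days`-day steps (default 28) until the clock strictly exceeds
`end_threshold_date` (default 2041-05-01): the defaults give exactly 292
steps. A run whose start equals its threshold still executes one step.

Hazard rates λ per person-year convert to per-step probabilities by the
exponential-survival rule `p = 1 − exp(−λ · step_days/365.25)`, clamped to
stay strictly below 1. This is the standard discrete-time treatment when
competing risks within a step are not modeled.

Within a step, components run in a fixed order: mortality → fertility →
domestic individual migration → domestic household migration → emigration →
immigration → employment change → observers due in the step's date window.
The order is a design choice (it only affects within-step interactions); one
consequence is that a simulant cannot both die and give birth in the same
step. Simulants created mid-step (newborns, immigrants) are not at risk for
events until the following step; a newborn whose uniformly drawn birth time
is the first instant of the step counts as at-risk from that step, a
deliberate simplification.

Each (component, step) pair draws from its own `numpy` Generator seeded by
`[master_seed, component_key, step]`, so runs are bit-reproducible and one
component's draw volume cannot perturb another's stream.

## Synthetic calibration fixtures

All inputs are generated by `simpop.fixtures`; none are calibrated to real
data. They reproduce the *structure* the simulator needs:

* **Microdata** — household-clustered person records with integer ages,
  binary sex, raw race code + Hispanic flag, one of 13 relationship values,
  GQ/institutional flags, positive lognormal sampling weights, and
  foreign-born / recent-immigrant flags. Household sizes are truncated
  geometric (mean ≈ 2.5, cap 12), giving the small-household-dominant shape
  of real census microdata. Member ages are generated relative to the
  reference person's age per relationship (children ≈ 18–40 years younger,
  parents 20–35 older, …). Race and ethnicity are drawn at the household
  level and copied to members with 10% individual resampling. Defaults: 14%
  foreign-born, 1% recent immigrants, 2% GQ.
* **Rate tables** — deterministic functions of a `RateConfig` (the seed is
  reserved for optional jitter and currently unused, which keeps calibration
  checks sharp). Mortality is Gompertz, `λ(a) = λ₀·exp(b·a)` with λ₀ = 1e-4,
  b = 0.085 and a 1.5× male factor — monotone in age within sex by
  construction. Fertility is a fixed age schedule over 15–49 summing to a
  total fertility rate ≈ 1.8. Domestic migration is 0.12 moves/person-year
  (0.07 per household-year) with a young-adult peak. Emigration is 0.002
  events/person-year split over three move types, 5× higher for the
  foreign-born. Immigration is expressed as yearly event counts per
  reference population of 10,000 (defaults 8 household, 3 GQ-person, 12
  non-reference events/year) and scaled by the engine to the run's target
  population; the tables' "events per year" framing only makes sense at a
  fixed scale, hence the reference-population convention.
* **Name tables** — Zipf-shaped frequencies over fixed name pools per (sex,
  birth decade) for first/middle names and per race/ethnicity for surnames,
  with configurable minimum-frequency floors (defaults 5 and 100) emulating
  the privacy suppression of rare names in real source files.
* **Location-name corpus and address lexicon** — word-pool-generated business
  names (1–4 words, shared vocabulary so bigrams recombine) and street/city/
  state/zip component lists.

Five-year age groups (0–4 … 80–84, 85+) stratify every rate table; the
granularity is a design choice matching typical demographic rate tables.

What the fixtures do **not** emulate: real marginal or joint distributions of
any US attribute, geography below state level, spouse relationships (the
13-value relationship list has none), household structures rarer than the
generator produces, and correlation between names and any attribute other
than the stratifiers. Tests passing on these fixtures therefore demonstrate
the *mechanics* (rules, invariants, calibrated rates), not demographic
realism.

## Population initialization

Entities — whole non-GQ households, or individual GQ persons — are sampled
with replacement, probability proportional to weight (the reference person's
weight for a household), until the present count reaches the target. Because
the source table is small relative to the target, many simulants share a
source record; to avoid clones the ages are perturbed: nominal integer age +
uniform(0,1) fraction first, then one standard-normal shift (in years)
shared by the whole entity, then a sign flip of any negative result. The
order — fraction, shared shift, per-member flip — keeps the shift
interpretable as an entity-level perturbation while letting a household
shift push only an infant negative. Date of birth is then set to
`start_date − round(age·365.25)` days, so age and DOB agree to within a day.

Six GQ units (one per kind) are created up front with their own addresses;
GQ residents get a uniformly random kind consistent with their
institutional flag and no tracked relationship. Residential mailing
addresses are a PO box with probability 0.1 (configurable; the rate is a
design choice, only the mechanism being prescribed). US-born simulants
always hold an SSN; foreign-born hold one with probability 0.5
(configurable — the nativity→SSN link is qualitative, not quantified, in
the source setting).

## Demographic events

**Mortality.** Each present simulant dies with the per-step probability of
their (age group, sex) hazard. A dead residential reference person triggers
succession: the oldest remaining present member (by DOB) becomes reference
person — even an unrealistically young one — and other members are remapped
by a fixed table: members sharing a child-type relationship with the new
reference person become "Sibling"; other kin collapse to "Other relative";
non-kin (roommate, foster child, other nonrelative) become "Other
nonrelative". Emptied households are closed and their addresses vacated,
never to be reissued.

**Fertility.** Present female simulants of any age face the age-specific
birth hazard (the table confines it to 15–49; keeping the restriction in
data rather than code is deliberate). Each birth event occurs at a uniform
time within the step and is a twin event with probability 0.04. Newborns
inherit household, race/ethnicity and (at name assignment) surname from the
single identified parent; they are US-born with an SSN, and their
relationship to the reference person derives from the parent's: child of the
reference person → biological child; child of a child → grandchild; deeper
or lateral kin → other relative; child of a non-kin member → other
nonrelative. A GQ-resident parent's newborn stays in the parent's GQ with no
tracked relationship — a documented oddity (a college dorm acquiring an
infant) preferred over inventing an unstated rehousing rule. No birth
spacing is enforced; the rates make consecutive-step births rare.

## Migration

**Domestic individual moves** (at most one per simulant per step) send the
mover to a new one-person household (becoming reference person), an existing
residential household chosen uniformly (always entering as "Other
nonrelative"), or a uniformly chosen GQ kind, with a configurable
destination split defaulting to 0.5/0.4/0.1. The uniform join-target rule
means every open household is equally likely to receive a mover. Because
joiners are always "Other nonrelative", the share of that relationship in
census output drifts upward over a multi-decade run — the direction is a
structural consequence and is tested; the magnitude depends entirely on
calibration and is not asserted.

**Domestic household moves** relocate an entire household of more than one
present member — hazard read off the reference person's demographics — to a
fresh address, relationships untouched, old addresses vacated.

All movers aged 18+ change employment (same resampling as a change event).

**Emigration** removes simulants permanently via household moves (triggered
through the reference person, removing every present member and closing the
household), GQ-person moves, and non-reference-person moves (which by
construction can never remove a reference person, hence never trigger
succession). Emigrated simulants are dropped from all subsequent
observation.

**Immigration** adds entities cloned from the recent-immigrant subset of the
microdata at constant Poisson rates (yearly counts × step fraction), with no
seasonal or temporal variation. Cloned ages keep their source integer age
(uniform fraction only, no normal shift). Household moves preserve internal
relationships; GQ-person moves take a uniformly chosen kind consistent with
the record's institutional flag; non-reference-person moves join a uniformly
chosen open household with their source relationship, downgraded to "Other
nonrelative" if the source record was itself a reference person.

## Employment and income

Employers (default 100) get initial sizes from a log-normal with σ = 1.5 —
a few large, many small (Gini ≈ 0.7). Assignment is one categorical draw
with probability proportional to initial size, with "unemployed" (weight
0.05) and a single military employer (0.01) inside the same draw; the
weights are design defaults, only the three-state structure being
prescribed. Working-age (18+) simulants, including the unemployed, change
employment at 0.5 changes/person-year; a change re-runs the same draw — it
may land on the same employer and still counts as a change — so employer
shares remain proportional to initial sizes indefinitely. Simulants becoming
18 (or arriving as adults) get a first assignment that does not count as a
change event.

Wages are log-normal per (age group, sex, race/ethnicity), independent of
employer, resampled at assignment and at each change, zero when unemployed.
The stratum parameters are synthetic and uncalibrated: median
32,000 × an age profile peaking near 48 × small sex/race factors, σ = 0.8 on
the log scale. Employers carry a tax-form kind (85% W2, 15% 1099) as an
employer-level attribute.

Employment stints (simulant, employer, income, start, end) are recorded in
an append-only ledger — one open stint per simulant — from which tax tables
are reconstructed.

## Identity post-processing

Names, taxpayer IDs and employer names are assigned after the dynamic run
(they would be dead weight to carry through the simulation). First and
middle names are drawn frequency-weighted within (sex, birth decade); the
full middle name is stored and schemas that want an initial take the first
letter. Surnames are drawn by race/ethnicity for simulants without a tracked
mother; with probability 0.05 a surname is compounded with a second draw,
joined by a hyphen or space with equal odds. In-simulation births inherit
the mother's surname, processed in birth order so chains resolve; twins
therefore share surname, household, address and date of birth — the
deliberately hard linkage cases. First and last names are independent; the
real-world correlation between them is an acknowledged omission.

SSNs are uniform over the valid space — area 001–899 excluding 666, group
01–99, serial 0001–9999, i.e. 898 × 99 × 9999 = 888,931,098 numbers —
rendered `AAA-GG-SSSS` and globally unique (collisions redrawn; exhaustion
aborts). ITINs use the same mechanism with a leading 9 and group ranges
50–65, 70–88, 90–92, 94–99, and are issued only to tax filers without an
SSN, at observation-finalization time.

Employer names come from a random walk over a word digraph built from the
location-name corpus: nodes are words plus `<start>`/`<end>` sentinels, and
each adjacent word pair contributes one multi-edge (stored as an integer
count on an aggregated `networkx` DiGraph). Walks start at `<start>`, choose
outgoing edges with probability proportional to count (= uniform over
multi-edges), and stop at `<end>` or after `max_path_length` (default 10)
words, emitting the truncated name rather than rejecting it. Every adjacent
word pair in a generated name therefore occurs somewhere in the corpus.

## Observers

All observers emit only simulants present at the observation date and always
include the true simulant id.

* **Decennial census**: April 1 of years divisible by 10; full enumeration,
  one row per present simulant with floored age (calendar years completed),
  DOB, sex, race/ethnicity, relationship, household address and kind.
* **Tax**: per completed calendar year, rebuilt from the stint ledger — one
  W2/1099 row per stint overlapping the year (employer's form kind, wages =
  stint annual income × overlapping fraction of the year), plus one 1040 row
  per present working-age filer with summed wages and their SSN or ITIN.
  Simulants who died or emigrated before the year-end observation date are
  excluded.
* **WIC**: each January 1, covering the prior year; members of residential
  households whose summed income falls below 1.85 × (13,000 + 4,600 per
  additional member), restricted to women with a birth event that year and
  children under 5. All three constants are configurable assumptions.
* **Household survey**: a generic census-shaped survey sampling residential
  households independently (default 1% every 13th step). It stands in for
  recurring surveys generally and claims fidelity to none in particular.

Schedules are design choices; the source setting names the datasets but not
their timing.

## Verification strategy and known limitations

The test suite checks, among others: the accounting identity
`present(t+1) = present(t) + births + immigrants − deaths − emigrants`
exactly at every step; recovery of configured rates (twin fraction, the
0.5/person-year change rate, a constant mortality hazard) within 3 standard
errors at fixed seeds; weight-proportionality of initialization sampling and
size-proportionality of employer shares by chi-square at α = 0.001;
exhaustive SSN format validity and uniqueness at 10⁵ issues; bigram closure
of every generated employer name; hand-enumerated walk probabilities on a
toy corpus; and the upward drift of the census "Other nonrelative" share
across 20 seeded multi-decade runs (direction only). `scripts/acceptance.py`
recomputes the twin percentage (≥ 10,000 events from a 2,000-female pool at
an inflated 2.0/year hazard, ~25 steps) and the employment-change rate
(1,000 adults × 65 steps); problem sizes were chosen so each quantity's
Monte-Carlo error is well inside its tolerance while the script stays fast.

Beyond the fixture caveats above: household sub-structure does not interact
with migration (children move alone; spouses — unmodeled anyway — would not
move together); relationship does not affect emigration; all households are
equally likely to gain or lose individual movers; GQ is represented as one
unit per kind, so all college residents share an address; income does not
feed back into fertility, mortality or migration; and the simulation has no
notion of marriage, adoption (beyond the static relationship code), or
guardianship.
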