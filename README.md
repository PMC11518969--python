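# simpop

An individual-based microsimulation of a national population, built to
manufacture realistic, ground-truth-linked test data for **entity resolution
(ER)** research. Real record-linkage work runs on personally identifiable
information — names, addresses, dates of birth, taxpayer IDs — which is
exactly the data researchers cannot freely share. `simpop` sidesteps that by
simulating the people instead: simulants are born, age, die, move, emigrate,
immigrate and change jobs on a 28-day clock, and are then *observed* through
simulated data-collection systems (a decennial census, annual tax filings, a
means-tested WIC program, household surveys). Every output row carries the
true simulant id, so any linkage algorithm run on the observed columns can be
scored exactly.

All calibration inputs are synthetic and bundled: household-clustered
microdata with sampling weights, stratified hazard-rate tables, name
frequency tables, a business location-name corpus and an address lexicon are
generated programmatically by `simpop.fixtures`. They emulate the *shape* of
the public data a production calibration would use (census microdata, vital
statistics, agency name files, a points-of-interest corpus), not their actual
distributions — so nothing here requires a download and nothing here is about
real people.

## The model

* **Population.** Entities — whole households or individual group-quarters
  (GQ) residents — are sampled from microdata with probability proportional
  to sampling weight, with replacement, until the target size is reached.
  Integer ages get a uniform fractional part, then each entity receives one
  shared standard-normal age shift; negative results have their sign flipped.
  Race and Hispanic ethnicity composite into seven exhaustive categories
  (Hispanic ⇒ Latino). GQ splits into carceral / nursing home / other
  institutional and college / military / other non-institutional, chosen
  uniformly within institutional status.
* **Events.** Each 28-day step converts stratified hazard rates λ (per
  person-year) into per-step probabilities `p = 1 − exp(−λ·28/365.25)` and
  applies, in fixed order: mortality (age×sex), fertility (age-specific, 4%
  of birth events are twins), domestic migration (individual and
  whole-household), emigration, immigration, and employment change (a flat
  0.5/person-year hazard for everyone 18+, including the unemployed).
  When a reference person dies or moves out, the oldest remaining member
  takes over and relationships are remapped by a fixed kinship table.
* **Identity.** After the run: first/middle names frequency-matched by sex
  and birth decade; last names by race/ethnicity, inherited from the mother
  for in-simulation births (twins share everything but first name); SSNs
  uniform over area 001–899 (never 666), group 01–99, serial 0001–9999,
  unique; ITINs for SSN-less tax filers; employer names generated by uniform
  random walks over a bigram multigraph of a location-name corpus.
* **Accounting.** Every step satisfies
  `present(t+1) = present(t) + births + immigrants − deaths − emigrants`
  exactly, and the event log records each term.

## Worked example

```python
from simpop import engine, fixtures

fx = fixtures.default_fixtures(seed=11, n_households=500)
cfg = engine.SimulationConfig(target_population=1500, master_seed=11, max_steps=20)
res = engine.run(cfg, fx)

print(res.event_log[["step", "present_end", "births", "deaths",
                     "individual_moves", "employment_changes"]].tail(3))
```

```
 step  present_end  births  deaths  individual_moves  employment_changes
   17         1456       1       1                14                  49
   18         1455       4       5                 8                  41
   19         1459       7       3                21                  37
```

About 1,500 simulants live through 20 steps (≈ 18 months): a handful of
births and deaths per step, ~1% of the population moving each step, and
roughly `1500 × 0.037 ≈ 50` job changes per step, the per-step probability
implied by the 0.5/person-year hazard. The 2020 census the run produces
looks like:

```python
census = [o for o in res.observations if o.dataset == "census"][0]
print(census.data.head(4))
```

```
 simulant_id first_name middle_initial last_name  age date_of_birth    sex race_ethnicity     relationship
           0      Caleb              J     Young   34    1985-11-19   Male          White Reference person
           1     Olivia              R    Carter   80    1940-03-07 Female         Latino Reference person
           2       Gail              M     White   35    1984-07-18 Female         Latino Reference person
           3     Gloria              M       Kim   12    2008-03-31 Female         Latino Biological child
```

and the 2019 tax table pairs the same simulants with SSNs, wages prorated
per employment stint, and walk-generated employer names:

```
 simulant_id first_name last_name         ssn                employer   wages tax_form
           0      Caleb     Young 134-29-6876 Red's Family City Grill 28678.0       W2
           1     Olivia    Carter 134-82-4102        Village Pharmacy  3248.0       W2
           2       Gail     White 128-67-7287          Summit Brewing  5737.0       W2
           4     Rachel  Castillo 007-10-7450        Nashville Market  8401.0       W2
```

The `simulant_id` column is the ground truth: any ER method linking the
census to the tax table on the fuzzy columns can be scored against it.

A command-line wrapper does the same end to end:

```bash
simpop-simulate --seed 11 --output-dir out/ --population 1500 --steps 20
```

writing `out/population/` (simulants, households, addresses, employers,
stints, event log) and `out/observations/` (one CSV per dataset-year plus a
manifest).

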