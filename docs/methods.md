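# Methods and design notes

## The screening model

The screen operationalises a *potential* drug-drug interaction (pDDI) as
temporal co-dispensation: drug classes A and B stand in possible conflict,
and a patient was dispensed one drug from each side **within the same
calendar month**. No clinical outcome is modelled; the severity category
(C = monitor therapy, D = consider therapy modification, X = avoid
combination) is carried as metadata and never filters detection, so the
engine can host X-category rules even though the packaged nine are C/D.

Assumptions inherited from the design:

* **Calendar-month granularity.** A pair dispensed on the 31st and the 1st
  of adjacent months is *not* a pDDI; a pair dispensed 30 days apart inside
  one month is. This undercounts true pharmacological overlap (an
  acknowledged conservative bias) but makes the rule auditable on claims
  data without exposure modelling. The day gap between the closest
  qualifying fills is recorded per flagged month (`min_interval_days`);
  same-day pairs are allowed.
* **Dispensation = exposure.** Fills are taken at face value; adherence,
  stockpiling and over-the-counter purchases are outside the data.
* **One month, one flag.** Multiple qualifying pairs in a patient-month
  still yield one flag (`n_pairs` records how many).

### Rules and catalog

A rule is two class *selectors* (sets of class labels), a severity
category, and optional conditions: `require_distinct_substance` for the
self-pair rule (two fills of one substance never interact with themselves)
and `min_daily_dose_mg` applied to side A fills (only the tramadol rule,
200 mg). Antihypertensives are modelled as three subclasses (ACEI, ARB,
beta-blocker) unioned by a selector, keeping the roster auditable while the
rule matches a single combined row. Tramadol is its own class — it is the
only weak opioid in scope and the only dose-conditioned one — whereas
codeine is grouped with the strong opioids, matching its prescription
regime in Poland. Substance matching is case-insensitive, ATC code first,
then name; the catalog carries the alias spelling "nebiolol" for nebivolol
because the source roster circulates with that spelling.

The dose condition is evaluated **per dispensation**, not summed over the
month: a record qualifies if its own daily dose reaches the threshold.
Claims data give a prescribed daily dose per fill, and summing daily doses
across fills of a month would conflate dose with refill frequency.

### Attribution

A flagged month is **co-prescribed** when some qualifying pair in it has
equal, non-empty prescriber IDs. An empty prescriber ID means "unknown" and
matches nothing — a conservative choice that can only underestimate
co-prescribing. At case level the default policy is **any** (a case is
same-prescriber if at least one of its months is); `all` and `majority`
are available because the dichotomisation of multi-month cases is genuinely
underdetermined — "any" is the most sensitive reading and is what
reproduces the published attribution columns when combined with the
month-level percentages.

## Statistics

* **Prevalence** divides *cases* (patient × rule pairs) by the population
  denominator; a patient with two pDDI types counts twice, exactly as the
  published arithmetic implies (2 485 787 / 38 413 139 = 6.47 %). Because
  the phrase "% of the population" invites a unique-person reading, the
  summary also emits a clearly labelled unique-patient prevalence.
* **Persistence** per rule is the mean of the per-case month counts with a
  95 % normal-approximation CI, x̄ ± 1.96·s/√n, s the sample standard
  deviation, computed exactly from the grouped histogram
  (s² = (Σ m²cₘ − n x̄²)/(n−1)). The published material does not state its
  CI construction; the normal approximation is adopted because it
  reproduces every printed interval from the printed histograms (e.g.
  2.16–2.22 for opioids + gabapentinoids, 1.96–2.33 for tramadol +
  SSRIs/SNRIs), which is as strong a validation as the data permit. With
  n in the hundreds of thousands the approximation is unimpeachable; for
  tiny rules (n ≈ 500) it is still adequate for 2-decimal display.
* **Attribution means** over rules are **weighted** — by cases for the case
  percentages and by patient-months for the month percentages. The
  unweighted column mean (≈ 71 %) does not reproduce the published overall
  76.63 %; the case-weighted mean does, so the weighted definition is the
  one the headline numbers actually use.
* **Kruskal–Wallis** (groups = rules, observations = per-case month counts)
  uses the tie-corrected statistic with the χ² approximation on
  groups − 1 degrees of freedom, delegated to `scipy.stats.kruskal`. Ties
  are massive by construction (12 possible values), making the tie
  correction essential. A seeded label-permutation p-value
  (`method="permutation"`) exists for toy inputs where the χ²
  approximation is doubtful.
* All accumulation is integer or full-precision float; **rounding is
  display-only** (half away from zero, `display_round`), applied at the
  published precisions (2 decimals for population percentages and means,
  1 for shares).

## Synthetic data

The generator is **constructive**: episodes are written straight into the
claims stream rather than arising from a behavioural model of prescribing.
This is a deliberate trade — the analysis consumes only the co-occurrence
structure, and constructive generation makes parameter recovery *exact*,
which turns the generator into a usable oracle for the detector.

`simulate(config)` plants, per rule, `n_cases` episodes on dedicated
patients: the month count is drawn from the configured distribution, the
specific months uniformly without replacement, dates uniformly within each
month, substances uniformly from the class rosters (distinct for the
self-pair rule; tramadol at the threshold dose), and each month is
co-prescribed with probability `p_co_prescribed_month`. The defaults are
the published national screen scaled to 1/1000: per-rule volumes, the
per-rule month-count distributions, and co-prescribing probabilities equal
to the published month-level percentages. Around the planted episodes the
pool hosts three kinds of guaranteed-negative traffic: single-substance
background fills (a lone substance can never satisfy any rule), near-misses
(a conflicting pair split across *adjacent* months), and sub-threshold
tramadol months. Patients are partitioned by role and rules are planted on
disjoint patients, so no synthetic patient can trigger a rule other than
their own — this is what makes "recovered exactly" a testable contract
rather than a statistical hope.

What the generator does **not** emulate: patients with several interaction
types (the fixture therefore exercises the cases-vs-unique-patients
distinction only trivially), seasonality, demographics, prescriber panels
with realistic sharing structure, OTC purchases, or non-adherence. Passing
tests therefore certify the *pipeline arithmetic* on data with the assumed
structure, not robustness to real-world messiness beyond what the
validation layer rejects.

`expand_reference_fixture` inverts the published aggregates: for each rule
and month-count m it emits exactly `counts[m]` synthetic patients with a
qualifying pair in m distinct months. Same-prescriber assignment must hit
two totals at once (cases and patient-months), so co-prescribed status is
granted to the longest-persisting cases first — maximising reachable
co-months for a fixed co-case count — then each co-case gets one co-month
and the remainder are distributed longest-first. Requested percentages are
realised to the nearest achievable integers; infeasible requests are
clamped and reported in `notes`. A side effect is that within a rule,
co-prescribing correlates with persistence in the expansion (the real
correlation is unknown — only the two published margins constrain it);
aggregate statistics are unaffected. Scaling uses largest-remainder
apportionment per rule so the scaled histogram keeps the rounded total and
the shape; a rule never scales to zero cases, so the tiniest rules are
over-represented at extreme scales (their scaled means drift from the
full-scale ones — the recovery tests therefore check exactness against the
*scaled* histogram, and closeness to full-scale means only where the
scaled rule keeps ≥ 200 cases).

## Numerical and engineering choices

* Detection is vectorised: claims are classified and factorised to integer
  codes, then per rule a side-A × side-B merge on (patient, month) yields
  qualifying pairs; for identical sides each unordered distinct-substance
  pair is kept once (substance-order filter). A quadratic all-pairs oracle
  in the test suite pins the semantics (flags, intervals, attribution,
  pair counts) on randomised inputs.
* Output is canonically sorted, so results are independent of input record
  order; duplicate (patient, rule, month) flags are a hard error by
  construction and guard against upstream aggregation bugs.
* The fixture expansion materialises records as categorical columns built
  from integer codes (no per-row Python strings); the full national
  expansion (~8.2 M records, ~2.5 M patients) plus detection and statistics
  runs in roughly six minutes and < 4 GB on one CPU.
* Claims validation rejects rows (not files) for unparsable dates, missing
  drug identification, or negative doses, reporting 1-based row numbers and
  reasons; a file fails hard when > 10 % of rows are rejected (configurable).
  Records outside the study window are dropped before detection.
* Randomness is confined to `numpy.random.default_rng(seed)`; identical
  configs give byte-identical output files.

## Problem sizes used by the checks

Unit and property tests run on toy inputs (hundreds of patients, ≤ 5 000
records) plus 1/1000- and 1/100-scale expansions; the acceptance script
defaults to the full national volume, which is where the published numbers
are reproduced exactly (a `--scale` flag trades exactness for speed).

## Known limitations

* Month-boundary blindness is inherent to the rule, not a bug; a sliding
  or multi-month window mode is deliberately out of scope.
* The tramadol dose semantics assume the claims dialect delivers a daily
  dose per fill; data dictionaries that encode pack strength instead need
  mapping before ingestion.
* The unique-patient prevalence across all rules is correct only within a
  run; patients cannot be linked across separate runs.
* `min_interval_days` is reported per month flag but not aggregated into
  the summary tables — it exists for auditing and downstream analyses.
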