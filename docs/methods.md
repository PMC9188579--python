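# Methods

## Cohort model

The unit of analysis is a patient-level "transaction": the set of
3-character ICD-10-CM parental categories a patient accumulated over a
fixed two-year window (default 2016-01-01 … 2017-12-31), across all
encounters. A patient is included iff all of:

1. age ≥ 45 years (as supplied in the demographics table; the analysis
   does not model age at a specific encounter),
2. at least one valid BMI measurement, 18.5 ≤ BMI ≤ 206 (both ends
   inclusive; out-of-range values are dropped, never clamped),
3. an assigned race/ethnicity from the final category list,
4. at least one in-window ICD-10-CM diagnosis record (any chapter), and
5. no in-window ICD-9-CM record (mixed-vintage charts cannot be rolled
   up consistently).

All failed criteria are recorded — exclusion reporting is not
short-circuited at the first failure. Race labels are mapped through a
configurable table: Asian, Pacific Islander and the combined label merge
into "Asian/Pacific Islander"; missing, "Other" and "Mid-Eastern Indian"
are excluded; unrecognized labels are logged and excluded (or raise, in
strict mode). Hispanic participates as a category on the same footing as
the race groups, a known limitation of the source labelling this package
reproduces deliberately.

Strata: age band `middle_aged` (45–64) or `elderly` (65+); obesity class
`with_obesity` iff the unweighted mean of valid BMI values is ≥ 30.
Both cutoffs are inclusive at the boundary.

Denominators: a patient whose in-window codes all fall outside the
chapter filter keeps an empty transaction and still counts in the
stratum denominator — criterion 4 requires a diagnosis, not an *eligible*
diagnosis. `drop_empty_transactions` flips this if a per-diagnosed-patient
denominator is wanted.

## Code eligibility

Codes are upper-cased, the dot and any suffix are discarded, and the
first three characters must match letter-digit-digit; anything else is a
rejection that callers log. Eligibility is decided purely on the
3-character category against a configurable list of inclusive ranges
plus a blocklist. The default includes nine chapters (blood, endocrine,
mental/behavioral, nervous, circulatory, respiratory, digestive,
musculoskeletal, genitourinary) and excludes E66 (obesity), since BMI is
already a stratification axis. Whether every 3-character category in
those chapters, or only a curated chronic subset, should count is
genuinely open; the chapter filter is the documented approximation and
is fully overridable in the run config.

## Mining

`mine_frequent_itemsets` is a single-machine recursive FP-growth:
items are ordered by descending support (ties lexicographic), identical
filtered transactions are merged before tree construction, and mining
proceeds item-by-item from the least frequent through conditional
pattern bases. The minimum support count is ⌈ξ·n⌉ computed as
`ceil(ξ·n − 1e−9)`: the subtraction guards against IEEE round-up on
exact products (0.05·2000 must give 100, not 101), and the comparison is
inclusive — a pattern at exactly ξ is frequent. Output is sorted by
(size, items) so runs are bit-reproducible. No cap on itemset size by
default; `max_itemset_size` exists as a safety valve.

`brute_force_itemsets` enumerates all subsets of the observed universe
(guarded at 20 items) and exists so the miner never has to be trusted:
equality of itemsets *and counts* against this oracle is asserted over
random transaction sets in the tests, alongside downward closure,
threshold monotonicity, and input-order invariance.

## Cross-race classification

Within one (age band, obesity class) cell, every multimorbidity pattern
(size ≥ 2) frequent in at least one race is labelled: `shared_all` iff
frequent in every configured race, `distinct` iff in exactly one,
`shared_some` otherwise. The partition is relative to the configured
race list, so adding a race with no data demotes `shared_all` patterns —
intended behaviour, tested explicitly. For races where the pattern fell
below threshold, exact support counts are recomputed from the raw
transactions (the "gray sector" values): the downstream g-test needs the
full races × (present, absent) table, and display thresholds
(`report_filter`, defaults off) never feed back into classification.
Patterns are never compared across cells.

## Statistics

* **Clopper–Pearson**: lower = BetaInv(α/2; x, n−x+1) (0 at x=0),
  upper = BetaInv(1−α/2; x+1, n−x) (1 at x=n) — the closed form of
  inverting the exact binomial tails. Conservative by construction;
  simulated coverage at n=200, p=0.1 runs ≈ 0.96 at the 95% level.
* **g-test**: G = 2·Σ O·ln(O/E) with 0·ln 0 = 0, df = (r−1)(c−1),
  p from the χ² upper tail. Williams correction available but off by
  default. Zero row/column margins raise a degenerate-table error; the
  pipeline records such patterns with NaN statistics rather than
  failing the run.
* **Kruskal–Wallis**: mid-ranks over the pooled sample,
  H = 12/(N(N+1))·Σ Rᵢ²/nᵢ − 3(N+1), divided by the tie correction
  C = 1 − Σ(t³−t)/(N³−N); all-identical input (C = 0) is an error.
  This is the standard rank statistic, used as an approximation of a
  median-based ANOVA; it is applied to per-patient mean BMI across races
  within each cell as a sensitivity check.
* No multiple-testing correction by default (p < 0.05 is the working
  significance convention); Benjamini–Hochberg is available for callers
  who want it.

## Synthetic data

The generator is the package's study-conditions definition, not a
convenience fixture. Per (race, age band, obesity class) stratum it
draws, per patient:

* cluster indicators Bernoulli(q) for each planted cluster targeting the
  stratum — an active cluster adds all its items;
* independent background Bernoulli(pᵢ) per eligible item
  (pᵢ ∈ [0.005, 0.03] by default, so pairwise background co-occurrence
  is orders of magnitude below the 5% threshold);
* ineligible noise codes (Z51, R06) so transaction filtering and empty
  transactions are exercised; a patient with no items at all receives one
  noise code, keeping criterion 4 satisfied for every valid patient;
* 1–3 BMI values from a normal truncated to the class band
  ([30, 206] at location 34 for `with_obesity`, [18.5, 29.9] at 25.5
  otherwise — locations near typical class medians), which makes class
  membership exact by construction;
* encounters 1 + Poisson(6) (mean 7, cosmetic), uniform in-window dates,
  and a 50% chance per emitted code of a dotted sub-code suffix to
  exercise normalization.

Under this model the joint prevalence of a planted cluster has the
closed form q′ = q + (1−q)·Π pᵢ (items independent given the cluster is
off), which the ledger stores per cluster. When items are shared between
clusters (I10 appears in three default clusters) this is a slight
underestimate of the true joint rate — conservative for recovery checks
in target strata; cross-stratum leakage of planted pairs stays below
~0.005 against a 0.05 threshold.

Default sizes per cell: Caucasian 6000, African American 2400,
Asian/Pacific Islander 1400, Hispanic 1100, Native American 1000,
Biracial 800 — unequal and Caucasian-dominant like real US hospital
samples, averaging ≈ 2100 patients per stratum (50,800 valid patients in
24 strata). The six default clusters plant all three sharing classes
with q between 0.12 and 0.30, giving q′ ≥ ξ + 3·SE margins even in the
smallest stratum, so recovery failures signal bugs, not sampling noise.
Deliberately invalid patients (1% of the valid total per reason) each
violate exactly one criterion, so per-reason exclusion counts must match
the ledger *exactly*. `small_config()` scales the same conditions to
~10% for quick runs and examples.

What the generator does **not** emulate: real diagnostic dependence
structure (comorbidity networks, coding practice variation between
systems), visit-driven observation bias, longitudinal progression, or
within-patient BMI drift. Passing tests therefore demonstrate that the
pipeline recovers known structure under a faithful sampling model — not
that any particular clinical finding generalizes.

## Determinism and outputs

All randomness flows from one `numpy` Generator seeded in the config;
strata are generated and mined in sorted order; all output tables are
sorted — two runs with the same config and inputs are byte-identical.
Every CSV begins with a `# config_hash:` comment (sha256 of the
canonical config JSON) and a `MANIFEST.json` records content digests.

## Problem sizes

The test suite and the acceptance script size their simulations as
follows: oracle equivalence over 100 random transaction sets of ≤ 30
patients × 8 items; CI coverage over 5000 binomial draws; null
calibration of both tests over 2000 replicates (6 groups of 500 and of
50 respectively); end-to-end recovery on the full default cohort
(~53,000 generated patients). These sizes give Monte-Carlo error well
inside the asserted tolerances (±0.02 on a 0.05 rate at 2000 reps) while
keeping a complete run in the tens of seconds.

## Known limitations

* The chapter filter is coarser than a curated chronic-condition code
  list; per-study sub-code lists should be supplied via the config.
* The g-test composition (which races enter each table) defaults to all
  configured races; restricting to races where the pattern is frequent
  is a caller choice.
* Kruskal–Wallis on mean BMI is a rank test, not a robust median ANOVA.
* Single-machine execution: strata are mined sequentially; the loop is
  embarrassingly parallel if ever needed, and results are order-independent.
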