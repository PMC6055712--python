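# Methods

## The problem

Primary-care prescribing records (the CPRD-style "therapy" file) do not
record when a prescription ends. Before any pharmacoepidemiological analysis
of drug exposure, each record's stop date must be derived from one of three
imperfect duration sources — the prescriber-entered treatment days
(`numdays`), the database-derived duration (`dose_duration`), or the implied
supply `qty / ndd` — after cleaning implausible and missing field values,
and the resulting dated prescriptions must be reconciled into disjoint
exposure episodes (same-day duplicates, overlaps, short gaps). Every one of
those steps involves an assumption that is defensible in several ways, is
rarely reported, and can move downstream effect estimates.

This package makes the assumption space explicit. The preparation algorithm
is a fixed sequence of ten decision nodes in three steps:

* **Step A — field cleaning** (nodes 1–5): implausible `qty` (node 1),
  missing `qty` (2), implausible `ndd` (3), missing `ndd` (4), implausible
  `numdays`/`dose_duration` (5). Options per node: leave as-is, set
  missing, cap at the nearest plausibility bound, impute the product-level
  population mean, the patient's own mean, carry the patient's previous
  value forward, or substitute the product default (the exact option list
  varies by node; see `default_registry()`).
* **Step B — stop dates** (nodes 6–7): node 6 chooses the duration source
  (`6a` numdays, `6b` dose_duration, `6c` qty/ndd) or reconciles all
  available sources within a day tolerance x (`6d(x)`, x ∈ {15, 30, 60,
  90}); node 7 imputes still-missing stop dates (patient mean, population
  mean, product default, carry-forward) or keeps them missing. **Any record
  without a stop date after node 7 is dropped.**
* **Step C — episodes** (nodes 8–10): same-day duplicate handling (8),
  overlap resolution (9: stockpiling, truncation, union, duration-sum,
  drop-later), and gap bridging (10: never, gap < x days for x ∈ {7, 15,
  30, 60, 90}, or fully continuous).

The registry has 54 options in total (5+5+5+5+5+7+5+5+5+7) and
5⁸ × 7 × 7 = 19 140 625 complete pathways. A published option inventory of
this kind reports 54 options across 10 nodes but only "over 11 000"
pathways; the exact per-node option lists behind that count are not public,
so this registry is a reconstruction completed from every option named in
print, and its pathway count is treated as needing only to exceed the
printed lower bound. The node order 1→10 is fixed; order sensitivity is a
known open issue and deliberately out of scope.

## Conventions and numerical choices

* Dates are integer day offsets; intervals are half-open `[start, stop)`;
  a one-day prescription has `stop = start + 1`.
* Means of dates or durations are rounded half-up; a derived duration below
  one day is treated as missing (a zero-day script carries no exposure).
* Plausibility bounds are inclusive. Unknown product codes are treated as
  fully plausible (logged), and their defaults are unavailable.
* Donor statistics for imputation are frozen from the data as it enters
  each node, computed on plausible non-missing values per product (or per
  patient × product), so results are order-independent within a node and
  each node is idempotent. Fallback chain: patient mean → product
  population mean → product default; carry-forward with no prior
  prescription leaves the value missing.
* `6d(x)` reconciliation: one candidate → use it; two equal → that date;
  two unequal within x days (inclusive) → their mean; three not all equal →
  mean of the closest pair if within x; otherwise missing. When two pairs
  tie on distance, the pair involving the qty/ndd candidate wins (it is by
  far the best-populated source), then the pair involving numdays.
* "Gap < x days" at node 10 is strict.
* Overlap/gap resolution pools all product codes of a drug class and runs a
  single left-to-right sweep with a running exposure end.
* Gap bridging happens before clipping to follow-up.

## Audit ledger

Every node reports records in, modified, set missing, merged, dropped, and
records out, with the conservation law `out = in − dropped − merged`.
"Dropped" is reserved for discarded information: unresolvable stop dates at
node 7, later overlapping records under option 9e, and episodes outside
follow-up at the final clipping step. Merging (8c/8d, 9c/9d, 10b/10c)
combines records without discarding person-time accounting. Node 5 counts
are summed over the two duration fields it cleans.

## Synthetic cohorts

No real extract can be redistributed, so every test runs on generated data
(`drugprep.synthetic`). Key modelling choices:

* **Pack-level product codes.** As in CPRD GOLD, each strength/pack size is
  its own product code; one drug class spans 12 codes and consecutive
  scripts repeat the previous code with probability 0.5. Scripts per
  patient × product group are therefore few (≈2–3 in the intermittent
  regime). This granularity is what makes *patient-level, per-product*
  imputation donor-poor when a duration field is ~97% missing, and is the
  honest origin of the record-loss mechanism under options 6a/6b.
* **Regimes.** `continuous` mimics long-term repeat prescribing (28/56-day
  scripts, refill jitter ~Poisson(1 day), occasional treatment breaks ≥30
  days); `intermittent` mimics short-course therapy (1–3 scripts per
  course, inter-course gaps ≈30+Exp(90) days). Field-missingness defaults
  are 12.5% / 97.2% / 99.9% (ndd / numdays / dose_duration) for the
  continuous regime and 50% / 97% / 99.2% for the intermittent regime,
  matching published profiles of UK primary-care extracts. Out-of-bounds
  contamination is 2% per field (no published figure exists; chosen as a
  realistic low rate).
* **Truth as consumption.** Ground-truth exposure follows a
  supply-consumption (stockpiling) model: each script adds its duration to
  a stockpile consumed one day at a time. Records are written fully
  consistent with the truth (numdays = dose_duration = duration,
  qty = duration × ndd) and then corrupted (masking and contamination are
  independent per field and record — marginal rates are matched, missingness
  correlation is not modelled, a documented simplification).
* **Outcome.** Event times are piecewise exponential: baseline hazard
  2 × 10⁻⁴/day off drug (≈20% cumulative risk over a median two-year
  follow-up), multiplied by exp(log-HR) during true exposure; default true
  HR 2.0. This is the simplest data-generating process consistent with a
  proportional-hazards analysis.

What passing tests show — and do not. The generator reproduces the
structural features the algorithm exists to handle (three redundant
duration sources, realistic missingness, duplicates, overlaps, gaps,
contamination) with a known truth, so correctness of the machinery and the
direction of the 6a/6b mechanism are genuinely tested. It does not emulate
free-text dosing, practice-level clustering, competing risks, informative
missingness, or confounding; agreement on synthetic data does not certify
any particular pathway as unbiased on real data.

## Analysis

Person-time is split at episode boundaries into counting-process rows
`[start, stop)` alternating exposed/unexposed, censored at the event.
Exposure is treated as a left-continuous (predictable) covariate, so the
state at an event on day *d* is the state just before *d* — this also
guarantees no zero-length rows when an event coincides with an episode
boundary. The Cox model is fit by maximum partial likelihood (statsmodels
`PHReg`) with counting-process left truncation and Breslow tie handling
(day-granular data make ties certain); no covariates are included by
design, since the object of study is the preparation step, not
confounding. CIs are Wald on the log scale with 1.96. A fit is flagged
non-estimable rather than raised when there are no events, a contrast level
has zero person-time or zero events, the optimiser fails, or the estimate
diverges (|log HR| > 15 or SE > 50, the signature of a monotone
likelihood).

The two-stage sensitivity experiment mirrors standard practice: stage 1
draws 50 pathways uniformly at random (uniformity over the full product
space; no stratification); stage 2 runs a pre-specified primary pathway —
default `1b,2a,3b,4b,5b,6c,7b,8c,9a,10b(15)` — plus all 44 one-at-a-time
variants. Summaries report median HR/SE, IQR and 1.5×IQR outlier flags;
absolute outlier thresholds are configurable, never hard-coded, because
they are dataset-specific.

## Problem sizes

The shipped experiments use 2000-patient cohorts (≈19 000–40 000
prescriptions depending on regime), 50 random pathways plus 45 stage-2
pathways, and 20 replicates for coverage; these sizes give stable medians
and binomially tight coverage counts while keeping a full run in the
minutes range on one core.

## Known limitations

* The registry is a reconstruction (see above); per-node option lists may
  differ from any specific published inventory even though node count,
  option count and every named option match.
* Node order is fixed; conditional option applicability (options that only
  make sense given earlier choices) is not modelled, which is the likely
  reason reconstructed pathway counts exceed published ones.
* Dose quantification, researcher-specified duration source preference,
  drug-substance-level (rather than product-level) processing, covariate
  adjustment and competing risks are out of scope.
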