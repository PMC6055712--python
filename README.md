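# drugprep

Preparing raw prescription records for analysis — deriving stop dates,
cleaning implausible quantities and doses, collapsing duplicates, resolving
overlaps, bridging gaps — is an unreported step in most pharmacoepidemiology
studies, and the small choices it involves can move the final hazard ratio.
`drugprep` implements that preparation step as an explicit, auditable
algorithm: ten decision nodes with 54 assumption options, each complete set
of choices (a *pathway*) turning a CPRD-style therapy table into disjoint
time-varying exposure episodes, plus a sensitivity harness that quantifies
how pathway choice changes a Cox proportional-hazards estimate.

It is aimed at pharmacoepidemiologists and methods researchers working with
primary-care prescribing data (or any EHR source with the same structure:
product code, start date, quantity `qty`, daily dose `ndd`, sparse duration
fields `numdays` / `dose_duration`, no stop date).

## The algorithm

Step A cleans fields (nodes 1–5: implausible/missing `qty`, `ndd`, and the
duration fields, against per-product clinical plausibility bounds). Step B
derives each prescription's stop date (node 6: from `numdays`,
`dose_duration`, `qty/ndd`, or a reconciliation of all available sources
within *x* days; node 7: imputation of missing stop dates — anything still
unresolved is dropped). Step C builds episodes (node 8: same-day
duplicates; node 9: overlaps, e.g. stockpiling; node 10: bridging gaps
shorter than *x* days). Exposure is binary — currently on or off the drug
class — on half-open day intervals `[start, stop)`.

For a cohort with follow-up windows and event dates, person-time is split
into counting-process rows alternating on/off therapy and the contrast is
estimated as a hazard ratio from a Cox partial likelihood (Breslow ties,
Wald 95% CI). The sensitivity experiment runs (1) 50 uniformly random
pathways and (2) a pre-specified primary pathway plus all 44 one-at-a-time
variants, reporting the HR/SE distribution across pathways.

Because no real extract can be shipped, `drugprep.synthetic` generates
CPRD-like cohorts with known ground-truth exposure and a known true hazard
ratio (see `docs/methods.md` for the generative model and its limits).

## Worked example

```python
import drugprep as dp

cfg = dp.GeneratorConfig.intermittent(n_patients=2000, seed=11,
                                      miss_ndd=0.125, miss_numdays=0.972,
                                      miss_dose_duration=0.999)
therapy, followup, truth = dp.generate_cohort(cfg)   # 19 182 prescriptions
plaus = dp.make_plausibility(cfg)

primary = dp.PathwaySpec.parse(dp.DEFAULT_PRIMARY)   # 1b,2a,3b,4b,5b,6c,7b,8c,9a,10b(15)
for spec in (primary, primary.replace(6, "6a")):
    timeline, ledger = dp.run_pathway(therapy, spec, plaus, followup)
    fit = dp.fit_exposure_model(dp.build_person_time(timeline, followup))
    r = dp.PathwayResult(spec.serialize(), fit["log_hr"], fit["se"],
                         ledger.total_dropped, fit["estimable"])
    frac = ledger.total_dropped / ledger.entries[0].records_in
    print(f"{spec.token(6)}: dropped {frac:5.1%}  "
          f"HR {r.hr:.2f} (95% CI {r.ci_low:.2f}-{r.ci_high:.2f})  SE {r.se:.3f}")
```

prints

```
6c: dropped  0.4%  HR 1.90 (95% CI 1.53-2.36)  SE 0.111
6a: dropped 91.0%  HR 1.40 (95% CI 0.77-2.55)  SE 0.307
```

The cohort was simulated with a true HR of 2.0. The primary pathway (stop
date from `qty/ndd`, 87.5% populated) keeps virtually all records and
estimates HR 1.90 with SE 0.11. Switching only node 6 to option 6a (stop
date from `numdays`, 97.2% missing) drops 91% of records at node 7, and the
estimate degrades to HR 1.40 with a threefold larger SE — the single
preparation choice dominates everything else in the recipe. The per-node
`ledger` shows exactly where the records went.

A command-line interface wraps the same functions
(`drugprep simulate | prepare | enumerate | sample | sensitivity`).

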