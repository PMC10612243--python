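# tcellstrat

Gene-signature stratification of expression cohorts by CD8⁺/PD1⁺/CD28
status, with survival and immunotherapy-response association, plus Boolean
combinatorics for gated single-cell cytometry events.

## The problem

CD8⁺ T cells that co-express the inhibitory receptor PD1 split into two
functionally distinct populations depending on the co-stimulatory receptor
CD28: PD1⁺CD28⁻ cells behave like terminally differentiated effectors while
PD1⁺CD28⁺ cells resemble a "pre-exhausted" memory-like state that is the
preferential target of PD1-axis checkpoint blockade. Transcriptomic
signatures of these populations can stratify lung-adenocarcinoma patients
by prognosis and predict response to anti-PD-L1 therapy — but only within
the right cellular context, which bulk cohorts must approximate by
expression gating. This package implements that whole analysis chain as a
tested, reusable library for bioinformaticians:

1. **Signature derivation** — filter a per-cluster differential-expression
   marker table to genes with fold change > 1.5 and adjusted *P* < 0.001
   that belong to a gene universe (e.g. an adaptive-immunity pathway set).
   Three published CD8⁺PD1⁺ cluster signatures (11, 5 and 6 genes) ship as
   fixtures.
2. **Cohort stratification** — keep patients with overall survival
   > 1 month; gate the CD8⁺PD1⁺ cohort as both `CD8A` and `PDCD1`
   strictly above their 25th percentile; split it into CD28⁺/CD28⁻ at the
   within-cohort 25th percentile of `CD28`.
3. **Scoring and splitting** — score a signature per patient as the mean
   log2(expr + 1) (survival arm) or the mean per-gene Z-score (response
   arm); split High/Low at the median score after removing an exclusion
   band of 0%, 10% or 50% of patients nearest the median.
4. **Outcome association** — Kaplan–Meier curves with the two-group
   log-rank test (χ² with tie-corrected hypergeometric variance) for
   survival; CR/PR → responder, PD → non-responder, SD excluded, with a
   two-sided Fisher's exact test on the High/Low × R/NR table for
   response.
5. **Cytometry combinatorics** — PD1/CD28 quadrant gating, exhaustive
   2^k inhibitory-receptor co-expression profiles (16 patterns for
   TIGIT/CTLA4/TIM3/LAG3, 32 with PD1), polyfunctionality (≥ 2 effector
   molecules of GRZB/IFN-γ/TNF-α), PD1 intensity high/low partitions, and
   Wilcoxon/Friedman/Mann–Whitney/Kruskal–Wallis district comparisons with
   Bonferroni correction.
6. **Synthetic data** — seed-reproducible generators for all inputs:
   expression cohorts with a planted proportional-hazards effect
   (exponential survival, hazard `h₀·exp(β·(s − s̄))` in the signature
   score `s`) or a planted logistic response effect, marker tables with
   filter-failing decoys, and Bernoulli/multinomial Boolean event tables.

## Worked example

```python
import tcellstrat as ts

cfg = ts.SimulationConfig(seed=42, n_patients=500, log_hr_beta=-0.8, censor_rate=0.2)
cohort = ts.generate_survival_cohort(cfg)
signature = ts.bundled_signatures()["C0"]          # 11-gene KLRG1+EOMES+CD28+ signature

config = ts.PipelineConfig(score_method="log2", exclusion_fraction=0.10)
reports = ts.run_survival_pipeline(cohort, signature, config)
rep = reports["dp"]
print(rep.n_patients, rep.result.logrank_chi2, rep.result.p_value)
```

prints (as produced by `examples/survival_stratification.py`):

```
dp           n=277  High/Low = 126/125  chi2 =  19.10  log-rank p = 1.24e-05  median OS High =   53.0 mo, Low =   29.8 mo
dp_cd28neg   n= 70  High/Low = 32/32  chi2 =  16.86  log-rank p = 4.02e-05  median OS High =  111.0 mo, Low =   23.3 mo
dp_cd28pos   n=207  High/Low = 94/93  chi2 =   7.09  log-rank p = 7.74e-03  median OS High =   48.5 mo, Low =   30.5 mo
```

Of the 500 simulated patients, 277 pass the survival filter and the double
CD8A/PDCD1 gate ("dp"); with a 10% exclusion band they split 126/125 into
High/Low signature scores. The planted protective effect (log hazard ratio
−0.8 per unit score) surfaces as a longer High-group median survival and a
small log-rank *p* in every stratum.

The other `examples/` scripts cover responder analysis
(`response_association.py`), signature derivation from a marker table
(`derive_signature.py`) and inhibitory-receptor combination profiles with
polyfunctionality (`combination_profiles.py`).

A thin CLI mirrors the library:

```bash
tcell-strat simulate survival --out cohort/ --seed 3
tcell-strat survival --expr cohort/expr.tsv --clinical cohort/clinical.tsv \
    --signature c0.gmt --stratum dp --exclusion 0.1 --out report.json
tcell-strat combos --events events.tsv --markers TIGIT,CTLA4,TIM3,LAG3 \
    --subset PD1posCD28neg --out combos.tsv
```

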