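"""Stratify a simulated expression cohort and test the signature against survival.

Generates a 500-patient cohort in which a lower hazard is planted for
patients with a high C0 (KLRG1+EOMES+ CD28+) signature score, then runs the
full chain: OS > 1 month filter, CD8A/PDCD1 double 25th-percentile gate,
CD28 split, log2 signature scoring, median High/Low split with a 10%
exclusion band, and the Kaplan-Meier / log-rank comparison per stratum.
"""

import tcellstrat as ts

cfg = ts.SimulationConfig(seed=42, n_patients=500, log_hr_beta=-0.8, censor_rate=0.2)
cohort = ts.generate_survival_cohort(cfg)
signature = ts.bundled_signatures()["C0"]

config = ts.PipelineConfig(score_method="log2", exclusion_fraction=0.10)
reports = ts.run_survival_pipeline(cohort, signature, config)

for name, rep in reports.items():
    res = rep.result
    print(
        f"{name:12s} n={rep.n_patients:3d}  High/Low = "
        f"{rep.labeling.n_high}/{rep.labeling.n_low}  "
        f"chi2 = {res.logrank_chi2:6.2f}  log-rank p = {res.p_value:.2e}  "
        f"median OS High = {res.median_survival('High'):6.1f} mo, "
        f"Low = {res.median_survival('Low'):6.1f} mo"
    )

# A small p-value with a longer High-group median survival means the planted
# protective effect of the signature was recovered through the whole
# gate -> score -> split -> test chain.
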