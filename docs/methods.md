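# Methods

## Stratification procedure

The expression pipeline assumes a normalized genes × patients matrix with
non-negative finite values; no library-size or batch correction is applied.
The steps and their conventions:

* **Survival filter.** Patients with overall survival strictly greater
  than 1 month are retained (`min_months` configurable). "Greater than"
  is strict; a patient at exactly 1.0 month is dropped.
* **Double-positive gate.** The CD8⁺PD1⁺ surrogate cohort is
  `CD8A > q25(CD8A)` AND `PDCD1 > q25(PDCD1)`, with each 25th percentile
  computed across all retained patients by linear interpolation between
  order statistics (numpy's default quantile). "Above" is read as strict
  `>`, so ties at the cutoff fall outside the gate; with ties-free
  continuous expression the gate captures ≈ 0.75² = 56.25% of patients.
  Gene symbols default to `CD8A`/`PDCD1`/`CD28` but are configurable, as
  are the percentile and the quantile convention's consequences via the
  recorded thresholds.
* **CD28 split.** The CD28⁺/CD28⁻ cutoff is the 25th percentile of CD28
  computed *within* the double-positive cohort (the split happens
  "subsequently" to the gate); `within_dp=False` switches to whole-cohort
  cutoffs. `pos` is strictly above the cutoff, `neg` at or below.
* **Scoring.** `log2_mean`: mean of log2(expr + 1) over signature genes,
  pseudocount 1 by default (configurable — "log2-scaled" admits several
  conventions). `zscore_mean`: per-gene Z across the scored patient set
  using the sample (n−1) standard deviation, then the mean Z over
  signature genes; zero-variance genes contribute 0 with a warning.
  Z-scoring happens within the selected stratum, i.e. after cohort
  selection. Signature genes absent from the matrix are dropped with a
  warning naming them; scoring with no gene present is an error.
* **High/Low split.** Patients are sorted by score ascending with
  patient-id lexicographic tie-break (so all-tied scores still split
  deterministically). With exclusion fraction *f*, `m = floor(n·f/2)`
  patients are removed from each side of the median rank; of the remaining
  `n − 2m`, the lowest `floor((n−2m)/2)` are Low and the rest High. With
  *f* = 0 and even *n* this is the plain equal-halves median split; the
  patient at an exact odd-*n* median lands in High. The rank rule makes
  labelings nested across *f*: widening the band only removes patients
  from the groups, never moves one between them. Fewer than 4 patients
  after exclusion is an error.

All thresholds (gate cutoffs, score band edges) are recorded in the
outputs, and re-applying recorded thresholds reproduces the assignment
exactly.

## Outcome tests

Kaplan–Meier estimation and the two-group log-rank test are delegated to
`lifelines`; Fisher's exact test to `scipy.stats.fisher_exact`. The
package-level contracts on top of them:

* KM curves are right-continuous step functions starting at 1; with no
  censoring they equal the empirical survival function.
* The log-rank χ² uses the tie-corrected hypergeometric variance at each
  distinct event time, with 1 df for two groups; events are processed
  before censorings tied at the same time (the standard convention). A
  risk-set configuration with zero total variance (every event time sees a
  single-group or single-patient risk set) raises an undefined-statistic
  error rather than reporting χ² = 0.
* Fisher's test is two-sided by the "sum of hypergeometric probabilities
  ≤ that of the observed table" rule; the odds ratio is the sample
  (a·d)/(b·c) with infinity when b·c = 0, distinct from scipy's
  conditional MLE. Degenerate margins (an empty row or column after
  exclusions) return p = 1 with a flag instead of erroring, so seed sweeps
  never abort.
* Response mapping is strict: CR/PR → R, PD → NR, SD and missing →
  excluded (counted and reported); any other label, including case
  variants, is an error.
* P-values are reported raw; each stratum is a single test, so no
  multiplicity correction is applied by the pipelines. The cytometry
  `compare_groups` dispatcher, by contrast, takes an explicit
  `family_size` from the caller — the analysis, not the test, defines the
  comparison family — and reports `p_adjusted = min(1, p·family_size)`
  (Bonferroni).

## Cytometry conventions

Event tables are consumed as already-gated Booleans with subject and
district (PBMC / NT / T) annotations. The 2^k combination lattice is
capped at k = 5 (guarding against silent combinatorial blowup) and always
emits all patterns, zero-frequency included, with frequencies summing to 1
per stratum. The canonical order — ascending count of positives, ties
broken lexicographically in marker order with positive before negative —
is a package choice; published figure labels (IR-1…IR-16 style) come from
dot-matrix legends that are not machine-readable, so an explicit
`index_labels` map lets the user attach any figure's numbering rather than
the package guessing it. Empty strata propagate as missing, not 0%, so
district comparisons are not biased by absent subsets. The PD1
intensity high/low threshold is user-supplied per dataset; gates are set
by inspection upstream and no automatic inference is attempted.

## Synthetic-data model

The generators emulate the study conditions the pipeline is meant to
operate under, not any particular dataset's artifacts:

* **Expression** is i.i.d. log-normal per gene and patient with log-scale
  location `expr_mu = 2.0` and spread `expr_sigma = 1.0` — a heavy-tailed,
  strictly positive distribution of normalized-expression magnitude. No
  gene–gene correlation, library-size variation or batch structure is
  simulated, so passing recovery tests demonstrate the pipeline's
  statistical behavior under clean planted effects, not robustness to real
  RNA-Seq artifacts.
* **Survival** is exponential (constant baseline hazard, the simplest
  proportional-hazards form; a shape parameter is left as an extension
  point): hazard `baseline_hazard · exp(log_hr_beta · (s − s̄))` where `s`
  is the patient's mean log2(expr+1) over the signature genes. Defaults:
  `baseline_hazard = 0.02`/month (median survival ≈ 35 months at the mean
  score, a plausible resected-adenocarcinoma scale), `log_hr_beta = −0.8`
  (the planted protective effect used in the recovery analyses),
  `censor_rate = 0.2`. Censoring is administrative-uniform on [0, T_max]
  with T_max solved numerically (Brent) so the *expected* censored
  fraction equals `censor_rate`; the realized fraction is binomial around
  it — the mechanism is approximate by design.
* **Response** draws SD with probability `sd_fraction = 0.15`; otherwise
  responder (PR/CR, split 50/50) vs PD from a logistic model on the
  centered Z-score-based signature score with slope `logistic_beta` and
  intercept `logit(baseline_response_rate = 0.3)`.
* **Marker tables** keep planted rows verbatim and add decoys guaranteed
  to fail fold change > 1.5 and/or adjusted P < 0.001, shuffled by seed.
* **Event tables** draw markers as independent Bernoulli at per-district
  marginal probabilities, or whole patterns multinomially from explicit
  `combo_weights` indexed in the canonical combination order (which makes
  the generator/analyzer round-trip exact in expectation). PD1⁺ cells draw
  a log-normal intensity at a higher location (log-mean 2.0) than PD1⁻
  cells (0.5), so intensity partitions are exercisable.

Determinism: each generator derives its own RNG stream from the global
seed via a fixed spawn key, so outputs are pure functions of (seed,
config) and adding a generator never perturbs existing ones. Default
panels always contain the literal `CD8A`, `PDCD1`, `CD28` symbols so the
gating defaults run unmodified.

## Calibration problem sizes

The null calibration of the score → split → log-rank chain uses 1,000
seeds at 150 patients each (the type-I error is a per-test property and
converges quickly in n); planted-effect detection uses the 500-patient /
100-seed / 20%-censoring condition of the recovery analysis; round-trip
checks of combination weights use 10,000 cells, where 3 binomial standard
errors is a tight band. `scripts/acceptance.py` recomputes all of these at
run time from the seed it is given.

## Known limitations

* Gene-symbol matching is exact and case-sensitive; no alias resolution.
* Fold changes are consumed as linear; `log2fc=True` converts `2^x` before
  filtering, but mixed-convention tables cannot be detected automatically.
* The C2 bundled signature carries the 5 genes printed for it even though
  the surrounding text cites 7; the discrepancy is documented, not
  resolved.
* No Cox regression or multivariable adjustment; the KM plot is for
  inspection only. No FCS parsing, compensation or automated gating; no
  TCGA/OAK download layer — cohorts arrive as TSV.
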