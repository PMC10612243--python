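"""Outcome association: Kaplan-Meier / log-rank and Fisher responder tests.

High/Low signature groups are compared on overall survival (Kaplan-Meier
product-limit curves, two-group log-rank test) or on immunotherapy response
(CR/PR mapped to responder, PD to non-responder, SD excluded; two-sided
Fisher's exact test on the 2x2 High/Low x R/NR table).

Estimation goes through ``lifelines`` (KaplanMeierFitter,
``statistics.logrank_test``) and ``scipy.stats.fisher_exact``; this module
adds the stratification-aware orchestration, the response-label mapping and
the machine-readable reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .cohort import ExpressionCohort
from .errors import ConfigurationError, DegenerateStatisticError
from .signatures import GeneSignature
from .stratify import (
    CohortStrata,
    GroupLabeling,
    ScoreVector,
    filter_min_survival,
    gate_double_positive,
    score_signature_log2,
    score_signature_zscore,
    split_by_gene,
    split_high_low,
)

logger = logging.getLogger(__name__)

STRATA = ("dp", "dp_cd28neg", "dp_cd28pos")


# ----------------------------------------------------------------------
# Kaplan-Meier


@dataclass
class KMCurve:
    """A product-limit survival curve as a right-continuous step function.

    ``times`` are the distinct observed times (events and censorings),
    ``survival`` the estimate just after each time, ``at_risk`` the number
    at risk just before it and ``events`` the events at it.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    n: int

    def survival_at(self, t: float) -> float:
        """S(t) of the step function (1 before the first observed time)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    @property
    def event_times(self) -> np.ndarray:
        return self.times[self.events > 0]


def _check_surv_arrays(times, events) -> tuple[np.ndarray, np.ndarray]:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if times.shape != events.shape or times.ndim != 1:
        raise ValueError("times and events must be equal-length 1-D arrays")
    if len(times) == 0:
        raise ValueError("empty survival data")
    if not np.all(np.isfinite(times)) or (times <= 0).any():
        raise ValueError("survival times must be finite and positive")
    uniq = set(np.unique(events).tolist())
    if not uniq <= {0, 1, 0.0, 1.0, False, True}:
        raise ValueError(f"event indicators must be 0/1, got {sorted(uniq)}")
    return times, events.astype(int)


def km_estimate(times: Sequence[float], events: Sequence[int]) -> KMCurve:
    """Kaplan-Meier product-limit estimate of the survival function."""
    times, events = _check_surv_arrays(times, events)
    kmf = KaplanMeierFitter().fit(times, events)
    table = kmf.event_table.drop(index=0.0, errors="ignore")
    obs_times = table.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(obs_times).to_numpy(dtype=float)
    return KMCurve(
        times=obs_times,
        survival=surv,
        at_risk=table["at_risk"].to_numpy(dtype=int),
        events=table["observed"].to_numpy(dtype=int),
        n=len(times),
    )


# ----------------------------------------------------------------------
# Log-rank


@dataclass
class SurvivalTestResult:
    """Two-group log-rank outcome plus the per-group KM curves."""

    curves: dict[str, KMCurve]
    logrank_chi2: float
    df: int
    p_value: float
    group_sizes: dict[str, int]

    def median_survival(self, group: str) -> float:
        """Median survival time of one group's KM curve (inf if S stays > 0.5)."""
        curve = self.curves[group]
        below = curve.times[curve.survival <= 0.5]
        return float(below[0]) if len(below) else float("inf")


def logrank_test(
    times: Sequence[float],
    events: Sequence[int],
    groups: Sequence[str],
) -> SurvivalTestResult:
    """Two-group log-rank test with tie-corrected hypergeometric variance.

    ``groups`` assigns each observation to one of exactly two labels
    (canonically "High"/"Low").  The chi-square statistic uses the standard
    per-event-time hypergeometric expectation and variance; p is the upper
    tail of chi-square with 1 df.
    """
    times, events = _check_surv_arrays(times, events)
    groups = np.asarray(groups, dtype=object)
    if groups.shape != times.shape:
        raise ValueError("groups must match times in length")
    labels = sorted(set(groups.tolist()))
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 non-empty groups, got {labels}")
    if events.sum() == 0:
        raise DegenerateStatisticError("no events in either group")
    masks = {lab: groups == lab for lab in labels}
    # zero total variance: no event time has a mixed, >1-patient risk set
    informative = False
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n_t = int(at_risk.sum())
        n1_t = int((at_risk & masks[labels[0]]).sum())
        if n_t > 1 and 0 < n1_t < n_t:
            informative = True
            break
    if not informative:
        raise DegenerateStatisticError("log-rank statistic undefined (zero variance)")
    res = _ll_logrank(
        times[masks[labels[0]]],
        times[masks[labels[1]]],
        event_observed_A=events[masks[labels[0]]],
        event_observed_B=events[masks[labels[1]]],
    )
    chi2 = float(res.test_statistic)
    if not np.isfinite(chi2):
        raise DegenerateStatisticError("log-rank statistic undefined (zero variance)")
    curves = {
        lab: km_estimate(times[masks[lab]], events[masks[lab]]) for lab in labels
    }
    return SurvivalTestResult(
        curves=curves,
        logrank_chi2=chi2,
        df=1,
        p_value=float(stats.chi2.sf(chi2, df=1)),
        group_sizes={lab: int(masks[lab].sum()) for lab in labels},
    )


# ----------------------------------------------------------------------
# Response mapping and Fisher's exact test

_RESPONSE_MAP = {"CR": "R", "PR": "R", "PD": "NR", "SD": "excluded"}


def classify_response(label: object) -> str:
    """Map a RECIST-style label to R / NR / excluded.

    CR and PR are responders, PD non-responders; SD and missing labels are
    excluded.  Unknown strings raise (no silent coercion).
    """
    if label is None or (isinstance(label, float) and np.isnan(label)):
        return "excluded"
    if label in _RESPONSE_MAP:
        return _RESPONSE_MAP[label]  # type: ignore[index]
    raise ValueError(f"unknown response label {label!r}")


@dataclass
class ResponseTable:
    """2x2 responder table (rows High/Low, columns R/NR) with Fisher's test."""

    counts: np.ndarray  # shape (2, 2): [[High-R, High-NR], [Low-R, Low-NR]]
    odds_ratio: float
    p_value: float
    excluded_labels: int
    degenerate: bool = False

    @property
    def n_included(self) -> int:
        return int(self.counts.sum())


def fisher_exact_2x2(counts: np.ndarray) -> tuple[float, float, bool]:
    """Two-sided Fisher's exact p and the sample odds ratio for a 2x2 table.

    Two-sidedness follows the "sum of hypergeometric probabilities at most
    that of the observed table" rule.  Degenerate margins (an empty row or
    column) return p = 1 with a flag.  The odds ratio is (a*d)/(b*c), with
    infinity when b*c = 0 and a*d > 0 and nan for 0/0.
    """
    counts = np.asarray(counts, dtype=int)
    if counts.shape != (2, 2) or (counts < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    a, b = counts[0]
    c, d = counts[1]
    degenerate = any(m == 0 for m in (a + b, c + d, a + c, b + d))
    if degenerate:
        p = 1.0
    else:
        p = float(stats.fisher_exact(counts, alternative="two-sided")[1])
    ad, bc = a * d, b * c
    if bc == 0:
        odds = float("nan") if ad == 0 else float("inf")
    else:
        odds = ad / bc
    return odds, p, degenerate


def fisher_response(
    labeling: GroupLabeling, responses: pd.Series
) -> ResponseTable:
    """Fisher's exact test of High/Low membership against responder status.

    ``responses`` holds RECIST labels indexed by patient.  Patients labelled
    Excluded by the median split are not counted; among High/Low patients,
    SD and missing labels are excluded (and counted in ``excluded_labels``).
    """
    counts = np.zeros((2, 2), dtype=int)
    excluded = 0
    for row, group in enumerate(("High", "Low")):
        for pid in labeling.group(group):
            cls = classify_response(responses.get(pid))
            if cls == "excluded":
                excluded += 1
            else:
                counts[row, 0 if cls == "R" else 1] += 1
    odds, p, degenerate = fisher_exact_2x2(counts)
    if degenerate:
        logger.warning("degenerate responder table %s; p set to 1", counts.tolist())
    return ResponseTable(
        counts=counts,
        odds_ratio=odds,
        p_value=p,
        excluded_labels=excluded,
        degenerate=degenerate,
    )


# ----------------------------------------------------------------------
# End-to-end pipelines


@dataclass
class PipelineConfig:
    """Settings for the stratify-score-split-test pipelines."""

    score_method: str = "log2"  # {"log2", "zscore"}
    exclusion_fraction: float = 0.0
    strata: tuple[str, ...] = STRATA
    gene_a: str = "CD8A"
    gene_b: str = "PDCD1"
    split_gene: str = "CD28"
    percentile: float = 25.0
    min_months: float = 1.0
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.score_method not in ("log2", "zscore"):
            raise ConfigurationError(
                f"score_method must be 'log2' or 'zscore', got {self.score_method!r}"
            )
        unknown = [s for s in self.strata if s not in STRATA]
        if unknown:
            raise ConfigurationError(f"unknown strata: {unknown}")


@dataclass
class StratumReport:
    """Everything needed to reproduce one stratum's analysis."""

    stratum: str
    n_patients: int
    thresholds: dict[str, float]
    labeling: GroupLabeling
    scores: ScoreVector
    result: object  # SurvivalTestResult or ResponseTable


def _score(cohort: ExpressionCohort, signature: GeneSignature, config: PipelineConfig) -> ScoreVector:
    if config.score_method == "log2":
        return score_signature_log2(cohort, signature, pseudocount=config.pseudocount)
    return score_signature_zscore(cohort, signature)


def score_split_logrank(
    cohort: ExpressionCohort,
    signature: GeneSignature,
    score_method: str = "log2",
    exclusion_fraction: float = 0.0,
    pseudocount: float = 1.0,
) -> SurvivalTestResult:
    """The core score -> High/Low split -> log-rank chain on one cohort."""
    config = PipelineConfig(score_method=score_method, pseudocount=pseudocount)
    scores = _score(cohort, signature, config)
    labeling = split_high_low(scores, exclusion_fraction)
    keep = labeling.labels != "Excluded"
    pids = labeling.labels.index[keep]
    clin = cohort.clinical.loc[pids]
    return logrank_test(
        clin["os_months"].to_numpy(dtype=float),
        clin["os_event"].to_numpy(dtype=int),
        labeling.labels[pids].to_numpy(dtype=object),
    )


def _stratify(
    cohort: ExpressionCohort, config: PipelineConfig
) -> tuple[ExpressionCohort, CohortStrata]:
    strata = gate_double_positive(
        cohort, gene_a=config.gene_a, gene_b=config.gene_b, percentile=config.percentile
    )
    strata = split_by_gene(
        cohort, strata, gene=config.split_gene, percentile=config.percentile
    )
    return cohort, strata


def run_survival_pipeline(
    cohort: ExpressionCohort,
    signature: GeneSignature,
    config: PipelineConfig | None = None,
) -> dict[str, StratumReport]:
    """Survival filter -> DP gate -> CD28 split -> score -> split -> log-rank.

    Returns one :class:`StratumReport` per requested stratum, each carrying
    the gate thresholds and group sizes so the analysis can be re-run from
    the report alone.
    """
    config = config or PipelineConfig()
    filtered = filter_min_survival(cohort, min_months=config.min_months)
    filtered, strata = _stratify(filtered, config)
    reports: dict[str, StratumReport] = {}
    for name in config.strata:
        pids = strata.patients_in(name)
        sub = filtered.subset(pids)
        scores = _score(sub, signature, config)
        labeling = split_high_low(scores, config.exclusion_fraction)
        keep = labeling.labels.index[labeling.labels != "Excluded"]
        clin = sub.clinical.loc[keep]
        try:
            result = logrank_test(
                clin["os_months"].to_numpy(dtype=float),
                clin["os_event"].to_numpy(dtype=int),
                labeling.labels[keep].to_numpy(dtype=object),
            )
        except (ValueError, DegenerateStatisticError) as exc:
            raise type(exc)(f"stratum {name!r}: {exc}") from exc
        reports[name] = StratumReport(
            stratum=name,
            n_patients=len(pids),
            thresholds=dict(strata.thresholds),
            labeling=labeling,
            scores=scores,
            result=result,
        )
    return reports


def run_response_pipeline(
    cohort: ExpressionCohort,
    signature: GeneSignature,
    config: PipelineConfig | None = None,
) -> dict[str, StratumReport]:
    """DP gate -> CD28 split -> score -> split -> Fisher responder test.

    The survival filter is applied only when the cohort carries survival
    annotations (trial cohorts with response labels may lack them).
    """
    config = config or PipelineConfig(score_method="zscore")
    if cohort.has_survival() and cohort.survival_complete().all():
        cohort = filter_min_survival(cohort, min_months=config.min_months)
    cohort, strata = _stratify(cohort, config)
    if "response" not in cohort.clinical:
        raise ConfigurationError("cohort has no response column")
    reports: dict[str, StratumReport] = {}
    for name in config.strata:
        pids = strata.patients_in(name)
        sub = cohort.subset(pids)
        scores = _score(sub, signature, config)
        labeling = split_high_low(scores, config.exclusion_fraction)
        table = fisher_response(labeling, sub.clinical["response"])
        reports[name] = StratumReport(
            stratum=name,
            n_patients=len(pids),
            thresholds=dict(strata.thresholds),
            labeling=labeling,
            scores=scores,
            result=table,
        )
    return reports


# ----------------------------------------------------------------------


def plot_km(result: SurvivalTestResult, ax=None, title: str | None = None):
    """Quick inspection plot of the two KM step curves (not publication-grade)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for label, curve in result.curves.items():
        x = np.concatenate([[0.0], curve.times])
        y = np.concatenate([[1.0], curve.survival])
        ax.step(x, y, where="post", label=f"{label} (n={curve.n})")
    ax.set_xlabel("months")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.05)
    ax.legend()
    if title:
        ax.set_title(title)
    ax.text(
        0.02, 0.02,
        f"log-rank p = {result.p_value:.3g}",
        transform=ax.transAxes,
    )
    return ax
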