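"""Patient stratification: survival filter, percentile gating, scoring, split.

The procedure mirrors how bulk expression cohorts are stratified to enrich
for tumors with a CD8+PD1+ T-cell infiltrate:

1. keep patients with overall survival strictly greater than 1 month;
2. gate the CD8+PD1+ "double-positive" (DP) cohort: both CD8A and PDCD1
   expression strictly above their 25th percentile across retained patients;
3. split the DP cohort into CD28+ / CD28- at the 25th percentile of CD28
   computed *within* the DP cohort;
4. score a gene signature per patient (mean log2(expr+1), or mean of
   per-gene Z-scores);
5. split scored patients into High / Low at the median, optionally removing
   an exclusion band of patients nearest the median (0%, 10% or 50%).

Quantile convention is linear interpolation between order statistics;
"above" is read as strict ">", so ties at a cutoff fall outside the gated
group.  Both choices are configurable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import ExpressionCohort
from .errors import ConfigurationError, MissingGeneError
from .signatures import GeneSignature

logger = logging.getLogger(__name__)

CD28_GROUPS = ("pos", "neg", "none")


@dataclass
class CohortStrata:
    """Per-patient gate flags plus the cutoffs that produced them.

    ``thresholds`` maps gene symbol -> cutoff so that re-applying the
    recorded cutoffs reproduces the assignment exactly (round-trip
    contract, see :meth:`reapply`).
    """

    in_dp_cohort: pd.Series  # bool per patient
    cd28_group: pd.Series  # {"pos", "neg", "none"} per patient
    thresholds: dict[str, float]
    gate_genes: tuple[str, str]  # (CD8-like, PD1-like)
    split_gene: str | None = None

    def __post_init__(self) -> None:
        if not self.in_dp_cohort.index.equals(self.cd28_group.index):
            raise ValueError("strata series must share a patient index")
        bad = self.cd28_group[~self.cd28_group.isin(CD28_GROUPS)]
        if len(bad):
            raise ValueError(f"invalid cd28_group labels: {bad.unique().tolist()}")
        outside = (~self.in_dp_cohort) & (self.cd28_group != "none")
        if outside.any():
            raise ValueError("cd28_group assigned outside the DP cohort")

    @property
    def dp_patients(self) -> pd.Index:
        return self.in_dp_cohort.index[self.in_dp_cohort]

    def patients_in(self, stratum: str) -> pd.Index:
        """Patients of a named stratum: dp, dp_cd28neg or dp_cd28pos."""
        if stratum == "dp":
            return self.dp_patients
        if stratum == "dp_cd28neg":
            return self.cd28_group.index[self.cd28_group == "neg"]
        if stratum == "dp_cd28pos":
            return self.cd28_group.index[self.cd28_group == "pos"]
        raise ValueError(f"unknown stratum {stratum!r}")

    def reapply(self, cohort: ExpressionCohort) -> "CohortStrata":
        """Recompute the gate flags from the recorded thresholds."""
        gene_a, gene_b = self.gate_genes
        expr = cohort.expression
        for gene in (gene_a, gene_b):
            if gene not in expr.index:
                raise MissingGeneError(gene)
        in_dp = (expr.loc[gene_a] > self.thresholds[gene_a]) & (
            expr.loc[gene_b] > self.thresholds[gene_b]
        )
        cd28 = pd.Series("none", index=expr.columns, dtype=object)
        if self.split_gene is not None:
            if self.split_gene not in expr.index:
                raise MissingGeneError(self.split_gene)
            cut = self.thresholds[self.split_gene]
            vals = expr.loc[self.split_gene]
            cd28[in_dp] = np.where(vals[in_dp] > cut, "pos", "neg")
        return CohortStrata(
            in_dp_cohort=in_dp,
            cd28_group=cd28,
            thresholds=dict(self.thresholds),
            gate_genes=self.gate_genes,
            split_gene=self.split_gene,
        )


@dataclass
class ScoreVector:
    """Per-patient signature scores and how they were computed."""

    scores: pd.Series
    method: str  # {"log2_mean", "zscore_mean"}
    signature_name: str

    def __post_init__(self) -> None:
        if self.method not in ("log2_mean", "zscore_mean"):
            raise ValueError(f"unknown scoring method {self.method!r}")
        if not np.all(np.isfinite(self.scores.to_numpy(dtype=float))):
            raise ValueError("scores must be finite")


@dataclass
class GroupLabeling:
    """High/Low/Excluded assignment from the exclusion-band median split."""

    labels: pd.Series  # {"High", "Low", "Excluded"} per patient
    exclusion_fraction: float
    lower_threshold: float  # max score among Low
    upper_threshold: float  # min score among High

    def group(self, label: str) -> pd.Index:
        return self.labels.index[self.labels == label]

    @property
    def n_high(self) -> int:
        return int((self.labels == "High").sum())

    @property
    def n_low(self) -> int:
        return int((self.labels == "Low").sum())

    @property
    def n_excluded(self) -> int:
        return int((self.labels == "Excluded").sum())


# ----------------------------------------------------------------------


def filter_min_survival(
    cohort: ExpressionCohort, min_months: float = 1.0
) -> ExpressionCohort:
    """Keep patients with overall survival strictly above ``min_months``."""
    if not cohort.has_survival():
        raise ConfigurationError("cohort has no os_months/os_event columns")
    incomplete = ~cohort.survival_complete()
    if incomplete.any():
        raise ConfigurationError(
            "patients missing survival fields: "
            f"{cohort.patient_ids[incomplete].tolist()[:10]}"
        )
    keep = cohort.clinical["os_months"].astype(float) > min_months
    if not keep.any():
        logger.warning("survival filter at %s months removed every patient", min_months)
    return cohort.subset(cohort.patient_ids[keep])


def _quantile(values: np.ndarray, percentile: float) -> float:
    # linear interpolation between order statistics (the common default)
    return float(np.quantile(values, percentile / 100.0, method="linear"))


def gate_double_positive(
    cohort: ExpressionCohort,
    gene_a: str = "CD8A",
    gene_b: str = "PDCD1",
    percentile: float = 25.0,
) -> CohortStrata:
    """Gate the cohort on two genes both strictly above a percentile cutoff.

    Cutoffs are the linear-interpolation percentile of each gene across all
    patients of ``cohort``; a patient is in the double-positive cohort iff
    both expressions are strictly above their cutoffs.
    """
    expr = cohort.expression
    for gene in (gene_a, gene_b):
        if gene not in expr.index:
            raise MissingGeneError(gene)
    cut_a = _quantile(expr.loc[gene_a].to_numpy(dtype=float), percentile)
    cut_b = _quantile(expr.loc[gene_b].to_numpy(dtype=float), percentile)
    in_dp = (expr.loc[gene_a] > cut_a) & (expr.loc[gene_b] > cut_b)
    return CohortStrata(
        in_dp_cohort=in_dp,
        cd28_group=pd.Series("none", index=expr.columns, dtype=object),
        thresholds={gene_a: cut_a, gene_b: cut_b},
        gate_genes=(gene_a, gene_b),
    )


def split_by_gene(
    cohort: ExpressionCohort,
    strata: CohortStrata,
    gene: str = "CD28",
    percentile: float = 25.0,
    within_dp: bool = True,
) -> CohortStrata:
    """Split the gated cohort into positive/negative on one gene's cutoff.

    The cutoff is computed within the double-positive cohort (``within_dp``,
    the default, matching a stratify-"subsequently" reading) or across the
    whole cohort.  ``pos`` means strictly above the cutoff; ``neg`` means at
    or below; patients outside the DP cohort stay ``none``.
    """
    expr = cohort.expression
    if gene not in expr.index:
        raise MissingGeneError(gene)
    if not strata.in_dp_cohort.index.equals(expr.columns):
        raise ValueError("strata do not match cohort patients")
    dp = strata.dp_patients
    if len(dp) == 0:
        raise ConfigurationError("double-positive cohort is empty; cannot split")
    basis = expr.loc[gene, dp] if within_dp else expr.loc[gene]
    cut = _quantile(basis.to_numpy(dtype=float), percentile)
    cd28 = pd.Series("none", index=expr.columns, dtype=object)
    cd28[dp] = np.where(expr.loc[gene, dp] > cut, "pos", "neg")
    thresholds = dict(strata.thresholds)
    thresholds[gene] = cut
    return CohortStrata(
        in_dp_cohort=strata.in_dp_cohort.copy(),
        cd28_group=cd28,
        thresholds=thresholds,
        gate_genes=strata.gate_genes,
        split_gene=gene,
    )


# ----------------------------------------------------------------------
# Signature scoring


def _present_genes(cohort: ExpressionCohort, signature: GeneSignature) -> list[str]:
    present = [g for g in signature.genes if g in cohort.expression.index]
    absent = [g for g in signature.genes if g not in cohort.expression.index]
    if absent:
        logger.warning(
            "signature %s: %d gene(s) absent from matrix and dropped: %s",
            signature.name, len(absent), absent,
        )
    if not present:
        raise MissingGeneError(
            f"none of the {len(signature)} genes of {signature.name!r}"
        )
    return present


def score_signature_log2(
    cohort: ExpressionCohort, signature: GeneSignature, pseudocount: float = 1.0
) -> ScoreVector:
    """Mean log2(expr + pseudocount) over the signature genes, per patient."""
    present = _present_genes(cohort, signature)
    sub = cohort.expression.loc[present].to_numpy(dtype=float)
    scores = np.log2(sub + pseudocount).mean(axis=0)
    return ScoreVector(
        scores=pd.Series(scores, index=cohort.patient_ids),
        method="log2_mean",
        signature_name=signature.name,
    )


def score_signature_zscore(
    cohort: ExpressionCohort, signature: GeneSignature
) -> ScoreVector:
    """Mean per-gene Z-score (sample SD, n-1) over signature genes.

    Z-scores are computed across the scored patient set; a zero-variance
    gene contributes 0 to every patient's score (with a warning).
    """
    if cohort.n_patients < 2:
        raise ConfigurationError("Z-scoring needs at least 2 patients")
    present = _present_genes(cohort, signature)
    sub = cohort.expression.loc[present].to_numpy(dtype=float)
    mu = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, ddof=1, keepdims=True)
    flat = sd[:, 0] == 0
    if flat.any():
        logger.warning(
            "signature %s: zero-variance gene(s) contribute 0: %s",
            signature.name, [g for g, f in zip(present, flat) if f],
        )
    sd = np.where(sd == 0, 1.0, sd)
    z = (sub - mu) / sd
    scores = z.mean(axis=0)
    return ScoreVector(
        scores=pd.Series(scores, index=cohort.patient_ids),
        method="zscore_mean",
        signature_name=signature.name,
    )


# ----------------------------------------------------------------------
# Exclusion-band median split


def split_high_low(scores: ScoreVector, exclusion_fraction: float = 0.0) -> GroupLabeling:
    """Median split with a rank-symmetric exclusion band around the median.

    Patients are sorted by score ascending (ties broken by patient id);
    ``m = floor(n * exclusion_fraction / 2)`` patients are removed from each
    side of the median rank.  Of the remaining ``n - 2m``, the lowest
    ``floor((n - 2m) / 2)`` are Low and the rest High, so with no exclusion
    and even ``n`` the groups are equal halves split at the median.
    """
    if not 0 <= exclusion_fraction < 1:
        raise ConfigurationError(
            f"exclusion_fraction must be in [0, 1), got {exclusion_fraction}"
        )
    s = scores.scores
    n = len(s)
    m = math.floor(n * exclusion_fraction / 2.0)
    n_kept = n - 2 * m
    if n_kept < 4:
        raise ConfigurationError(
            f"only {n_kept} patients left after excluding {2 * m}; need >= 4"
        )
    order = sorted(s.index, key=lambda pid: (s[pid], str(pid)))
    n_low = (n - 2 * m) // 2
    labels = pd.Series(index=s.index, dtype=object)
    labels[order[:n_low]] = "Low"
    labels[order[n_low : n_low + 2 * m]] = "Excluded"
    labels[order[n_low + 2 * m :]] = "High"
    low_scores = s[labels == "Low"]
    high_scores = s[labels == "High"]
    return GroupLabeling(
        labels=labels,
        exclusion_fraction=exclusion_fraction,
        lower_threshold=float(low_scores.max()),
        upper_threshold=float(high_scores.min()),
    )
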