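"""Seed-reproducible synthetic cohorts and single-cell event tables.

Every downstream stage of the package is testable without external
downloads: this module generates

* expression cohorts with survival outcomes under a proportional-hazards
  (constant-baseline, exponential) model whose log hazard ratio per unit of
  signature score is planted by configuration;
* expression cohorts with RECIST-style response labels drawn from a
  logistic model on the signature score;
* differential-expression marker tables with planted signature genes and
  decoy rows that fail the fold-change / adjusted-P filter;
* cell-level Boolean event tables with independent-Bernoulli or explicit
  multinomial marker co-expression structure.

Every generator is a pure function of (seed, config).  Component RNG
streams are derived from the global seed by fixed spawn keys, so adding a
generator never perturbs existing outputs.  Gene panels always include the
literal CD8A, PDCD1 and CD28 symbols so stratification defaults work
unmodified.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .cohort import ExpressionCohort
from .cytometry import combo_patterns
from .errors import ConfigurationError

GATING_GENES = ("CD8A", "PDCD1", "CD28")

# fixed per-generator stream offsets (spawn keys off the global seed)
_STREAM = {"survival": 0, "response": 1, "markers": 2, "events": 3}


def _rng(seed: int, component: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAM[component],))
    )


def default_gene_panel(n_decoy: int = 20) -> tuple[str, ...]:
    """The default simulation panel: published C0 signature genes, the three
    gating genes and ``n_decoy`` unrelated filler genes."""
    from .signatures import bundled_signatures

    sig = bundled_signatures()["C0"].genes
    decoys = tuple(f"FILLER{i:03d}" for i in range(n_decoy))
    panel = list(dict.fromkeys((*sig, *GATING_GENES, *decoys)))
    return tuple(panel)


@dataclass
class SimulationConfig:
    """Parameters of the planted-effect expression-cohort generators.

    The planted effects act on the per-patient latent signature score
    (mean log2(expr+1) over ``signature_genes`` for survival; mean per-gene
    Z-score for response).  ``log_hr_beta`` is the log hazard ratio per unit
    score, ``logistic_beta`` the log odds of response per unit score, both
    applied to the centered score so intercepts stay interpretable.
    """

    seed: int = 0
    n_patients: int = 200
    gene_panel: tuple[str, ...] = field(default_factory=default_gene_panel)
    signature_genes: tuple[str, ...] | None = None  # default: C0 signature
    log_hr_beta: float = -0.8
    logistic_beta: float = 1.0
    baseline_hazard: float = 0.02  # events per month
    censor_rate: float = 0.2
    sd_fraction: float = 0.15
    baseline_response_rate: float = 0.3  # logistic intercept probability
    expr_mu: float = 2.0
    expr_sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.signature_genes is None:
            from .signatures import bundled_signatures

            sig = bundled_signatures()["C0"].genes
            self.signature_genes = tuple(g for g in sig if g in self.gene_panel)
        self.gene_panel = tuple(self.gene_panel)
        self.signature_genes = tuple(self.signature_genes)
        if len(set(self.gene_panel)) != len(self.gene_panel):
            raise ConfigurationError("gene_panel: duplicate symbols")
        if not self.gene_panel:
            raise ConfigurationError("gene_panel: empty")
        missing = set(self.signature_genes) - set(self.gene_panel)
        if missing:
            raise ConfigurationError(
                f"signature_genes: not in gene_panel: {sorted(missing)}"
            )
        if not self.signature_genes:
            raise ConfigurationError("signature_genes: empty")
        if self.n_patients < 2:
            raise ConfigurationError(f"n_patients: must be >= 2, got {self.n_patients}")
        if self.baseline_hazard <= 0:
            raise ConfigurationError(
                f"baseline_hazard: must be > 0, got {self.baseline_hazard}"
            )
        for name in ("censor_rate", "sd_fraction", "baseline_response_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name}: must be in [0, 1], got {v}")
        if self.expr_sigma < 0:
            raise ConfigurationError(f"expr_sigma: must be >= 0, got {self.expr_sigma}")


def _draw_expression(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    vals = rng.lognormal(
        mean=cfg.expr_mu, sigma=cfg.expr_sigma,
        size=(len(cfg.gene_panel), cfg.n_patients),
    )
    patients = [f"P{i:04d}" for i in range(cfg.n_patients)]
    return pd.DataFrame(vals, index=list(cfg.gene_panel), columns=patients)


def _latent_log2_score(expr: pd.DataFrame, genes: Sequence[str]) -> np.ndarray:
    return np.log2(expr.loc[list(genes)].to_numpy() + 1.0).mean(axis=0)


def _solve_censor_horizon(hazards: np.ndarray, censor_rate: float) -> float:
    """Administrative-censoring horizon T_max with C ~ U(0, T_max).

    For a patient with hazard h, P(censored) = (1 - exp(-h*T)) / (h*T);
    T_max solves mean over patients = censor_rate.  Approximate by design:
    the realized fraction is binomial around this expectation.
    """

    def mean_censor(t: float) -> float:
        x = hazards * t
        return float(np.mean((1.0 - np.exp(-x)) / x))

    lo, hi = 1e-9, 1.0
    while mean_censor(hi) > censor_rate:
        hi *= 2.0
        if hi > 1e9:  # pragma: no cover - censor_rate ~ 0 handled by caller
            break
    return float(optimize.brentq(lambda t: mean_censor(t) - censor_rate, lo, hi))


def generate_survival_cohort(cfg: SimulationConfig) -> ExpressionCohort:
    """Expression cohort with exponential survival times tied to the score.

    Expression is log-normal per gene; each patient's latent score is the
    mean log2(expr+1) over the signature genes; survival time is
    exponential with hazard ``baseline_hazard * exp(log_hr_beta * (s -
    mean(s)))``; censoring is administrative-uniform on [0, T_max] with
    T_max solved so the expected censoring fraction equals ``censor_rate``.
    """
    rng = _rng(cfg.seed, "survival")
    expr = _draw_expression(cfg, rng)
    score = _latent_log2_score(expr, cfg.signature_genes)
    hazards = cfg.baseline_hazard * np.exp(cfg.log_hr_beta * (score - score.mean()))
    t_event = rng.exponential(1.0 / hazards)
    if cfg.censor_rate > 0:
        t_max = _solve_censor_horizon(hazards, cfg.censor_rate)
        t_censor = rng.uniform(0.0, t_max, size=cfg.n_patients)
        os_months = np.minimum(t_event, t_censor)
        os_event = (t_event <= t_censor).astype(int)
    else:
        os_months = t_event
        os_event = np.ones(cfg.n_patients, dtype=int)
    os_months = np.maximum(os_months, 1e-6)  # strictly positive times
    clinical = pd.DataFrame(
        {
            "os_months": os_months,
            "os_event": pd.array(os_event, dtype="Int64"),
            "response": pd.array([pd.NA] * cfg.n_patients, dtype=object),
        },
        index=expr.columns,
    )
    return ExpressionCohort(expression=expr, clinical=clinical)


def generate_response_cohort(cfg: SimulationConfig) -> ExpressionCohort:
    """Expression cohort with RECIST labels from a logistic score model.

    With probability ``sd_fraction`` a patient is labelled SD; otherwise the
    responder probability is ``sigmoid(logit(baseline_response_rate) +
    logistic_beta * s)`` on the centered Z-score-based signature score, with
    responders split PR/CR 50/50 and the rest labelled PD.
    """
    rng = _rng(cfg.seed, "response")
    expr = _draw_expression(cfg, rng)
    sub = expr.loc[list(cfg.signature_genes)].to_numpy()
    sd = sub.std(axis=1, ddof=1, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    z = (sub - sub.mean(axis=1, keepdims=True)) / sd
    score = z.mean(axis=0)
    score = score - score.mean()
    p0 = min(max(cfg.baseline_response_rate, 1e-12), 1 - 1e-12)
    intercept = np.log(p0 / (1.0 - p0))
    p_resp = 1.0 / (1.0 + np.exp(-(intercept + cfg.logistic_beta * score)))
    is_sd = rng.uniform(size=cfg.n_patients) < cfg.sd_fraction
    is_resp = rng.uniform(size=cfg.n_patients) < p_resp
    pr_vs_cr = rng.uniform(size=cfg.n_patients) < 0.5
    labels = np.where(
        is_sd, "SD", np.where(is_resp, np.where(pr_vs_cr, "PR", "CR"), "PD")
    )
    clinical = pd.DataFrame({"response": labels}, index=expr.columns)
    return ExpressionCohort(expression=expr, clinical=clinical)


# ----------------------------------------------------------------------
# Marker tables


def generate_marker_table(
    planted: Sequence[tuple[str, str, float, float]],
    decoys: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Planted marker rows plus decoy rows that fail the signature filter.

    ``planted`` rows are (cluster, gene, fold_change, adj_p) kept verbatim;
    each of the ``decoys`` rows fails fold_change > 1.5 and/or
    adj_p < 0.001.  Row order is shuffled deterministically by ``seed``.
    """
    if decoys < 0:
        raise ConfigurationError(f"decoys: must be >= 0, got {decoys}")
    rng = _rng(seed, "markers")
    rows = [
        {"cluster": c, "gene": g, "fold_change": float(fc), "adj_p": float(p)}
        for c, g, fc, p in planted
    ]
    for row in rows:
        if row["fold_change"] <= 0:
            raise ConfigurationError(f"planted fold_change must be > 0: {row}")
        if not 0 <= row["adj_p"] <= 1:
            raise ConfigurationError(f"planted adj_p must be in [0, 1]: {row}")
    clusters = sorted({r["cluster"] for r in rows}) or ["C0"]
    for i in range(decoys):
        mode = rng.integers(3)  # 0: FC fails, 1: adj_p fails, 2: both fail
        fc = float(rng.uniform(0.2, 1.5)) if mode != 1 else float(rng.uniform(1.6, 5.0))
        padj = float(rng.uniform(0.001, 1.0)) if mode != 0 else float(rng.uniform(0.0, 0.0009))
        rows.append(
            {
                "cluster": clusters[int(rng.integers(len(clusters)))],
                "gene": f"DECOY{i:03d}",
                "fold_change": fc,
                "adj_p": padj,
            }
        )
    table = pd.DataFrame(rows, columns=["cluster", "gene", "fold_change", "adj_p"])
    order = rng.permutation(len(table))
    return table.iloc[order].reset_index(drop=True)


# ----------------------------------------------------------------------
# Single-cell event tables


@dataclass
class CytometrySpec:
    """Parameters of the Boolean single-cell event-table generator.

    ``marker_probs`` gives per-district marginal positivity probabilities
    (a mapping district -> per-marker probabilities, or one shared vector).
    When ``combo_weights`` is given, whole patterns are drawn multinomially
    from it instead, indexed in the canonical combination order of
    :func:`tcellstrat.cytometry.combo_patterns`.
    """

    seed: int = 0
    subjects: int = 2
    districts: tuple[str, ...] = ("PBMC", "NT", "T")
    cells_per_subject_district: int = 1000
    marker_names: tuple[str, ...] = ("PD1", "CD28", "TIGIT", "CTLA4", "TIM3", "LAG3")
    marker_probs: Mapping[str, Sequence[float]] | Sequence[float] = (
        0.4, 0.5, 0.3, 0.2, 0.25, 0.2,
    )
    combo_weights: Sequence[float] | None = None

    def __post_init__(self) -> None:
        self.marker_names = tuple(self.marker_names)
        self.districts = tuple(self.districts)
        k = len(self.marker_names)
        if k == 0:
            raise ConfigurationError("marker_names: empty")
        if len(set(self.marker_names)) != k:
            raise ConfigurationError("marker_names: duplicates")
        if k > 8:
            raise ConfigurationError(f"marker_names: k={k} exceeds maximum of 8")
        if self.subjects < 1:
            raise ConfigurationError(f"subjects: must be >= 1, got {self.subjects}")
        if self.cells_per_subject_district < 1:
            raise ConfigurationError("cells_per_subject_district: must be >= 1")
        bad = set(self.districts) - {"PBMC", "NT", "T"}
        if not self.districts or bad:
            raise ConfigurationError(f"districts: must be a subset of PBMC/NT/T, got {bad}")
        if self.combo_weights is not None:
            if k > 5:
                raise ConfigurationError(
                    "combo_weights: explicit pattern weights support k <= 5 markers"
                )
            w = np.asarray(self.combo_weights, dtype=float)
            if w.shape != (2 ** k,):
                raise ConfigurationError(
                    f"combo_weights: length {w.size} != 2^{k} = {2 ** k}"
                )
            if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
                raise ConfigurationError("combo_weights: must be >= 0 and sum to 1")
            self.combo_weights = tuple(float(x) for x in w)
        else:
            probs = self.marker_probs
            if not isinstance(probs, Mapping):
                probs = {d: probs for d in self.districts}
            norm: dict[str, tuple[float, ...]] = {}
            for d in self.districts:
                if d not in probs:
                    raise ConfigurationError(f"marker_probs: missing district {d!r}")
                p = np.asarray(probs[d], dtype=float)
                if p.shape != (k,):
                    raise ConfigurationError(
                        f"marker_probs[{d!r}]: length {p.size} != k = {k}"
                    )
                if (p < 0).any() or (p > 1).any():
                    raise ConfigurationError(f"marker_probs[{d!r}]: outside [0, 1]")
                norm[d] = tuple(float(x) for x in p)
            self.marker_probs = norm


def generate_event_table(spec: CytometrySpec) -> pd.DataFrame:
    """One Boolean row per cell with subject and district annotations.

    Markers are independent Bernoulli draws at the district's marginal
    probabilities, or whole patterns drawn from ``combo_weights`` when
    given.  A continuous ``pd1_intensity`` column is always emitted: PD1+
    cells draw from a higher-location log-normal than PD1- cells, so
    high/low intensity partitions can be exercised.
    """
    rng = _rng(spec.seed, "events")
    k = len(spec.marker_names)
    patterns = np.array(combo_patterns(spec.marker_names), dtype=bool) if k <= 5 else None
    frames = []
    for s in range(spec.subjects):
        for d in spec.districts:
            n = spec.cells_per_subject_district
            if spec.combo_weights is not None:
                idx = rng.choice(2 ** k, size=n, p=np.asarray(spec.combo_weights))
                gates = patterns[idx]
            else:
                p = np.asarray(spec.marker_probs[d], dtype=float)  # type: ignore[index]
                gates = rng.uniform(size=(n, k)) < p
            frame = pd.DataFrame(gates, columns=list(spec.marker_names))
            frame.insert(0, "district", d)
            frame.insert(0, "subject_id", f"S{s + 1:02d}")
            frame.insert(0, "cell_id", [f"S{s + 1:02d}_{d}_{i:05d}" for i in range(n)])
            if "PD1" in spec.marker_names:
                pos = frame["PD1"].to_numpy()
                intensity = np.where(
                    pos,
                    rng.lognormal(mean=2.0, sigma=0.4, size=n),
                    rng.lognormal(mean=0.5, sigma=0.4, size=n),
                )
            else:
                intensity = rng.lognormal(mean=0.5, sigma=0.4, size=n)
            frame["pd1_intensity"] = intensity
            frames.append(frame)
    return pd.concat(frames, ignore_index=True)
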