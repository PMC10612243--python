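"""Boolean single-cell analyses: quadrants, 2^k combinations, polyfunctionality.

Event tables are cell-level rows with subject/district annotations and
already-gated Boolean marker columns (PD1, CD28, the inhibitory receptors
TIGIT/CTLA4/TIM3/LAG3, effector molecules GRZB/IFNG/TNFA, ...).
Compensation, transformation and manual gating of raw FCS data are out of
scope — gates are set per experiment upstream.

The combination lattice over k markers (k <= 5) enumerates all 2^k
presence/absence patterns, including empty ones, in a canonical order:
ascending number of positive markers, ties broken lexicographically in
marker order with positive sorting before negative.  Index 1 is therefore
the all-negative pattern and index 2^k the all-positive one.  Figure-style
labels (e.g. "IR-1" ... "IR-16") can be attached via an explicit index map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateStatisticError

logger = logging.getLogger(__name__)

ANNOTATION_COLUMNS = ("subject_id", "district")
DISTRICTS = ("PBMC", "NT", "T")
QUADRANTS = ("PD1+CD28-", "PD1+CD28+", "PD1-CD28-", "PD1-CD28+")
DEFAULT_IRS = ("TIGIT", "CTLA4", "TIM3", "LAG3")
DEFAULT_EFFECTORS = ("GRZB", "IFNG", "TNFA")

MAX_COMBO_MARKERS = 5


def marker_columns(events: pd.DataFrame) -> list[str]:
    """The Boolean marker columns of an event table."""
    skip = set(ANNOTATION_COLUMNS) | {"pd1_intensity", "cell_id"}
    return [c for c in events.columns if c not in skip]


def validate_event_table(events: pd.DataFrame) -> pd.DataFrame:
    """Check annotation columns, Boolean markers and key uniqueness."""
    missing = [c for c in ANNOTATION_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"event table missing columns: {missing}")
    for col in marker_columns(events):
        vals = events[col]
        if vals.dtype == bool:
            continue
        uniq = set(pd.unique(vals).tolist())
        if not uniq <= {0, 1, True, False}:
            raise ValueError(f"marker column {col!r} is not Boolean: {sorted(uniq)[:5]}")
    if "cell_id" in events.columns:
        if events.duplicated(subset=["subject_id", "cell_id"]).any():
            raise ValueError("duplicate (subject_id, cell_id) keys")
    return events


def _require_markers(events: pd.DataFrame, markers: Iterable[str]) -> None:
    missing = [m for m in markers if m not in events.columns]
    if missing:
        raise KeyError(f"marker column(s) absent from event table: {missing}")


# ----------------------------------------------------------------------
# PD1/CD28 quadrants


def gate_quadrants(
    events: pd.DataFrame, pd1_col: str = "PD1", cd28_col: str = "CD28"
) -> pd.Series:
    """Assign each cell to one of the four PD1/CD28 quadrants."""
    _require_markers(events, (pd1_col, cd28_col))
    pd1 = events[pd1_col].astype(bool).to_numpy()
    cd28 = events[cd28_col].astype(bool).to_numpy()
    out = np.where(
        pd1,
        np.where(cd28, "PD1+CD28+", "PD1+CD28-"),
        np.where(cd28, "PD1-CD28+", "PD1-CD28-"),
    )
    return pd.Series(out, index=events.index, name="quadrant")


def quadrant_frequencies(
    events: pd.DataFrame,
    by: Sequence[str] = ANNOTATION_COLUMNS,
    pd1_col: str = "PD1",
    cd28_col: str = "CD28",
) -> pd.DataFrame:
    """Per-stratum percentage of each quadrant (rows sum to 100)."""
    quad = gate_quadrants(events, pd1_col, cd28_col)
    df = events[list(by)].assign(quadrant=quad)
    counts = (
        df.groupby(list(by))["quadrant"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=list(QUADRANTS), fill_value=0)
    )
    return counts.div(counts.sum(axis=1), axis=0) * 100.0


# ----------------------------------------------------------------------
# 2^k combination lattice


def combo_patterns(markers: Sequence[str]) -> list[tuple[bool, ...]]:
    """All 2^k Boolean patterns in canonical order.

    Ascending count of positives; ties broken lexicographically in marker
    order with positive before negative, so the first marker's
    single-positive pattern precedes the second marker's.
    """
    k = len(markers)
    if k < 1:
        raise ValueError("need at least one marker")
    if k > MAX_COMBO_MARKERS:
        raise ValueError(f"k={k} markers exceeds the supported maximum of {MAX_COMBO_MARKERS}")
    pats = list(product([False, True], repeat=k))
    pats.sort(key=lambda p: (sum(p), tuple(0 if b else 1 for b in p)))
    return pats


def pattern_string(pattern: Sequence[bool], markers: Sequence[str]) -> str:
    """Human-readable pattern label like ``TIGIT+CTLA4-TIM3+LAG3-``."""
    return "".join(f"{m}{'+' if b else '-'}" for m, b in zip(markers, pattern))


@dataclass
class ComboProfile:
    """Frequencies of every 2^k marker pattern within one cell stratum."""

    marker_order: tuple[str, ...]
    table: pd.DataFrame  # index 1..2^k; columns pattern, label, count, frequency
    n_cells: int

    @property
    def frequencies(self) -> pd.Series:
        return self.table["frequency"]

    def frequency_of(self, pattern: Sequence[bool]) -> float:
        key = pattern_string(pattern, self.marker_order)
        row = self.table[self.table["pattern"] == key]
        return float(row["frequency"].iloc[0])


def _profile(
    cells: pd.DataFrame,
    markers: Sequence[str],
    patterns: list[tuple[bool, ...]],
    index_labels: Mapping[int, str] | None,
) -> ComboProfile:
    mat = cells[list(markers)].astype(bool).to_numpy()
    # encode each cell's pattern as an integer in binary (first marker = MSB)
    weights = 1 << np.arange(len(markers) - 1, -1, -1)
    codes = mat @ weights
    counts_by_code = np.bincount(codes, minlength=2 ** len(markers))
    rows = []
    for idx, pat in enumerate(patterns, start=1):
        code = sum(w for w, b in zip(weights, pat) if b)
        n = int(counts_by_code[code])
        rows.append(
            {
                "pattern": pattern_string(pat, markers),
                "label": (index_labels or {}).get(idx, f"IR-{idx}"),
                "n_positive": sum(pat),
                "count": n,
                "frequency": n / len(cells),
            }
        )
    table = pd.DataFrame(rows, index=pd.RangeIndex(1, len(patterns) + 1, name="index"))
    return ComboProfile(marker_order=tuple(markers), table=table, n_cells=len(cells))


def enumerate_combinations(
    events: pd.DataFrame,
    markers: Sequence[str] = DEFAULT_IRS,
    within_subset: str | None = None,
    stratify_by: Sequence[str] | str | None = None,
    index_labels: Mapping[int, str] | None = None,
) -> dict[object, ComboProfile]:
    """Count every 2^k marker co-expression pattern, per stratum.

    ``within_subset`` restricts to one PD1/CD28 quadrant (e.g.
    ``"PD1+CD28-"``) before counting.  ``stratify_by`` may be ``"subject"``,
    ``"district"``, both, or None for a single profile keyed ``"all"``.
    All 2^k patterns are emitted, zero-frequency ones included; frequencies
    sum to 1 per stratum.  Empty strata are omitted (missing, not zero).
    """
    validate_event_table(events)
    _require_markers(events, markers)
    patterns = combo_patterns(markers)
    if within_subset is not None:
        if within_subset not in QUADRANTS:
            raise ValueError(f"unknown quadrant {within_subset!r}")
        events = events[gate_quadrants(events) == within_subset]
    if stratify_by is None:
        keys = None
    else:
        if isinstance(stratify_by, str):
            stratify_by = [stratify_by]
        alias = {"subject": "subject_id", "district": "district"}
        keys = [alias.get(k, k) for k in stratify_by]
        missing = [k for k in keys if k not in events.columns]
        if missing:
            raise KeyError(f"stratification column(s) absent: {missing}")
    profiles: dict[object, ComboProfile] = {}
    if keys is None:
        if len(events):
            profiles["all"] = _profile(events, markers, patterns, index_labels)
        return profiles
    for key, cells in events.groupby(keys if len(keys) > 1 else keys[0]):
        if len(cells):
            profiles[key] = _profile(cells, markers, patterns, index_labels)
    return profiles


# ----------------------------------------------------------------------
# Polyfunctionality


def polyfunctionality(
    events: pd.DataFrame,
    effector_markers: Sequence[str] = DEFAULT_EFFECTORS,
    min_positive: int = 2,
    within_subset: str | None = None,
    by: Sequence[str] | None = ANNOTATION_COLUMNS,
) -> pd.Series | float:
    """Fraction of cells positive for at least ``min_positive`` effectors.

    Polyfunctional cells simultaneously produce two or more lytic molecules
    (granzyme B, IFN-gamma, TNF-alpha) by default.  With ``by=None`` a single
    fraction is returned; otherwise a Series per stratum.  Empty strata are
    reported as missing rather than zero.
    """
    validate_event_table(events)
    _require_markers(events, effector_markers)
    if not 1 <= min_positive <= len(effector_markers):
        raise ValueError(
            f"min_positive must be in [1, {len(effector_markers)}], got {min_positive}"
        )
    if within_subset is not None:
        events = events[gate_quadrants(events) == within_subset]
    hits = events[list(effector_markers)].astype(bool).sum(axis=1) >= min_positive
    if by is None:
        if len(events) == 0:
            return float("nan")
        return float(hits.mean())
    grouped = hits.groupby([events[c] for c in by]).mean()
    return grouped.rename("polyfunctional_fraction")


# ----------------------------------------------------------------------
# PD1 intensity partition


def split_pd1_intensity(
    events: pd.DataFrame, threshold: float, pd1_col: str = "PD1"
) -> pd.Series:
    """Partition PD1-positive cells into PD1high / PD1low by intensity.

    The threshold is user-supplied per dataset (gates are set by inspection
    upstream; no automatic inference).  PD1-negative cells get a missing
    label; among PD1+ cells, high means intensity strictly above threshold.
    """
    if "pd1_intensity" not in events.columns:
        raise KeyError("event table has no pd1_intensity column")
    _require_markers(events, (pd1_col,))
    pos = events[pd1_col].astype(bool)
    out = pd.Series(pd.NA, index=events.index, dtype=object, name="pd1_level")
    out[pos] = np.where(
        events.loc[pos, "pd1_intensity"].to_numpy(dtype=float) > threshold,
        "PD1high",
        "PD1low",
    )
    return out


# ----------------------------------------------------------------------
# District-comparison statistics


@dataclass
class StatTestResult:
    """A nonparametric group-comparison outcome with Bonferroni adjustment."""

    test_name: str
    statistic: float
    p_raw: float
    p_adjusted: float
    family_size: int
    degenerate: bool = False
    n_used: int = 0


_DESIGN_TESTS = {
    "paired_two": "wilcoxon_signed_rank",
    "paired_many": "friedman",
    "unpaired_two": "mann_whitney",
    "unpaired_many": "kruskal_wallis",
}


def compare_groups(
    values: Sequence[Sequence[float]] | pd.DataFrame,
    design: str,
    family_size: int = 1,
) -> StatTestResult:
    """Dispatch the design-appropriate rank test with Bonferroni correction.

    paired_two -> Wilcoxon signed-rank, paired_many -> Friedman,
    unpaired_two -> Mann-Whitney U, unpaired_many -> Kruskal-Wallis.
    Paired designs take a subjects x conditions DataFrame (or list of
    equal-length condition vectors); incomplete subject rows are dropped
    with a logged count.  ``family_size`` is the caller's comparison family:
    adjusted p = min(1, p * family_size).  All-identical values yield a
    degenerate flag with p = 1 instead of an error.
    """
    if design not in _DESIGN_TESTS:
        raise ValueError(f"unknown design {design!r}; one of {sorted(_DESIGN_TESTS)}")
    if family_size < 1:
        raise ValueError("family_size must be a positive integer")
    test_name = _DESIGN_TESTS[design]

    if design.startswith("paired"):
        frame = (
            values if isinstance(values, pd.DataFrame) else pd.DataFrame(list(zip(*values)))
        )
        n_before = len(frame)
        frame = frame.dropna()
        if len(frame) < n_before:
            logger.info("dropped %d incomplete subject row(s)", n_before - len(frame))
        cols = [frame[c].to_numpy(dtype=float) for c in frame.columns]
        if design == "paired_two" and len(cols) != 2:
            raise ValueError("paired_two needs exactly 2 conditions")
        if design == "paired_many" and len(cols) < 3:
            raise ValueError("paired_many (Friedman) needs >= 3 conditions")
        n_used = len(frame)
        if n_used < 2:
            raise ValueError(f"too few complete subjects ({n_used}) for {test_name}")
        samples = cols
    else:
        samples = [np.asarray(v, dtype=float) for v in values]
        samples = [s[~np.isnan(s)] for s in samples]
        if design == "unpaired_two" and len(samples) != 2:
            raise ValueError("unpaired_two needs exactly 2 groups")
        if design == "unpaired_many" and len(samples) < 2:
            raise ValueError("unpaired_many needs >= 2 groups")
        if any(len(s) < 1 for s in samples):
            raise ValueError("every group needs >= 1 observation")
        n_used = int(sum(len(s) for s in samples))

    stacked = np.concatenate([np.asarray(s, dtype=float).ravel() for s in samples])
    degenerate = np.ptp(stacked) == 0
    if design == "paired_two" and np.all(samples[0] == samples[1]):
        # zero differences everywhere: signed-rank statistic undefined
        degenerate = True
    if degenerate:
        return StatTestResult(
            test_name=test_name, statistic=float("nan"), p_raw=1.0,
            p_adjusted=1.0, family_size=family_size, degenerate=True, n_used=n_used,
        )

    if design == "paired_two":
        stat, p = stats.wilcoxon(samples[0], samples[1])
    elif design == "paired_many":
        stat, p = stats.friedmanchisquare(*samples)
    elif design == "unpaired_two":
        stat, p = stats.mannwhitneyu(samples[0], samples[1], alternative="two-sided")
    else:
        stat, p = stats.kruskal(*samples)
    return StatTestResult(
        test_name=test_name,
        statistic=float(stat),
        p_raw=float(p),
        p_adjusted=min(1.0, float(p) * family_size),
        family_size=family_size,
        degenerate=False,
        n_used=n_used,
    )


# ----------------------------------------------------------------------
# Disk round-trip for event tables


def write_events(events: pd.DataFrame, path: str | Path) -> Path:
    """Write an event table as TSV with markers encoded 0/1."""
    path = Path(path)
    out = events.copy()
    for col in marker_columns(out):
        out[col] = out[col].astype(bool).astype(int)
    out.to_csv(path, sep="\t", index=False)
    return path


def read_events(path: str | Path) -> pd.DataFrame:
    """Read an events.tsv written by :func:`write_events`."""
    events = pd.read_csv(path, sep="\t")
    for col in marker_columns(events):
        events[col] = events[col].astype(bool)
    return validate_event_table(events)
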