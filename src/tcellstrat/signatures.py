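"""Cluster gene-signature derivation and gene-set file handling.

A signature is derived from a per-cluster differential-expression marker
table by keeping the genes that (i) pass a fold-change threshold, (ii) pass
an adjusted-P threshold, and (iii) belong to a gene universe — here
typically an adaptive-immunity gene set.  Both thresholds are strict
(fold change > 1.5 and adjusted P < 0.001 by default), so boundary values
are excluded.  Fold changes are consumed on the linear scale; pass
``log2fc=True`` when the marker table stores log2 fold changes.

Three signatures of CD8+PD1+ T-cell clusters (an effector-memory
KLRG1+EOMES+ CD28+ cluster, a KLRC1+KLRK1+ tissue-resident CD28- cluster
and a Treg-like tissue-resident CD28- cluster) ship as fixtures via
:func:`bundled_signatures`.

Gene-symbol matching is exact and case-sensitive; alias resolution is out
of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import EmptySignatureError, ParseError

MARKER_COLUMNS = ("cluster", "gene", "fold_change", "adj_p")


@dataclass(frozen=True)
class GeneSet:
    """A named set of unique gene symbols (e.g. a pathway gene universe)."""

    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("GeneSet must be non-empty")
        if any(not isinstance(g, str) or not g for g in self.genes):
            raise ValueError("gene symbols must be non-empty strings")
        object.__setattr__(self, "genes", frozenset(self.genes))

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class GeneSignature:
    """An ordered list of unique genes marking a cell population."""

    name: str
    genes: tuple[str, ...]
    source_cluster: str | None = None

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("GeneSignature must be non-empty")
        object.__setattr__(self, "genes", tuple(self.genes))
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("GeneSignature genes must be unique")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)


def validate_marker_table(markers: pd.DataFrame) -> pd.DataFrame:
    """Check a marker table for required columns and valid values."""
    missing = [c for c in MARKER_COLUMNS if c not in markers.columns]
    if missing:
        raise ValueError(f"marker table missing columns: {missing}")
    if markers.duplicated(subset=["cluster", "gene"]).any():
        dup = markers[markers.duplicated(subset=["cluster", "gene"], keep=False)]
        raise ValueError(
            f"duplicate (cluster, gene) pairs: "
            f"{dup[['cluster', 'gene']].drop_duplicates().values.tolist()[:5]}"
        )
    if (markers["fold_change"] <= 0).any():
        raise ValueError("fold_change must be positive")
    if ((markers["adj_p"] < 0) | (markers["adj_p"] > 1)).any():
        raise ValueError("adj_p must lie in [0, 1]")
    return markers


def derive_signature(
    markers: pd.DataFrame,
    cluster_id: str,
    universe: GeneSet,
    fc_min: float = 1.5,
    padj_max: float = 0.001,
    log2fc: bool = False,
    name: str | None = None,
) -> GeneSignature:
    """Filter a cluster's markers into a gene signature.

    Keeps exactly the genes of ``cluster_id`` with fold change strictly
    above ``fc_min``, adjusted P strictly below ``padj_max`` and membership
    in ``universe``; output is ordered by descending fold change with
    alphabetical tie-break so derivation is reproducible.

    Raises
    ------
    KeyError
        if ``cluster_id`` is absent from the table.
    EmptySignatureError
        if no gene passes all three predicates.
    """
    validate_marker_table(markers)
    sub = markers[markers["cluster"] == cluster_id]
    if sub.empty:
        raise KeyError(f"cluster {cluster_id!r} not present in marker table")
    fc = sub["fold_change"].astype(float)
    if log2fc:
        fc = 2.0 ** fc
    keep = (fc > fc_min) & (sub["adj_p"] < padj_max) & sub["gene"].isin(universe.genes)
    passed = sub.loc[keep].assign(_fc=fc[keep])
    if passed.empty:
        raise EmptySignatureError(
            f"no gene of cluster {cluster_id!r} passes fold_change > {fc_min}, "
            f"adj_p < {padj_max} and membership in {universe.name!r}"
        )
    passed = passed.sort_values(["_fc", "gene"], ascending=[False, True])
    return GeneSignature(
        name=name or f"{cluster_id}_signature",
        genes=tuple(passed["gene"]),
        source_cluster=str(cluster_id),
    )


# ----------------------------------------------------------------------
# Bundled fixtures: the three printed CD8+PD1+ cluster signatures.

_BUNDLED = {
    # KLRG1+EOMES+ CD28+ effector-memory cluster (11 genes)
    "C0": (
        "CD74", "PTPRC", "ITGA4", "KLRG1", "CD8A", "TRAT1",
        "CD8B", "LCK", "CD3E", "HLA-DMA", "HLA-DPA1",
    ),
    # KLRC1+KLRK1+ tissue-resident-memory CD28- cluster (5 genes as printed)
    "C2": ("KLRC1", "CD8A", "CD8B", "CD3E", "KLRK1"),
    # Treg-like tissue-resident-memory CD28- cluster (6 genes)
    "C4": ("CD74", "LAG3", "CD8B", "HLA-DMA", "HLA-DRA", "HLA-DPA1"),
}


def bundled_signatures() -> dict[str, GeneSignature]:
    """The three published adaptive-immunity cluster signatures.

    Returns a mapping ``{"C0": ..., "C2": ..., "C4": ...}``.  Gene lists are
    transcribed verbatim: C0 has 11 genes, C2 has the 5 genes printed for it
    (the accompanying prose cites 7, a discrepancy this fixture does not
    resolve), C4 has 6 genes.
    """
    return {
        cluster: GeneSignature(
            name=f"AdaptiveImmunity_{cluster}", genes=genes, source_cluster=cluster
        )
        for cluster, genes in _BUNDLED.items()
    }


# ----------------------------------------------------------------------
# File formats: plain gene lists, GMT gene sets, TSV marker tables.


def read_gene_set(path: str | Path, name: str | None = None) -> GeneSet:
    """Read a gene set from a plain list (one symbol per line) or a GMT line.

    A line containing tabs is interpreted as GMT (name, description,
    genes...); otherwise each non-empty line is one symbol.  Mixing the two
    styles is rejected.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    symbols: list[str] = []
    gmt_name: str | None = None
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if "\t" in line:
            if symbols:
                raise ParseError("GMT line mixed with plain gene list", lineno)
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    "GMT line needs name, description and >=1 gene", lineno
                )
            gmt_name = fields[0]
            genes = [g for g in fields[2:] if g.strip()]
            if not genes:
                raise ParseError("GMT line has no genes", lineno)
            if len(lines) > lineno and any(l.strip() for l in lines[lineno:]):
                raise ParseError("multiple gene sets in one file", lineno + 1)
            symbols = genes
            break
        token = line.strip()
        if " " in token:
            raise ParseError(f"unexpected whitespace in symbol {token!r}", lineno)
        symbols.append(token)
    if not symbols:
        raise ParseError(f"no genes found in {path}", None)
    return GeneSet(name=name or gmt_name or path.stem, genes=frozenset(symbols))


def write_gene_set(gene_set: GeneSet, path: str | Path) -> Path:
    """Write a gene set as a single GMT line (sorted symbols)."""
    path = Path(path)
    fields = [gene_set.name, "na", *sorted(gene_set.genes)]
    path.write_text("\t".join(fields) + "\n")
    return path


def write_signature(signature: GeneSignature, path: str | Path) -> Path:
    """Write a signature as a single GMT line preserving gene order."""
    path = Path(path)
    fields = [signature.name, signature.source_cluster or "na", *signature.genes]
    path.write_text("\t".join(fields) + "\n")
    return path


def read_signature(path: str | Path) -> GeneSignature:
    """Read a signature from a one-line GMT file (order-preserving)."""
    path = Path(path)
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        if not raw.strip():
            continue
        fields = raw.split("\t")
        if len(fields) < 3:
            raise ParseError("GMT line needs name, description and >=1 gene", lineno)
        return GeneSignature(
            name=fields[0],
            genes=tuple(g for g in fields[2:] if g.strip()),
            source_cluster=None if fields[1] in ("na", "") else fields[1],
        )
    raise ParseError(f"no signature found in {path}", None)


def read_marker_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV marker table with header cluster/gene/fold_change/adj_p."""
    markers = pd.read_csv(path, sep="\t")
    return validate_marker_table(markers)


def write_marker_table(markers: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    validate_marker_table(markers)
    markers.to_csv(path, sep="\t", index=False)
    return path
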