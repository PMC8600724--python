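"""Pfam-domain asparaginase classification and DEG table logic.

L-asparaginase (EC 3.5.1.1) candidates are grouped by domain architecture:

* class I  — PF01112 (Asparaginase_2);
* class II — PF00710 (Asparaginase, N-terminal) together with PF17763
  (Glutaminase/Asparaginase C-terminal);
* class III — PF06089 (L-asparaginase II);
* homology_only — no class domain, but the product annotation contains
  "asparaginase" (case-insensitive), i.e. a candidate from sequence
  homology alone.

Differential-expression calls consume an external results table (gene,
log2 fold change, p, adjusted p): this module applies the decision rules —
a DEG is a >= 4-fold change (|log2FC| >= 2, inclusive), and significance is
adjusted p <= 0.05 (inclusive; a missing adjusted p is never significant).
"Significantly up-regulated" uses the significance filter and the sign of
the fold change only, not the 4-fold rule; both filters are exposed
separately.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

CLASS_I_DOMAIN = "PF01112"
CLASS_II_DOMAINS = frozenset({"PF00710", "PF17763"})
CLASS_III_DOMAIN = "PF06089"

_PFAM_RE = re.compile(r"^PF\d{5}$")


@dataclass
class DomainAnnotation:
    """Pfam accessions and product annotation of one protein."""

    protein_id: str
    pfam_accessions: frozenset[str]
    product: str = ""

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise ValueError("protein_id must be non-empty")
        self.pfam_accessions = frozenset(self.pfam_accessions)
        for acc in self.pfam_accessions:
            if not _PFAM_RE.match(acc):
                raise ValueError(f"malformed Pfam accession {acc!r}")


@dataclass
class AsparaginaseCall:
    protein_id: str
    class_label: str  # class_I | class_II | class_III | homology_only | none
    evidence: str


@dataclass
class ExpressionRecord:
    """One row of an external differential-expression results table."""

    gene_id: str
    log2_fold_change: float
    p_value: float | None = None
    adjusted_p_value: float | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.log2_fold_change):
            raise ValueError(f"non-finite log2FC for {self.gene_id!r}")
        for p in (self.p_value, self.adjusted_p_value):
            if p is not None and not (0 <= p <= 1):
                raise ValueError(f"p-value {p} outside [0, 1] for {self.gene_id!r}")


@dataclass
class DegCall:
    gene_id: str
    significant: bool
    deg4: bool
    direction: str  # up | down | none
    linear_fold: float


def classify_asparaginase(
    annotations: Iterable[DomainAnnotation],
) -> list[AsparaginaseCall]:
    """Classify proteins by asparaginase domain architecture.

    Precedence when several class domains co-occur: class II > class III >
    class I (no known protein carries domains of two classes; the order is
    fixed for determinism).
    """
    calls = []
    for ann in annotations:
        accs = ann.pfam_accessions
        if CLASS_II_DOMAINS <= accs:
            calls.append(
                AsparaginaseCall(ann.protein_id, "class_II", "PF00710+PF17763")
            )
        elif CLASS_III_DOMAIN in accs:
            calls.append(AsparaginaseCall(ann.protein_id, "class_III", CLASS_III_DOMAIN))
        elif CLASS_I_DOMAIN in accs:
            calls.append(AsparaginaseCall(ann.protein_id, "class_I", CLASS_I_DOMAIN))
        elif "asparaginase" in (ann.product or "").lower():
            calls.append(
                AsparaginaseCall(ann.protein_id, "homology_only", ann.product)
            )
        else:
            calls.append(AsparaginaseCall(ann.protein_id, "none", ""))
    return calls


def prefilter_counts(
    count_matrix: pd.DataFrame,
    group_labels: Mapping[str, str],
    min_median: float = 10,
) -> list[str]:
    """Low-expression prefilter: keep a gene iff the maximum over groups of
    the within-group median count is at least ``min_median``.

    ``count_matrix`` is genes x samples; ``group_labels`` maps sample
    (column) names to group names.
    """
    groups: dict[str, list[str]] = {}
    for sample, group in group_labels.items():
        if sample not in count_matrix.columns:
            raise ValueError(f"sample {sample!r} not in count matrix")
        groups.setdefault(group, []).append(sample)
    if not groups:
        raise ValueError("no sample groups given")
    medians = pd.DataFrame(
        {g: count_matrix[samples].median(axis=1) for g, samples in groups.items()}
    )
    keep = medians.max(axis=1) >= min_median
    return list(count_matrix.index[keep])


def call_deg(
    records: Iterable[ExpressionRecord],
    fold_threshold: float = 4.0,
    alpha: float = 0.05,
) -> list[DegCall]:
    """Apply the DEG rules to an expression results table.

    ``deg4``: |log2FC| >= log2(fold_threshold) (inclusive).
    ``significant``: adjusted p <= alpha; missing adjusted p is never
    significant.  ``direction`` is the fold-change sign for significant
    genes, ``none`` otherwise.
    """
    lfc_threshold = math.log2(fold_threshold)
    calls = []
    for rec in records:
        significant = (
            rec.adjusted_p_value is not None and rec.adjusted_p_value <= alpha
        )
        deg4 = abs(rec.log2_fold_change) >= lfc_threshold
        if significant and rec.log2_fold_change > 0:
            direction = "up"
        elif significant and rec.log2_fold_change < 0:
            direction = "down"
        else:
            direction = "none"
        calls.append(
            DegCall(
                gene_id=rec.gene_id,
                significant=significant,
                deg4=deg4,
                direction=direction,
                linear_fold=2.0 ** rec.log2_fold_change,
            )
        )
    return calls


def cog_category_shares(
    cog_assignments: Mapping[str, str], gene_ids: Iterable[str]
) -> pd.Series:
    """Percentage share of each COG category within a gene set."""
    cats = [cog_assignments[g] for g in gene_ids if g in cog_assignments]
    if not cats:
        return pd.Series(dtype=float)
    counts = pd.Series(cats).value_counts()
    return 100.0 * counts / counts.sum()


# ---------------------------------------------------------------------------
# TSV I/O (headered, tab-separated, missing values as "NA")
# ---------------------------------------------------------------------------

def read_domain_table(path: str | Path) -> list[DomainAnnotation]:
    """Read a protein -> Pfam table (columns: protein_id, pfam, product).

    ``pfam`` holds semicolon-separated accessions, optionally with
    ``PFxxxxx:description`` suffixes which are stripped.
    """
    df = pd.read_csv(path, sep="\t", na_values=["NA"], dtype=str)
    annotations = []
    for _, row in df.iterrows():
        raw = row.get("pfam")
        accs = []
        if isinstance(raw, str) and raw:
            for token in raw.split(";"):
                token = token.strip().split(":")[0]
                if token:
                    accs.append(token)
        product = row.get("product")
        annotations.append(
            DomainAnnotation(
                protein_id=row["protein_id"],
                pfam_accessions=frozenset(accs),
                product=product if isinstance(product, str) else "",
            )
        )
    return annotations


def read_expression_table(path: str | Path) -> list[ExpressionRecord]:
    """Read a results TSV (gene_id, log2_fold_change, p_value, adjusted_p_value)."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    records = []
    for _, row in df.iterrows():
        records.append(
            ExpressionRecord(
                gene_id=str(row["gene_id"]),
                log2_fold_change=float(row["log2_fold_change"]),
                p_value=None if pd.isna(row.get("p_value")) else float(row["p_value"]),
                adjusted_p_value=(
                    None
                    if pd.isna(row.get("adjusted_p_value"))
                    else float(row["adjusted_p_value"])
                ),
            )
        )
    return records


def deg_table(calls: Sequence[DegCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": c.gene_id,
                "significant": c.significant,
                "deg4": c.deg4,
                "direction": c.direction,
                "linear_fold": c.linear_fold,
            }
            for c in calls
        ]
    )
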