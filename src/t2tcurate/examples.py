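"""Published worked-example data.

The deposited *Trichoderma simmonsii* GH-Sj1 annotation includes seven
putative L-asparaginase genes (locus tag prefix H0G86) with their Pfam
domains, product annotations and differential-expression results between
asparaginase-rich (1% L-asparagine) and non-rich culture conditions.  The
table below is that published gene table; it drives the README worked
example and the acceptance checks of the classification and DEG rules.

Note on fold changes: the linear fold for H0G86_011901 implied by its
log2 fold change (2**7.61 ~ 195) differs from the ~128-fold narrative
figure that circulates with this dataset; this package always reports
2**log2FC and leaves the source tables unreconciled.
"""

from __future__ import annotations

import pandas as pd

from .gene_tables import DomainAnnotation, ExpressionRecord

_ASPARAGINASE_ROWS = [
    # protein_id, amino_acids, log2_fold_change, p_value, adjusted_p_value,
    # product, pfam accessions
    ("H0G86_011901", 571, 7.61, 1.45e-05, 6.99e-05,
     "Putative L-asparaginase", "PF07690"),
    ("H0G86_012728", 522, 3.66, 3.30e-16, 6.31e-15,
     "Asparaginase", "PF00710;PF17763"),
    ("H0G86_013185", 362, 1.70, 3.80e-05, 1.69e-04,
     "hypothetical protein", "PF06089"),
    ("H0G86_012144", 460, -3.90, 8.70e-15, 1.46e-13,
     "hypothetical protein", "PF01112"),
    ("H0G86_001521", 614, -0.34, 0.082, 0.15,
     "hypothetical protein", "PF01112"),
    ("H0G86_011897", 840, 1.00, 0.04, 0.08,
     "hypothetical protein", "PF01112"),
    ("H0G86_012090", 361, 0.50, 0.16, 0.26,
     "Asparaginase", "PF01112"),
]


def asparaginase_gene_table() -> pd.DataFrame:
    """The published putative-asparaginase gene table as a DataFrame."""
    return pd.DataFrame(
        _ASPARAGINASE_ROWS,
        columns=[
            "protein_id", "amino_acids", "log2_fold_change", "p_value",
            "adjusted_p_value", "product", "pfam",
        ],
    )


def asparaginase_annotations() -> list[DomainAnnotation]:
    """The same table as :class:`DomainAnnotation` rows."""
    return [
        DomainAnnotation(
            protein_id=pid,
            pfam_accessions=frozenset(pfam.split(";")),
            product=product,
        )
        for pid, _aa, _lfc, _p, _padj, product, pfam in _ASPARAGINASE_ROWS
    ]


def asparaginase_expression_records() -> list[ExpressionRecord]:
    """The same table as :class:`ExpressionRecord` rows."""
    return [
        ExpressionRecord(
            gene_id=pid, log2_fold_change=lfc, p_value=p, adjusted_p_value=padj
        )
        for pid, _aa, lfc, p, padj, _product, _pfam in _ASPARAGINASE_ROWS
    ]
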