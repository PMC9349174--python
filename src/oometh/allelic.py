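"""SNP-based maternal/paternal read classification and allelic gene counts.

A read is classified from the bases it shows at strain-informative SNPs:
maternal if it matches only maternal alleles, paternal if only paternal,
unassigned if it matches neither (no SNPs, N bases, or sequencing-error
bases, which are ignored rather than counted as conflicts), and
conflicting if it matches both.  SNPs shared with the third strain in the
cross are excluded before classification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .genome import SnpRecord
from .simulate import ReadSnpObservation

MATERNAL = "maternal"
PATERNAL = "paternal"
UNASSIGNED = "unassigned"
CONFLICTING = "conflicting"
LABELS = (MATERNAL, PATERNAL, UNASSIGNED, CONFLICTING)


@dataclass(frozen=True)
class AllelicAssignment:
    read_id: str
    gene_id: str
    label: str


def filter_informative_snps(snps: Iterable[SnpRecord]) -> list[SnpRecord]:
    """Drop SNPs shared with the third strain (uninformative in the cross)."""
    return [s for s in snps if not s.shared_with_third_strain]


def assign_read_allele(read: ReadSnpObservation) -> AllelicAssignment:
    """Classify one read from its SNP base calls.

    Bases matching neither parental allele (including N) are treated as
    sequencing error and ignored.
    """
    m = p = 0
    for snp, base in read.observations:
        if base == snp.maternal_allele:
            m += 1
        elif base == snp.paternal_allele:
            p += 1
    if m > 0 and p == 0:
        label = MATERNAL
    elif p > 0 and m == 0:
        label = PATERNAL
    elif m == 0 and p == 0:
        label = UNASSIGNED
    else:
        label = CONFLICTING
    return AllelicAssignment(read.read_id, read.gene_id, label)


def assign_reads(reads: Sequence[ReadSnpObservation]) -> list[AllelicAssignment]:
    return [assign_read_allele(r) for r in reads]


def allelic_gene_counts(assignments: Sequence[AllelicAssignment]) -> pd.DataFrame:
    """Per-gene maternal / paternal / unassigned / conflicting read tallies.

    Conflicting reads are excluded from both allelic tallies and reported
    in their own column, so totals are conserved.
    """
    rows = [(a.gene_id, a.label) for a in assignments]
    df = pd.DataFrame(rows, columns=["gene_id", "label"])
    counts = (
        df.groupby(["gene_id", "label"]).size().unstack(fill_value=0)
        if len(df)
        else pd.DataFrame()
    )
    out = pd.DataFrame(index=counts.index if len(df) else [])
    for label in LABELS:
        out[label] = counts[label] if label in counts else 0
    out.index.name = "gene_id"
    return out.reset_index()
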