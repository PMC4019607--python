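"""Exact-term annotation filtering of predicted target genes.

Genes are kept when they carry at least one annotation whose term is
exactly (case-insensitively) in the query list with at least the
required evidence count — the offline analogue of restricting targets
to records indexed under a fixed set of subject headings with at least
one supporting literature reference.  Substring matches never count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import FormatError

log = logging.getLogger(__name__)

#: default eosinophil-biology query terms
DEFAULT_TERMS = (
    "eosinophils",
    "eosinophilia",
    "IL-3",
    "IL-5",
    "eosinophil peroxidase",
    "eosinophil cationic protein",
    "eosinophil granule proteins",
    "eosinophil major basic protein",
    "eosinophil-derived neurotoxin",
)


@dataclass
class TermQuery:
    terms: tuple[str, ...] = DEFAULT_TERMS
    min_evidence: int = 1

    @property
    def folded(self) -> frozenset[str]:
        return frozenset(t.casefold() for t in self.terms)


def read_annotation(path: str | Path) -> dict[str, set[tuple[str, int]]]:
    """Read a (gene, term, evidence_count) TSV into a gene->annotations map.

    Terms are stored case-folded.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"gene": str, "term": str})
    required = {"gene", "term", "evidence_count"}
    if not required.issubset(df.columns):
        raise FormatError(f"annotation TSV needs columns {sorted(required)}")
    if (df["evidence_count"] < 0).any():
        raise FormatError("negative evidence_count")
    annotation: dict[str, set[tuple[str, int]]] = {}
    for gene, term, count in df.itertuples(index=False):
        annotation.setdefault(gene, set()).add((term.casefold(), int(count)))
    return annotation


def filter_by_terms(
    genes: set[str],
    annotation: dict[str, set[tuple[str, int]]],
    query: TermQuery,
) -> set[str]:
    """Genes with >=1 annotation exactly matching a query term.

    Matching is exact full-term equality after case folding, with
    evidence_count >= query.min_evidence.  Genes absent from the
    annotation map are silently excluded (count logged).
    """
    folded = query.folded
    kept = set()
    unknown = 0
    for gene in genes:
        entries = annotation.get(gene)
        if entries is None:
            unknown += 1
            continue
        if any(t in folded and c >= query.min_evidence for t, c in entries):
            kept.add(gene)
    if unknown:
        log.info("%d query genes had no annotation record", unknown)
    return kept


def intersect_targets(predicted: set[str], annotated: set[str]) -> list[str]:
    """Sorted intersection of the predicted and annotation-filtered sets."""
    return sorted(set(predicted) & set(annotated))
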