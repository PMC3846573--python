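"""Tag-to-gene annotation against a virtual-digest reference index.

The index maps every CATG-anchored 21-mer of the sense strand of each
reference transcript to the genes carrying it, with the site rank counted
from the 3' end. Observed tags are assigned to a gene when their match set
(exact hits if any exist, otherwise all Hamming-distance-1 hits over the
17-nt variable region) contains exactly one gene; tags matching more than
one gene are discarded as ambiguous. Per-gene counts are normalized to
tags-per-million retained tags (TPM).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from tagdge.digest import ANCHOR, TAG_LENGTH, tag_sites
from tagdge.tagproc import TagCountTable
from tagdge.util import pct

_ALPHABET = "ACGT"


@dataclass
class ReferenceTagIndex:
    """Virtual-digest product: tag -> {gene -> 3'-rank of its site}."""

    tag_to_genes: dict[str, dict[str, int]] = field(default_factory=dict)
    genes: list[str] = field(default_factory=list)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def __len__(self) -> int:
        return len(self.tag_to_genes)

    def exact(self, tag: str) -> dict[str, int]:
        return self.tag_to_genes.get(tag, {})


def build_index(transcripts: Iterable[tuple[str, str]]) -> ReferenceTagIndex:
    """Virtually digest *transcripts* into a ReferenceTagIndex.

    Transcripts without any CATG site followed by >=17 nt contribute no
    keys (such genes can never be detected by tags). Duplicate gene IDs
    are rejected.
    """
    index = ReferenceTagIndex()
    seen: set[str] = set()
    for gene_id, seq in transcripts:
        if gene_id in seen:
            raise ValueError(f"duplicate gene ID: {gene_id}")
        seen.add(gene_id)
        index.genes.append(gene_id)
        for rank, _pos, tag in tag_sites(seq):
            genes = index.tag_to_genes.setdefault(tag, {})
            # a tag occurring at several sites of one gene keeps its 3'-most rank
            if gene_id not in genes or rank < genes[gene_id]:
                genes[gene_id] = rank
    return index


@dataclass
class AnnotationReport:
    """Mapping statistics of one library against the reference index."""

    unique_tags: int = 0
    matched_unique_tags: int = 0
    ambiguous_unique_tags: int = 0
    unmatched_unique_tags: int = 0
    matched_tag_copies: int = 0
    retained_tags: int = 0
    matched_genes: int = 0
    assignment: dict[str, str] = field(default_factory=dict, repr=False)


def _mismatch_variants(tag: str):
    """All Hamming-1 variants over the variable region (anchor untouched)."""
    for i in range(len(ANCHOR), TAG_LENGTH):
        original = tag[i]
        for b in _ALPHABET:
            if b != original:
                yield tag[:i] + b + tag[i + 1 :]


def map_tags(
    table: TagCountTable, index: ReferenceTagIndex, max_mismatch: int = 1
) -> tuple[dict[str, int], AnnotationReport]:
    """Assign retained tags to genes and aggregate per-gene copy numbers.

    Exact hits take precedence: a tag with exact hits is resolved on those
    alone, and the 1-mismatch neighborhood is searched only for tags with
    no exact hit. In either case a tag is assigned iff the resulting gene
    set is a single gene; multi-gene tags are discarded. An empty index
    simply leaves every tag unmatched.
    """
    gene_counts: dict[str, int] = {}
    report = AnnotationReport(
        unique_tags=table.ledger.unique_tags, retained_tags=table.ledger.retained_tags
    )
    for tag, count in table.entries.items():
        hits = index.exact(tag)
        genes = set(hits)
        if not genes and max_mismatch >= 1:
            for variant in _mismatch_variants(tag):
                genes.update(index.exact(variant))
        if len(genes) == 1:
            gene = next(iter(genes))
            gene_counts[gene] = gene_counts.get(gene, 0) + count
            report.matched_unique_tags += 1
            report.matched_tag_copies += count
            report.assignment[tag] = gene
        elif genes:
            report.ambiguous_unique_tags += 1
        else:
            report.unmatched_unique_tags += 1
    report.matched_genes = len(gene_counts)
    return gene_counts, report


def annotation_rates(report: AnnotationReport, n_reference_genes: int) -> dict[str, float]:
    """Table-2-style percentages (half-up, two decimals)."""
    if report.unique_tags == 0 or n_reference_genes == 0 or report.retained_tags == 0:
        raise ZeroDivisionError("annotation rates undefined: zero denominator")
    return {
        "matched_unique_pct": pct(report.matched_unique_tags, report.unique_tags),
        "matched_gene_pct": pct(report.matched_genes, n_reference_genes),
        "matched_total_pct": pct(report.matched_tag_copies, report.retained_tags),
    }


def expression_frame(
    libraries: Mapping[str, tuple[Mapping[str, int], int]],
    genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Combine per-library gene counts into a count/TPM table.

    *libraries* maps library ID to ``(gene_counts, retained_tags)``; TPM is
    count / retained_tags * 1e6. Genes absent from a library get count 0.
    """
    if genes is None:
        all_genes: set[str] = set()
        for counts, _ in libraries.values():
            all_genes.update(counts)
        genes = sorted(all_genes)
    data: dict[str, list] = {"gene_id": list(genes)}
    for lib, (counts, retained) in libraries.items():
        if retained <= 0:
            raise ValueError(f"library {lib!r} has no retained tags")
        col = [counts.get(g, 0) for g in genes]
        data[f"count_{lib}"] = col
        data[f"tpm_{lib}"] = [c / retained * 1e6 for c in col]
    return pd.DataFrame(data)
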