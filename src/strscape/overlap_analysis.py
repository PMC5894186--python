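"""Gene-level intersection statistics.

Counts genes carrying STRs, the triple overlap of trinucleotide STR x
size-3 indel x gene (heterozygous coding-STR length variants), and per-bp
variant rates by class.
"""

from __future__ import annotations

import warnings
from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._intervals import merge, overlaps
from .io_formats import GeneModel, StrscapeWarning, VariantRecord
from .str_detection import STRLocus

__all__ = [
    "GeneSTRSummary",
    "VariantRateTable",
    "genes_with_strs",
    "tri_indel_gene_overlap",
    "indel_anchor",
    "variant_rates",
]

VARIANT_CLASSES = ("SNP", "MNP", "INDEL", "COMPLEX")


@dataclass
class GeneSTRSummary:
    gene_id: str
    strs_total: int = 0
    strs_by_unit: dict[int, int] = field(default_factory=dict)
    has_str: bool = False
    has_tri_indel: bool = False


@dataclass
class VariantRateTable:
    """Per-class variant counts and per-bp rates (nucleotide diversity)."""

    counts: dict[str, int]
    assembly_bp: int

    @property
    def rates(self) -> dict[str, float]:
        return {k: v / self.assembly_bp for k, v in self.counts.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "count": pd.Series(self.counts),
                "rate_per_bp": pd.Series(self.rates),
            }
        )


def _gene_scope_intervals(gene: GeneModel, scope: str) -> list[tuple[int, int]]:
    if scope == "gene_span":
        return [(gene.span.start, gene.span.end)]
    if scope == "cds":
        return merge([(c.start, c.end) for c in gene.cds])
    raise ValueError(f"unknown scope {scope!r} (use 'gene_span' or 'cds')")


def genes_with_strs(
    genes: Sequence[GeneModel],
    loci: Sequence[STRLocus],
    scope: str = "gene_span",
) -> list[GeneSTRSummary]:
    """One summary per gene: STR counts overlapping the chosen scope.

    An STR counts for a gene if it overlaps the scope (whole gene span or
    merged CDS) by at least one bp; each locus is counted once per gene.
    """
    by_seq: dict[str, list[STRLocus]] = {}
    for l in loci:
        by_seq.setdefault(l.seq_id, []).append(l)
    starts: dict[str, list[int]] = {}
    maxlen: dict[str, int] = {}
    for seq_id, ls in by_seq.items():
        ls.sort(key=lambda l: l.start)
        starts[seq_id] = [l.start for l in ls]
        maxlen[seq_id] = max(l.array_bp for l in ls)
    gene_seqs = {g.span.seq_id for g in genes}
    if loci and genes and gene_seqs.isdisjoint(by_seq):
        warnings.warn(
            "gene and STR sequence ids are disjoint; all overlap counts will be zero",
            StrscapeWarning,
            stacklevel=2,
        )
    out: list[GeneSTRSummary] = []
    for gene in genes:
        summary = GeneSTRSummary(gene_id=gene.gene_id)
        seq_id = gene.span.seq_id
        ls = by_seq.get(seq_id, [])
        if ls:
            scope_ivs = _gene_scope_intervals(gene, scope)
            if scope_ivs:
                lo = min(s for s, _ in scope_ivs) - maxlen[seq_id]
                hi = max(e for _, e in scope_ivs)
                i0 = bisect_left(starts[seq_id], lo)
                for l in ls[i0:]:
                    if l.start >= hi:
                        break
                    if any(overlaps((l.start, l.end), iv) for iv in scope_ivs):
                        summary.strs_total += 1
                        summary.strs_by_unit[l.unit_size] = (
                            summary.strs_by_unit.get(l.unit_size, 0) + 1
                        )
        summary.has_str = summary.strs_total > 0
        out.append(summary)
    return out


def indel_anchor(variant: VariantRecord) -> int:
    """First affected base after the shared ref/alt prefix.

    Assumes VCF left alignment: for the usual padded representation
    (ref=A, alt=ATTT at pos p) the anchor is p+1, the first inserted or
    deleted base.
    """
    k = 0
    for a, b in zip(variant.ref, variant.alt):
        if a != b:
            break
        k += 1
    return variant.pos + k


def tri_indel_gene_overlap(
    genes: Sequence[GeneModel],
    tri_loci: Sequence[STRLocus],
    variants: Sequence[VariantRecord],
    scope: str = "gene_span",
) -> tuple[int, dict[str, bool]]:
    """Genes with a size-3 indel inside a trinucleotide STR.

    A gene is counted iff some quality/depth-filtered INDEL of |size| == 3
    has its anchor position inside a u=3 STR locus that overlaps the gene
    scope. Returns (count, per-gene flag map).
    """
    tri_loci = [l for l in tri_loci if l.unit_size == 3]
    anchors_by_seq: dict[str, list[int]] = {}
    for v in variants:
        if v.var_class == "INDEL" and abs(v.indel_size) == 3:
            anchors_by_seq.setdefault(v.seq_id, []).append(indel_anchor(v))
    # trinucleotide loci containing at least one size-3 indel anchor
    hit_loci: list[STRLocus] = []
    for l in tri_loci:
        anchors = anchors_by_seq.get(l.seq_id, ())
        if any(l.start <= a < l.end for a in anchors):
            hit_loci.append(l)
    flags: dict[str, bool] = {}
    for gene in genes:
        scope_ivs = _gene_scope_intervals(gene, scope)
        flags[gene.gene_id] = any(
            l.seq_id == gene.span.seq_id and overlaps((l.start, l.end), iv)
            for l in hit_loci
            for iv in scope_ivs
        )
    return sum(flags.values()), flags


def variant_rates(
    variants: Sequence[VariantRecord] | Mapping[str, int],
    assembly_bp: int,
) -> VariantRateTable:
    """Per-class counts and per-bp rates over the assembly.

    Accepts either a list of VariantRecords or a precomputed class->count
    mapping (useful when only published count tables are available).
    """
    if assembly_bp <= 0:
        raise ValueError("assembly_bp must be positive")
    if isinstance(variants, Mapping):
        counts = {k: 0 for k in VARIANT_CLASSES}
        for k, v in variants.items():
            if k not in counts:
                raise ValueError(f"unknown variant class {k!r}")
            counts[k] = int(v)
    else:
        counts = {k: 0 for k in VARIANT_CLASSES}
        for v in variants:
            counts[v.var_class] += 1
    return VariantRateTable(counts=counts, assembly_bp=assembly_bp)
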