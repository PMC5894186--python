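"""Readers and writers for FASTA, GFF3, VCF and the sidecar TSV maps.

Coordinate convention: everything in memory is 0-based half-open.
Conversion to/from 1-based closed coordinates happens only here, at the
file boundary (GFF3, VCF).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import gffutils
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from ._intervals import merge

__all__ = [
    "StrscapeWarning",
    "SequenceRecord",
    "GenomicInterval",
    "GeneModel",
    "VariantRecord",
    "read_fasta",
    "write_fasta",
    "read_placed_map",
    "write_placed_map",
    "read_gff3_genes",
    "write_gff3_genes",
    "read_go_map",
    "write_go_map",
    "attach_go_terms",
    "read_vcf",
    "classify_variant",
]

DNA_ALPHABET = frozenset("ACGTN")


class StrscapeWarning(UserWarning):
    """Warnings raised by strscape I/O and analysis routines."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on a named sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.seq_id}:{self.start}-{self.end} (need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class SequenceRecord:
    """One assembly sequence (contig/scaffold/linkage group)."""

    seq_id: str
    residues: str
    placed: Optional[bool] = None  # None = no placement information

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass
class GeneModel:
    """A gene with its merged CDS intervals and attached GO terms."""

    gene_id: str
    span: GenomicInterval
    cds: list[GenomicInterval] = field(default_factory=list)
    go_terms: set[str] = field(default_factory=set)

    @property
    def cds_length(self) -> int:
        return sum(iv.length for iv in self.cds)


@dataclass
class VariantRecord:
    """A called variant, post quality/depth filtering, one per alt allele."""

    seq_id: str
    pos: int  # 0-based position of the first ref base
    ref: str
    alt: str
    quality: float
    depth: int
    var_class: str  # SNP | MNP | INDEL | COMPLEX
    indel_size: int = 0


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path, placed_map: Optional[dict | str | Path] = None) -> list[SequenceRecord]:
    """Read a FASTA assembly into SequenceRecords.

    Residues are uppercased; characters outside {A,C,G,T,N} are mapped to N
    (one warning reports the total count). ``placed_map`` is either a dict
    or a path to a two-column TSV mapping seq_id to a placed flag.
    """
    path = Path(path)
    if isinstance(placed_map, (str, Path)):
        placed_map = read_placed_map(placed_map)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    n_unknown = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        residues = str(rec.seq).upper()
        bad = set(residues) - DNA_ALPHABET
        if bad:
            n_unknown += sum(residues.count(c) for c in bad)
            residues = "".join(c if c in DNA_ALPHABET else "N" for c in residues)
        placed = placed_map.get(rec.id) if placed_map is not None else None
        records.append(SequenceRecord(rec.id, residues, placed))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    if n_unknown:
        warnings.warn(
            f"{n_unknown} non-ACGTN characters mapped to N while reading {path}",
            StrscapeWarning,
            stacklevel=2,
        )
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.seq_id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def read_placed_map(path: str | Path) -> dict[str, bool]:
    """Two-column TSV: seq_id <tab> placed|unplaced (or true/false/1/0)."""
    truthy = {"placed", "true", "1", "yes"}
    falsy = {"unplaced", "false", "0", "no"}
    out: dict[str, bool] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            seq_id, flag = line.split("\t")[:2]
            flag = flag.lower()
            if flag in truthy:
                out[seq_id] = True
            elif flag in falsy:
                out[seq_id] = False
            else:
                raise ValueError(f"unrecognized placed flag {flag!r} for {seq_id}")
    return out


def write_placed_map(placed: dict[str, bool], path: str | Path) -> None:
    with open(path, "w") as fh:
        for seq_id, flag in placed.items():
            fh.write(f"{seq_id}\t{'placed' if flag else 'unplaced'}\n")


# ---------------------------------------------------------------------------
# GFF3 genes

def read_gff3_genes(path: str | Path) -> list[GeneModel]:
    """Read gene and CDS features from a GFF3 file.

    GFF3 1-based closed coordinates are converted to 0-based half-open.
    CDS features are assigned to their parent gene (directly or through an
    intermediate mRNA), sorted and overlap-merged. CDS features without a
    gene ancestor are skipped with a warning.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: dict[str, GeneModel] = {}
    for g in db.features_of_type("gene"):
        if g.end < g.start:
            raise ValueError(f"gene {g.id}: end < start in GFF3")
        span = GenomicInterval(g.seqid, g.start - 1, g.end, g.strand or ".")
        genes[g.id] = GeneModel(gene_id=g.id, span=span)
    raw_cds: dict[str, list[tuple[int, int]]] = {gid: [] for gid in genes}
    n_orphan = 0
    for c in db.features_of_type("CDS"):
        if c.end < c.start:
            raise ValueError(f"CDS at {c.seqid}:{c.start}: end < start in GFF3")
        parents = [p.id for p in db.parents(c.id, featuretype="gene")]
        if not parents:
            n_orphan += 1
            continue
        for gid in parents:
            raw_cds[gid].append((c.start - 1, c.end))
    if n_orphan:
        warnings.warn(
            f"{n_orphan} CDS features without a parent gene skipped in {path}",
            StrscapeWarning,
            stacklevel=2,
        )
    for gid, ivs in raw_cds.items():
        gene = genes[gid]
        gene.cds = [
            GenomicInterval(gene.span.seq_id, s, e, gene.span.strand)
            for s, e in merge(ivs)
        ]
    return list(genes.values())


def write_gff3_genes(genes: Iterable[GeneModel], path: str | Path, source: str = "strscape") -> None:
    """Write GeneModels back out as GFF3 (gene + CDS features)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            s = g.span
            fh.write(
                f"{s.seq_id}\t{source}\tgene\t{s.start + 1}\t{s.end}\t.\t{s.strand}\t.\tID={g.gene_id}\n"
            )
            for i, c in enumerate(g.cds):
                fh.write(
                    f"{c.seq_id}\t{source}\tCDS\t{c.start + 1}\t{c.end}\t.\t{c.strand}\t0\t"
                    f"ID={g.gene_id}.cds{i};Parent={g.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# GO maps

def read_go_map(path: str | Path) -> dict[str, set[str]]:
    """TSV of gene_id <tab> GO term, one pair per line."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            gene_id, term = line.split("\t")[:2]
            out.setdefault(gene_id, set()).add(term)
    return out


def write_go_map(go_map: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene_id in sorted(go_map):
            for term in sorted(go_map[gene_id]):
                fh.write(f"{gene_id}\t{term}\n")


def attach_go_terms(genes: Sequence[GeneModel], go_map: dict[str, set[str]]) -> None:
    for g in genes:
        g.go_terms = set(go_map.get(g.gene_id, set()))


# ---------------------------------------------------------------------------
# Variants

def classify_variant(ref: str, alt: str) -> tuple[str, int]:
    """Classify a ref/alt pair as SNP, MNP, INDEL or COMPLEX.

    Equal length 1 -> SNP; equal length > 1 -> MNP; one allele a strict
    prefix of the other (pure insertion/deletion) -> INDEL with signed size
    len(alt) - len(ref); anything else -> COMPLEX.
    """
    if not ref or not alt:
        raise ValueError("ref and alt must be non-empty")
    for s in (ref, alt):
        if set(s) - DNA_ALPHABET:
            raise ValueError(f"non-DNA characters in allele {s!r}")
    if len(ref) == len(alt):
        return ("SNP", 0) if len(ref) == 1 else ("MNP", 0)
    short, long_ = (ref, alt) if len(ref) < len(alt) else (alt, ref)
    if long_.startswith(short):
        return "INDEL", len(alt) - len(ref)
    return "COMPLEX", 0


def read_vcf(path: str | Path, min_quality: float = 20.0, min_depth: int = 5) -> list[VariantRecord]:
    """Read and filter a VCF.

    Only records with quality strictly greater than ``min_quality`` AND
    depth strictly greater than ``min_depth`` are retained. Multi-allelic
    records are split into one VariantRecord per alt allele. Depth is taken
    from INFO/DP, falling back to the summed per-sample FORMAT/DP.
    """
    out: list[VariantRecord] = []
    n_nodp = 0
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            depth = rec.info.get("DP")
            if depth is None:
                dps = [
                    s.get("DP")
                    for s in rec.samples.values()
                    if s.get("DP") is not None
                ]
                depth = sum(dps) if dps else None
            if depth is None:
                n_nodp += 1
                continue
            qual = rec.qual
            if qual is None or not (qual > min_quality and depth > min_depth):
                continue
            for alt in rec.alts or ():
                var_class, size = classify_variant(rec.ref, alt)
                out.append(
                    VariantRecord(
                        seq_id=rec.chrom,
                        pos=rec.start,
                        ref=rec.ref,
                        alt=alt,
                        quality=float(qual),
                        depth=int(depth),
                        var_class=var_class,
                        indel_size=size,
                    )
                )
    if n_nodp:
        warnings.warn(
            f"{n_nodp} VCF records without DP dropped from {path}",
            StrscapeWarning,
            stacklevel=2,
        )
    return out
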