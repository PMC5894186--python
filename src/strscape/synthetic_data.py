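"""Synthetic genomes with planted ground truth.

The generator emits everything the analysis stages consume — assembly
FASTA, gene models (GFF3), gene->GO map, variants (VCF), per-sequence
depth, and domain profiles — with every planted feature recorded, so the
whole pipeline can be validated against known truth without any external
data.

What is emulated, by stage:

* STR landscape: per-unit-size target densities (bp/Mbp), di-/tri-
  nucleotide dominated by default at codfish-like levels, planted as
  maximal perfect arrays into an otherwise STR-free background (accidental
  arrays are scrubbed by rejection), so detector recovery is exact.
* Gene/GO structure: genes with CDS exons; GO terms sampled over genes;
  designated terms multiply their genes' probability of carrying a CDS
  STR, which is precisely the quantity the Fisher tests measure.
* Heterozygous coding STRs: size-3 indels anchored inside trinucleotide
  arrays of a known subset of genes.
* Variant calls: per-class per-bp rates with a QUAL/DP mixture straddling
  the filtering thresholds.
* Multi-copy domain families: copies of a consensus domain (with
  configurable between-copy identity) on dedicated unplaced contigs, a
  configurable fraction pseudogenized by an internal stop, and assembly
  collapse simulated by emitting one contig for k copies with depth scaled
  by k.

Not emulated: read-level data (FASTQ), transposable elements, GC/coverage
biases, imperfect STRs, and linkage structure among variants.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pysam

from . import io_formats
from .domain_census import CODON_TO_AA, DomainProfile, write_profiles
from .io_formats import GeneModel, GenomicInterval, SequenceRecord
from .str_detection import (
    DEFAULT_MIN_LEN,
    STRLocus,
    _minimal_period,
    canonical_motif,
    find_strs,
    reverse_complement,
)
from .enrichment import GOCountTable

__all__ = [
    "DomainFamilyConfig",
    "SimulationConfig",
    "PlantedTruth",
    "simulate",
    "null_dataset",
    "simulate_go_counts",
    "DEFAULT_STR_SPECTRUM",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_AA_CODONS: dict[str, list[str]] = {}
for codon, aa in CODON_TO_AA.items():
    _AA_CODONS.setdefault(aa, []).append(codon)

# Codfish-like unit-size spectrum (bp/Mbp), dinucleotide dominated,
# totalling 96,364 bp/Mbp over the whole assembly.
DEFAULT_STR_SPECTRUM: dict[int, float] = {
    1: 4000,
    2: 55364,
    3: 20000,
    4: 8000,
    5: 4000,
    6: 3000,
    7: 1000,
    8: 500,
    9: 300,
    10: 200,
}


@dataclass
class DomainFamilyConfig:
    """One multi-copy domain family to plant."""

    name: str = "FISNA-like"
    n_copies: int = 10
    length_aa: int = 72
    pseudogene_fraction: float = 0.2
    collapse_multiplicities: list[int] = field(default_factory=list)
    identity: float = 0.95
    flank_bp: int = 1500


@dataclass
class SimulationConfig:
    seed: int = 0
    n_contigs: int = 8
    contig_length_bp: int = 250_000
    str_spectrum: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_STR_SPECTRUM)
    )
    n_genes: int = 300
    mean_cds_bp: int = 1200
    n_go_terms: int = 40
    genes_per_term: int = 25
    enriched_terms: dict[str, float] = field(
        default_factory=lambda: {"GO:SIM0001": 3.0, "GO:SIM0002": 3.0}
    )
    base_str_prob: float = 0.3
    tri_indel_fraction: float = 0.021
    domain_families: list[DomainFamilyConfig] = field(
        default_factory=lambda: [
            DomainFamilyConfig(
                name="FISNA-like",
                n_copies=10,
                length_aa=72,
                pseudogene_fraction=0.2,
                collapse_multiplicities=[3],
            ),
            DomainFamilyConfig(
                name="NACHT-like",
                n_copies=8,
                length_aa=166,
                pseudogene_fraction=0.25,
                collapse_multiplicities=[],
            ),
        ]
    )
    variant_rates: dict[str, float] = field(
        default_factory=lambda: {
            "SNP": 5.4e-3,
            "MNP": 0.2e-3,
            "INDEL": 1.6e-3,
            "COMPLEX": 0.5e-3,
        }
    )
    base_depth: float = 30.0
    depth_format: str = "summary"  # or "per-base"
    fail_quality_fraction: float = 0.2
    fail_depth_fraction: float = 0.1


@dataclass
class PlantedTruth:
    """Everything the generator planted, in analysis-ready form."""

    records: list[SequenceRecord]
    genes: list[GeneModel]
    loci: list[STRLocus]
    gene_flags: dict[str, dict[str, bool]]  # gene -> {has_str, has_tri_indel}
    term_effects: dict[str, float]
    domain_loci: list[dict]  # seq_id/start/end/strand/family/pseudogene/copies
    contig_multiplier: dict[str, int]
    placed: dict[str, bool]
    variants: list[dict]  # all emitted VCF records with qual/depth/class
    assembly_bp: int
    config: SimulationConfig

    @property
    def genes_with_str(self) -> set[str]:
        return {g for g, f in self.gene_flags.items() if f["has_str"]}

    @property
    def genes_with_tri_indel(self) -> set[str]:
        return {g for g, f in self.gene_flags.items() if f["has_tri_indel"]}


# ---------------------------------------------------------------------------
# Helpers

def _random_bases(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, n)]


def _scrub_contig(buf: np.ndarray, seq_id: str, rng: np.random.Generator,
                  protected: Sequence[tuple[int, int]] = (), max_iter: int = 40) -> None:
    """Rewrite background bases until no accidental STR array remains.

    ``protected`` intervals (planted arrays, domain DNA) are never
    rewritten; any detected locus that is not exactly a protected interval
    has its unprotected bases re-randomized.
    """
    protected = sorted(protected)
    prot_set = set(protected)
    for _ in range(max_iter):
        rec = SequenceRecord(seq_id, buf.tobytes().decode("ascii"))
        dirty = False
        for locus in find_strs(rec):
            key = (locus.start, locus.end)
            if key in prot_set:
                continue
            pos = [
                p
                for p in range(locus.start, locus.end)
                if not any(s <= p < e for s, e in protected)
            ]
            if not pos:
                continue  # fully inside protected space; leave alone
            buf[pos] = _random_bases(rng, len(pos))
            dirty = True
        if not dirty:
            return
    raise RuntimeError(f"could not scrub accidental STRs from {seq_id}")


def _random_unit(rng: np.random.Generator, u: int) -> str:
    """Random motif of length u whose minimal period is exactly u."""
    while True:
        unit = "".join("ACGT"[i] for i in rng.integers(0, 4, u))
        if u == 1 or _minimal_period(unit, u) == u:
            return unit


def _array_string(unit: str, length: int) -> str:
    reps = -(-length // len(unit))
    return (unit * reps)[:length]


def _write_array(buf: np.ndarray, start: int, array: str, u: int,
                 rng: np.random.Generator) -> None:
    """Write a tandem array and pick flank guard bases that stop extension."""
    end = start + len(array)
    buf[start:end] = np.frombuffer(array.encode(), dtype=np.uint8)
    if start > 0:
        ext = buf[start - 1 + u] if start - 1 + u < len(buf) else None
        choices = [b for b in _BASES if b != ext]
        buf[start - 1] = choices[rng.integers(0, len(choices))]
    if end < len(buf):
        ext = buf[end - u]
        choices = [b for b in _BASES if b != ext]
        buf[end] = choices[rng.integers(0, len(choices))]


class _FreeSpace:
    """Random placement of non-overlapping features with guard gaps."""

    def __init__(self, rng: np.random.Generator, guard: int = 6):
        self.rng = rng
        self.guard = guard
        self.free: list[tuple[str, int, int]] = []

    def add(self, seq_id: str, start: int, end: int) -> None:
        if end - start > 2 * self.guard:
            self.free.append((seq_id, start, end))

    def allocate(self, length: int) -> tuple[str, int]:
        need = length + 2 * self.guard
        # rejection-sample a free interval; full scan only as a fallback
        i = -1
        for _ in range(64):
            j = int(self.rng.integers(0, len(self.free))) if self.free else -1
            if j >= 0 and self.free[j][2] - self.free[j][1] >= need:
                i = j
                break
        if i < 0:
            fits = [k for k, (_, s, e) in enumerate(self.free) if e - s >= need]
            if not fits:
                raise RuntimeError(
                    "requested feature density infeasible for the configured contig space"
                )
            i = fits[int(self.rng.integers(0, len(fits)))]
        seq_id, s, e = self.free[i]
        self.free[i] = self.free[-1]  # swap-remove: order is irrelevant
        self.free.pop()
        off = int(self.rng.integers(s + self.guard, e - self.guard - length + 1))
        self.add(seq_id, s, off - self.guard)
        self.add(seq_id, off + length + self.guard, e)
        return seq_id, off


def _codons_for(protein: str, rng: np.random.Generator) -> str:
    return "".join(
        _AA_CODONS[aa][rng.integers(0, len(_AA_CODONS[aa]))] for aa in protein
    )


def _clean_domain_dna(protein: str, rng: np.random.Generator, max_iter: int = 60) -> str:
    """Synonymous-codon choices resampled until the DNA carries no STR."""
    for _ in range(max_iter):
        dna = _codons_for(protein, rng)
        if not find_strs(SequenceRecord("_", dna)):
            return dna
    raise RuntimeError("could not encode domain without accidental STRs")


# ---------------------------------------------------------------------------
# Main generator

def simulate(config: SimulationConfig, out_dir: str | Path) -> PlantedTruth:
    """Generate a synthetic dataset with planted truth; write all files.

    Outputs in ``out_dir``: assembly.fasta, placed.tsv, genes.gff3,
    go_terms.tsv, variants.vcf, depth.tsv, profiles.txt, truth.json. The
    seed in the config fully determines every byte written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    for u, dens in config.str_spectrum.items():
        if dens > 1e6:
            raise ValueError(f"density {dens} bp/Mbp for unit {u} exceeds 1e6")

    # 1. background contigs (placed), initially STR-free
    buffers: dict[str, np.ndarray] = {}
    placed: dict[str, bool] = {}
    background_ids = []
    for i in range(config.n_contigs):
        seq_id = f"ctg{i + 1:03d}"
        buf = _random_bases(rng, config.contig_length_bp).copy()
        _scrub_contig(buf, seq_id, rng)
        buffers[seq_id] = buf
        placed[seq_id] = True
        background_ids.append(seq_id)

    # 2. domain families: profiles + dedicated unplaced contigs
    profiles: list[DomainProfile] = []
    domain_loci: list[dict] = []
    contig_multiplier: dict[str, int] = {s: 1 for s in buffers}
    protected: dict[str, list[tuple[int, int]]] = {s: [] for s in buffers}
    for fam in config.domain_families:
        consensus = "".join(
            "ACDEFGHIKLMNPQRSTVWY"[i] for i in rng.integers(0, 20, fam.length_aa)
        )
        profiles.append(DomainProfile.from_consensus(fam.name, consensus))
        n_pseudo = round(fam.pseudogene_fraction * fam.n_copies)
        remaining = fam.n_copies
        emitted: list[tuple[int, bool]] = []  # (copies represented, pseudo)
        for k in fam.collapse_multiplicities:
            if k > remaining:
                raise ValueError("collapse multiplicities exceed n_copies")
            emitted.append((k, False))
            remaining -= k
        emitted.extend((1, False) for _ in range(remaining))
        # pseudogenize single-copy loci (collapsed contigs stay intact)
        singles = [i for i, (k, _) in enumerate(emitted) if k == 1]
        if n_pseudo > len(singles):
            raise ValueError("pseudogene fraction too high for collapse layout")
        for i in singles[:n_pseudo]:
            emitted[i] = (1, True)
        n_mut = round((1 - fam.identity) * fam.length_aa)
        for j, (k, pseudo) in enumerate(emitted):
            protein = list(consensus)
            for p in rng.choice(fam.length_aa, size=n_mut, replace=False):
                alts = [a for a in "ACDEFGHIKLMNPQRSTVWY" if a != protein[p]]
                protein[p] = alts[rng.integers(0, len(alts))]
            if pseudo:
                protein[fam.length_aa // 2] = "*"
            dna = _clean_domain_dna("".join(protein), rng)
            seq_id = f"{fam.name}_ctg{j + 1:02d}"
            flank = int(rng.integers(fam.flank_bp // 2, fam.flank_bp))
            flank2 = int(rng.integers(fam.flank_bp // 2, fam.flank_bp))
            buf = np.empty(flank + len(dna) + flank2, dtype=np.uint8)
            buf[:flank] = _random_bases(rng, flank)
            buf[flank + len(dna):] = _random_bases(rng, flank2)
            strand = "+" if rng.random() < 0.5 else "-"
            ins = dna if strand == "+" else reverse_complement(dna)
            buf[flank : flank + len(dna)] = np.frombuffer(ins.encode(), np.uint8)
            prot_iv = (flank, flank + len(dna))
            _scrub_contig(buf, seq_id, rng, protected=[prot_iv])
            buffers[seq_id] = buf
            placed[seq_id] = False
            protected[seq_id] = [prot_iv]
            contig_multiplier[seq_id] = k
            domain_loci.append(
                {
                    "seq_id": seq_id,
                    "start": prot_iv[0],
                    "end": prot_iv[1],
                    "strand": strand,
                    "family": fam.name,
                    "pseudogene": pseudo,
                    "copies": k,
                }
            )

    assembly_bp = sum(len(b) for b in buffers.values())

    # 3. genes placed into background contigs
    space = _FreeSpace(rng, guard=10)
    for seq_id in background_ids:
        space.add(seq_id, 0, len(buffers[seq_id]))
    genes: list[GeneModel] = []
    for i in range(config.n_genes):
        cds_total = max(300, int(rng.normal(config.mean_cds_bp, 0.2 * config.mean_cds_bp)))
        cds_total -= cds_total % 3
        n_exons = int(rng.integers(1, 4))
        cuts = np.sort(rng.choice(np.arange(1, cds_total // 3), n_exons - 1, replace=False)) * 3 if n_exons > 1 else np.array([], dtype=int)
        exon_lens = np.diff(np.concatenate([[0], cuts, [cds_total]])).astype(int)
        intron_lens = rng.integers(100, 500, n_exons - 1) if n_exons > 1 else np.array([], dtype=int)
        span_len = int(exon_lens.sum() + intron_lens.sum())
        seq_id, start = space.allocate(span_len)
        gene_id = f"gene{i + 1:05d}"
        cds = []
        cursor = start
        for e in range(n_exons):
            cds.append(GenomicInterval(seq_id, cursor, cursor + int(exon_lens[e]), "+"))
            cursor += int(exon_lens[e])
            if e < n_exons - 1:
                cursor += int(intron_lens[e])
        genes.append(
            GeneModel(
                gene_id=gene_id,
                span=GenomicInterval(seq_id, start, start + span_len, "+"),
                cds=cds,
            )
        )

    # 4. GO terms and per-gene STR probabilities
    gene_ids = [g.gene_id for g in genes]
    go_map: dict[str, set[str]] = {gid: set() for gid in gene_ids}
    term_effects: dict[str, float] = {}
    for t in range(config.n_go_terms):
        term = f"GO:SIM{t + 1:04d}"
        members = rng.choice(gene_ids, size=min(config.genes_per_term, len(gene_ids)), replace=False)
        for gid in members:
            go_map[gid].add(term)
        term_effects[term] = float(config.enriched_terms.get(term, 1.0))
    for term, mult in config.enriched_terms.items():
        if term not in term_effects:
            raise ValueError(f"enriched term {term} not among simulated terms")
        term_effects[term] = float(mult)

    # 5. plant CDS STRs per gene flag; force u=3 for tri-indel genes
    min_len = dict(DEFAULT_MIN_LEN)
    gene_flags: dict[str, dict[str, bool]] = {}
    loci: list[STRLocus] = []
    in_gene_bp: dict[int, int] = {u: 0 for u in config.str_spectrum}
    gene_by_id = {g.gene_id: g for g in genes}
    effects = {
        gid: float(np.prod([term_effects[t] for t in go_map[gid]])) if go_map[gid] else 1.0
        for gid in gene_ids
    }
    has_str = {
        gid: bool(rng.random() < min(0.95, config.base_str_prob * effects[gid]))
        for gid in gene_ids
    }
    str_gene_ids = [g for g in gene_ids if has_str[g]]
    n_tri = round(config.tri_indel_fraction * config.n_genes)
    if n_tri > len(str_gene_ids):
        n_tri = len(str_gene_ids)
    tri_gene_ids = set(
        rng.choice(str_gene_ids, size=n_tri, replace=False) if n_tri else []
    )
    tri_arrays: dict[str, STRLocus] = {}
    for gid in gene_ids:
        gene_flags[gid] = {"has_str": has_str[gid], "has_tri_indel": gid in tri_gene_ids}
        if not has_str[gid]:
            continue
        gene = gene_by_id[gid]
        u = 3 if gid in tri_gene_ids else int(rng.choice([2, 3]))
        exons = [c for c in gene.cds if c.length >= min_len[u] + 20]
        exon = exons[rng.integers(0, len(exons))] if exons else max(gene.cds, key=lambda c: c.length)
        arr_len = min_len[u] + int(rng.integers(0, u * 4))
        arr_len = min(arr_len, exon.length - 10)
        start = int(rng.integers(exon.start + 4, exon.end - arr_len - 4))
        unit = _random_unit(rng, u)
        buf = buffers[gene.span.seq_id]
        _write_array(buf, start, _array_string(unit, arr_len), u, rng)
        locus = STRLocus(
            seq_id=gene.span.seq_id,
            interval=GenomicInterval(gene.span.seq_id, start, start + arr_len),
            unit_size=u,
            motif=canonical_motif(unit),
            copy_number=arr_len / u,
        )
        loci.append(locus)
        protected[gene.span.seq_id].append((start, start + arr_len))
        in_gene_bp[u] = in_gene_bp.get(u, 0) + arr_len
        if gid in tri_gene_ids:
            tri_arrays[gid] = locus

    # 6. intergenic fill to the per-u density targets
    # gene spans leave the free pool so the genes-with-STR truth stays exact
    space2 = _FreeSpace(rng, guard=6)
    gene_spans: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        gene_spans.setdefault(g.span.seq_id, []).append((g.span.start - 10, g.span.end + 10))
    for seq_id, buf in buffers.items():
        blocked = sorted(gene_spans.get(seq_id, []) + protected[seq_id])
        cursor = 0
        for s, e in blocked:
            space2.add(seq_id, cursor, max(cursor, s))
            cursor = max(cursor, e)
        space2.add(seq_id, cursor, len(buf))
    genome_mbp = assembly_bp / 1e6
    for u in sorted(config.str_spectrum):
        target_bp = int(round(config.str_spectrum[u] * genome_mbp))
        rem = target_bp - in_gene_bp.get(u, 0)
        if rem < 0:
            warnings.warn(
                f"in-gene STR bp exceeds the u={u} density target; skipping fill",
                io_formats.StrscapeWarning,
            )
            continue
        lengths: list[int] = []
        while rem >= min_len[u]:
            arr_len = min_len[u] + int(rng.geometric(0.12)) - 1
            if rem - arr_len < min_len[u]:
                arr_len = rem
            lengths.append(arr_len)
            rem -= arr_len
        if rem > 0:
            if lengths:
                lengths[-1] += rem
            elif target_bp > 0:
                warnings.warn(
                    f"u={u} density target smaller than one minimal array; skipped",
                    io_formats.StrscapeWarning,
                )
        for arr_len in lengths:
            seq_id, start = space2.allocate(arr_len)
            unit = _random_unit(rng, u)
            _write_array(buffers[seq_id], start, _array_string(unit, arr_len), u, rng)
            loci.append(
                STRLocus(
                    seq_id=seq_id,
                    interval=GenomicInterval(seq_id, start, start + arr_len),
                    unit_size=u,
                    motif=canonical_motif(unit),
                    copy_number=arr_len / u,
                )
            )
            protected[seq_id].append((start, start + arr_len))

    # 7. final scrub + planted-truth verification
    planted_by_seq: dict[str, set[tuple[int, int, int]]] = {}
    for l in loci:
        planted_by_seq.setdefault(l.seq_id, set()).add((l.start, l.end, l.unit_size))
    for seq_id, buf in buffers.items():
        _scrub_contig(buf, seq_id, rng, protected=sorted(protected[seq_id]))
        rec = SequenceRecord(seq_id, buf.tobytes().decode("ascii"))
        found = {(l.start, l.end, l.unit_size) for l in find_strs(rec)}
        if found != planted_by_seq.get(seq_id, set()):
            raise RuntimeError(f"planted truth verification failed on {seq_id}")

    records = [
        SequenceRecord(seq_id, buf.tobytes().decode("ascii"), placed[seq_id])
        for seq_id, buf in buffers.items()
    ]
    rec_by_id = {r.seq_id: r for r in records}

    # 8. variants (background indel sizes exclude |3| so the planted
    # tri-indel truth stays exact)
    variants: list[dict] = []

    def qual_depth() -> tuple[float, int]:
        if rng.random() < config.fail_quality_fraction:
            q = float(rng.uniform(0, 20))
        else:
            q = float(rng.uniform(20.5, 60))
        if rng.random() < config.fail_depth_fraction:
            d = int(rng.integers(0, 6))
        else:
            d = max(6, int(rng.poisson(config.base_depth)))
        return q, d

    seq_ids = list(buffers)
    seq_weights = np.array([len(buffers[s]) for s in seq_ids], dtype=float)
    seq_weights /= seq_weights.sum()

    def random_site(margin: int) -> tuple[str, int]:
        seq_id = seq_ids[rng.choice(len(seq_ids), p=seq_weights)]
        pos = int(rng.integers(1, len(buffers[seq_id]) - margin))
        return seq_id, pos

    for cls, rate in config.variant_rates.items():
        n = int(round(rate * assembly_bp))
        for _ in range(n):
            seq_id, pos = random_site(12)
            s = rec_by_id[seq_id].residues
            if cls == "SNP":
                ref = s[pos]
                alt = "ACGT"[rng.integers(0, 4)]
                while alt == ref:
                    alt = "ACGT"[rng.integers(0, 4)]
            elif cls == "MNP":
                k = int(rng.integers(2, 4))
                ref = s[pos : pos + k]
                alt = "".join(
                    "ACGT"[(("ACGT".index(c)) + 1 + rng.integers(0, 3)) % 4] for c in ref
                )
            elif cls == "INDEL":
                size = int(rng.choice([1, 2, 4, 5]))  # |3| reserved for planted tri-indels
                if rng.random() < 0.5:
                    ref = s[pos]
                    alt = ref + "".join("ACGT"[i] for i in rng.integers(0, 4, size))
                else:
                    ref = s[pos : pos + size + 1]
                    alt = s[pos]
            elif cls == "COMPLEX":
                ref = s[pos : pos + 2]
                alt = "".join("ACGT"[i] for i in rng.integers(0, 4, 4))
                while alt.startswith(ref):
                    alt = "".join("ACGT"[i] for i in rng.integers(0, 4, 4))
            else:
                raise ValueError(f"unknown variant class {cls!r}")
            q, d = qual_depth()
            variants.append(
                {"seq_id": seq_id, "pos": pos, "ref": ref, "alt": alt,
                 "qual": q, "depth": d, "class": cls}
            )
    # planted size-3 indels inside trinucleotide gene arrays, always passing
    for gid in sorted(tri_gene_ids):
        l = tri_arrays[gid]
        s = rec_by_id[l.seq_id].residues
        pos = l.start  # anchor pos+1 lies inside the array
        ref = s[pos]
        if rng.random() < 0.5:
            alt = ref + s[pos + 1 : pos + 4]  # duplicate one unit: +3 insertion
        else:
            ref = s[pos : pos + 4]
            alt = s[pos]
        variants.append(
            {"seq_id": l.seq_id, "pos": pos, "ref": ref, "alt": alt,
             "qual": float(rng.uniform(30, 60)), "depth": max(10, int(rng.poisson(config.base_depth))),
             "class": "INDEL"}
        )
    variants.sort(key=lambda v: (v["seq_id"], v["pos"]))

    # 9. depth table
    depth_rows = []
    for seq_id in seq_ids:
        n_bp = len(buffers[seq_id])
        lam = config.base_depth * contig_multiplier[seq_id]
        if config.depth_format == "per-base":
            depths = rng.poisson(lam, n_bp)
            for i, dp in enumerate(depths):
                depth_rows.append(f"{seq_id}\t{i + 1}\t{int(dp)}")
        else:
            mean = rng.poisson(lam * n_bp) / n_bp
            depth_rows.append(f"{seq_id}\t{mean:.6f}\t{n_bp}")

    # 10. write everything
    io_formats.write_fasta(records, out_dir / "assembly.fasta")
    io_formats.write_placed_map(placed, out_dir / "placed.tsv")
    io_formats.write_gff3_genes(genes, out_dir / "genes.gff3")
    io_formats.write_go_map(go_map, out_dir / "go_terms.tsv")
    _write_vcf(variants, records, out_dir / "variants.vcf")
    (out_dir / "depth.tsv").write_text("\n".join(depth_rows) + "\n" if depth_rows else "")
    write_profiles(profiles, out_dir / "profiles.txt")
    truth = PlantedTruth(
        records=records,
        genes=genes,
        loci=sorted(loci, key=lambda l: (l.seq_id, l.start)),
        gene_flags=gene_flags,
        term_effects=term_effects,
        domain_loci=domain_loci,
        contig_multiplier=contig_multiplier,
        placed=placed,
        variants=variants,
        assembly_bp=assembly_bp,
        config=config,
    )
    _write_truth_json(truth, out_dir / "truth.json")
    return truth


def _write_vcf(variants: list[dict], records: list[SequenceRecord], path: Path) -> None:
    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">')
    for r in records:
        header.contigs.add(r.seq_id, length=r.length)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for v in variants:
            rec = vf.new_record(
                contig=v["seq_id"],
                start=v["pos"],
                alleles=(v["ref"], v["alt"]),
                qual=v["qual"],
            )
            rec.info["DP"] = v["depth"]
            vf.write(rec)


def _write_truth_json(truth: PlantedTruth, path: Path) -> None:
    payload = {
        "assembly_bp": truth.assembly_bp,
        "loci": [
            {
                "seq_id": l.seq_id,
                "start": l.start,
                "end": l.end,
                "unit_size": l.unit_size,
                "motif": l.motif,
            }
            for l in truth.loci
        ],
        "gene_flags": truth.gene_flags,
        "term_effects": truth.term_effects,
        "domain_loci": truth.domain_loci,
        "contig_multiplier": truth.contig_multiplier,
        "variants": truth.variants,
        "config": asdict(truth.config),
    }
    path.write_text(json.dumps(payload, indent=1))


def null_dataset(config: SimulationConfig, out_dir: str | Path) -> PlantedTruth:
    """Simulate with all enrichment effect sizes zeroed (type-I harness)."""
    import copy

    cfg = copy.deepcopy(config)
    cfg.enriched_terms = {}
    return simulate(cfg, out_dir)


# ---------------------------------------------------------------------------
# Count-level GO simulation (for enrichment power / null calibration)

def simulate_go_counts(
    rng: np.random.Generator,
    species_effects: dict[str, dict[str, float]],
    n_terms: int = 510,
    genes_per_term: int = 200,
    base_p: float = 0.1,
) -> tuple[list[GOCountTable], set[str]]:
    """Per-species GO count tables with designated effect terms.

    Each term annotates ``genes_per_term`` genes per species; each gene
    carries an STR with probability base_p x the species' effect multiplier
    for that term (1.0 where unspecified). Returns the tables plus the set
    of terms where any species' multiplier differs from 1.
    """
    terms = [f"GO:SIM{t + 1:04d}" for t in range(n_terms)]
    tables = []
    for species, effects in species_effects.items():
        counts = {}
        for term in terms:
            p = min(1.0, base_p * effects.get(term, 1.0))
            n_with = int(rng.binomial(genes_per_term, p))
            counts[term] = (n_with, genes_per_term - n_with)
        tables.append(GOCountTable(species, counts))
    truly_different = {
        t
        for t in terms
        if len({e.get(t, 1.0) for e in species_effects.values()}) > 1
    }
    return tables, truly_different
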