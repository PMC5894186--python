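"""Six-frame translation and ungapped profile search for multi-copy
gene-family censuses (NLR-, MHCI-, TLR-style families).

A domain profile is an ungapped position-specific scoring matrix over the
20 amino acids plus the stop symbol '*'. Stops carry a large negative
score so a strong hit can span an internal stop codon and be flagged as a
putative pseudogene rather than lost. For each alignment diagonal the
best-scoring contiguous run of profile columns (an ungapped local segment)
is taken; coverage is that run's column count divided by the profile
length, which places truncated copies in the expected coverage bins.

Hits from the six frames are back-projected to genomic coordinates and
deduplicated (>= 50% reciprocal overlap keeps the best-scoring hit), since
near-identical copies are otherwise recounted across frames.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .io_formats import GenomicInterval, SequenceRecord, StrscapeWarning
from .str_detection import reverse_complement

__all__ = [
    "AA_ALPHABET",
    "DomainProfile",
    "DomainHit",
    "CensusReport",
    "six_frame_translate",
    "translate_frame",
    "profile_scan",
    "census",
    "classify_copy_completeness",
    "classify_mhc_region",
    "mhc_region_census",
    "read_profiles",
    "write_profile",
    "write_profiles",
]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY*"
_AA_INDEX = {c: i for i, c in enumerate(AA_ALPHABET)}
STOP_SCORE = -8.0  # default per-column bit score for '*'
UNKNOWN_SCORE = -1.0  # per-column score for residues outside the alphabet (X)

_table = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_table.forward_table)
CODON_TO_AA.update({c: "*" for c in _table.stop_codons})


@dataclass
class DomainProfile:
    """Ungapped log-odds profile: L columns x 21 symbols (20 aa + stop)."""

    name: str
    scores: np.ndarray  # (L, 21) float
    bit_threshold: float
    consensus: str

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != len(AA_ALPHABET):
            raise ValueError("scores must be an (L, 21) matrix")
        if self.length < 10:
            raise ValueError("profiles must have at least 10 columns")
        if not np.isfinite(self.scores.max(axis=1)).all():
            raise ValueError("every column needs a finite maximum score")

    @property
    def length(self) -> int:
        return self.scores.shape[0]

    @classmethod
    def from_consensus(
        cls,
        name: str,
        consensus: str,
        match: float = 2.0,
        mismatch: float = -1.0,
        stop: float = STOP_SCORE,
        bit_threshold: Optional[float] = None,
    ) -> "DomainProfile":
        """Build a simple match/mismatch profile around a consensus protein.

        The default threshold, 40% of the maximum attainable score, tolerates
        roughly 20% consensus mismatches plus one internal stop.
        """
        L = len(consensus)
        scores = np.full((L, len(AA_ALPHABET)), mismatch, dtype=float)
        scores[:, _AA_INDEX["*"]] = stop
        for i, aa in enumerate(consensus):
            scores[i, _AA_INDEX[aa]] = match
        if bit_threshold is None:
            bit_threshold = 0.4 * match * L
        return cls(name=name, scores=scores, bit_threshold=bit_threshold, consensus=consensus)


@dataclass
class DomainHit:
    seq_id: str
    frame: int  # one of +1, +2, +3, -1, -2, -3
    protein_interval: tuple[int, int]  # [start, end) in frame coordinates
    genomic_interval: GenomicInterval
    coverage: float  # aligned profile columns / L
    score: float
    has_internal_stop: bool
    profile: str = ""


@dataclass
class CensusReport:
    """Per-profile hit tallies (Table-5-style bins, placed/unplaced split)."""

    table: pd.DataFrame  # indexed by profile name
    hits: list[DomainHit] = field(default_factory=list)
    raw_hits: list[DomainHit] = field(default_factory=list)

    def per_sequence_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for h in self.hits:
            out[h.seq_id] = out.get(h.seq_id, 0) + 1
        return out


# ---------------------------------------------------------------------------
# Translation

def translate_frame(seq: str, frame: int) -> str:
    """Translate one frame; stops rendered '*', codons containing N -> 'X'."""
    if frame not in (1, 2, 3, -1, -2, -3):
        raise ValueError(f"invalid frame {frame}")
    s = seq if frame > 0 else reverse_complement(seq)
    off = abs(frame) - 1
    out = []
    for i in range(off, len(s) - 2, 3):
        codon = s[i : i + 3]
        aa = CODON_TO_AA.get(codon)
        out.append(aa if aa is not None else "X")
    return "".join(out)


def six_frame_translate(seq: SequenceRecord) -> dict[int, str]:
    """All six conceptual translations, keyed by frame (+1..+3, -1..-3)."""
    if seq.length < 3:
        warnings.warn(
            f"sequence {seq.seq_id} shorter than one codon; empty translations",
            StrscapeWarning,
            stacklevel=2,
        )
        return {f: "" for f in (1, 2, 3, -1, -2, -3)}
    return {f: translate_frame(seq.residues, f) for f in (1, 2, 3, -1, -2, -3)}


# ---------------------------------------------------------------------------
# Profile scan

_ENCODE_TABLE = np.full(256, -1, dtype=np.int64)
for _c, _i in _AA_INDEX.items():
    _ENCODE_TABLE[ord(_c)] = _i


def _encode_protein(protein: str) -> np.ndarray:
    return _ENCODE_TABLE[np.frombuffer(protein.encode("ascii"), dtype=np.uint8)]


def _segment_from_diagonal(d: np.ndarray) -> tuple[float, int, int]:
    """Kadane max-subarray with indices over one diagonal's column scores."""
    best, best_s, best_e = -np.inf, 0, 0
    run, run_s = 0.0, 0
    for i, x in enumerate(d):
        if run <= 0:
            run, run_s = x, i
        else:
            run += x
        if run > best:
            best, best_s, best_e = run, run_s, i + 1
    return best, best_s, best_e


def profile_scan(
    protein: str,
    profile: DomainProfile,
    bit_threshold: Optional[float] = None,
) -> list[DomainHit]:
    """Ungapped scan of one translated frame against a profile.

    Every alignment diagonal (the profile may overhang either sequence end)
    is scored column-by-column; the diagonal's best contiguous column run
    is a candidate hit with score = run sum and coverage = run length / L.
    Candidates above the bit threshold are kept greedily best-score-first,
    discarding ones overlapping an already-kept hit on the protein.

    Returned hits are frame-local: seq_id/frame/genomic fields are filled
    in by :func:`census`.
    """
    threshold = profile.bit_threshold if bit_threshold is None else bit_threshold
    L = profile.length
    n = len(protein)
    if n == 0:
        return []
    enc = _encode_protein(protein)
    S = profile.scores.astype(np.float32)
    # Sp[i, j] = score of profile column i against protein residue j
    Sp = np.where(
        enc >= 0, S[:, np.clip(enc, 0, len(AA_ALPHABET) - 1)], np.float32(UNKNOWN_SCORE)
    )
    offsets = np.arange(-(L - 1), n)
    candidates: list[tuple[float, int, int, int]] = []  # score, pstart, pend, cols
    chunk = 16384
    # pad with sentinel columns so every diagonal gather stays in bounds
    SpPad = np.full((L, n + 2 * (L - 1)), np.float32(-1e6))
    SpPad[:, L - 1 : L - 1 + n] = Sp
    for c0 in range(0, offsets.size, chunk):
        offs = offsets[c0 : c0 + chunk]
        base = offs + (L - 1)
        D = np.empty((offs.size, L), dtype=np.float32)
        for i in range(L):
            D[:, i] = SpPad[i, base + i]
        cs = np.cumsum(D, axis=1)
        prev = np.concatenate([np.zeros((D.shape[0], 1)), cs[:, :-1]], axis=1)
        best = (cs - np.minimum.accumulate(prev, axis=1)).max(axis=1)
        # overhang rows carry -1e6 sentinels that inflate the prescreen, so
        # the exact Kadane score is re-checked against the threshold
        for k in np.flatnonzero(best >= threshold):
            score, cstart, cend = _segment_from_diagonal(D[k])
            if score < threshold:
                continue
            o = int(offs[k])
            candidates.append((float(score), o + cstart, o + cend, cend - cstart))
    # greedy non-overlap selection, best score first
    candidates.sort(key=lambda t: (-t[0], t[1]))
    kept: list[tuple[float, int, int, int]] = []
    for cand in candidates:
        if all(cand[2] <= k[1] or cand[1] >= k[2] for k in kept):
            kept.append(cand)
    hits = []
    for score, ps, pe, ncols in sorted(kept, key=lambda t: t[1]):
        segment = protein[ps:pe]
        hits.append(
            DomainHit(
                seq_id="",
                frame=0,
                protein_interval=(ps, pe),
                genomic_interval=GenomicInterval("_", 0, 3),  # placeholder
                coverage=ncols / L,
                score=score,
                has_internal_stop="*" in segment,
                profile=profile.name,
            )
        )
    return hits


def _backproject(frame: int, protein_interval: tuple[int, int], seq_len: int, seq_id: str) -> GenomicInterval:
    off = abs(frame) - 1
    ps, pe = protein_interval
    s, e = off + 3 * ps, off + 3 * pe
    if frame > 0:
        return GenomicInterval(seq_id, s, e, "+")
    return GenomicInterval(seq_id, seq_len - e, seq_len - s, "-")


def _reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    if a.seq_id != b.seq_id:
        return 0.0
    ov = min(a.end, b.end) - max(a.start, b.start)
    if ov <= 0:
        return 0.0
    return min(ov / a.length, ov / b.length)


def _dedup_hits(hits: list[DomainHit], min_reciprocal: float = 0.5) -> list[DomainHit]:
    """Keep the best-scoring hit among groups overlapping >= 50% reciprocally."""
    out: list[DomainHit] = []
    for h in sorted(hits, key=lambda h: -h.score):
        if all(
            _reciprocal_overlap(h.genomic_interval, k.genomic_interval) < min_reciprocal
            for k in out
        ):
            out.append(h)
    return out


def census(
    assembly: Sequence[SequenceRecord],
    profiles: Sequence[DomainProfile],
    placed_map: Optional[Mapping[str, bool]] = None,
    coverage_bins: tuple[float, float] = (0.5, 0.75),
) -> CensusReport:
    """Domain census over all six frames of an assembly.

    Per profile the report counts deduplicated hits in total, above each
    coverage bin (>50%, >75% of the domain length), stop-flagged hits in
    the top bin, and the placed/unplaced split. Raw (pre-deduplication)
    per-frame hits are kept alongside for comparability with pipelines that
    count frame hits directly.
    """
    lo, hi = coverage_bins
    raw: list[DomainHit] = []
    for rec in assembly:
        frames = six_frame_translate(rec) if rec.length >= 3 else {}
        for frame, protein in frames.items():
            for prof in profiles:
                for h in profile_scan(protein, prof):
                    h.seq_id = rec.seq_id
                    h.frame = frame
                    h.genomic_interval = _backproject(
                        frame, h.protein_interval, rec.length, rec.seq_id
                    )
                    raw.append(h)
    unknown_placed: set[str] = set()

    def is_placed(seq_id: str) -> bool:
        if placed_map is None:
            return False
        if seq_id not in placed_map:
            unknown_placed.add(seq_id)
            return False
        return bool(placed_map[seq_id])

    rows = []
    deduped: list[DomainHit] = []
    for prof in profiles:
        mine = [h for h in raw if h.profile == prof.name]
        kept = _dedup_hits(mine)
        deduped.extend(kept)
        n_all = len(kept)
        n_gt50 = sum(1 for h in kept if h.coverage > lo)
        n_gt75 = sum(1 for h in kept if h.coverage > hi)
        n_stop = sum(1 for h in kept if h.coverage > hi and h.has_internal_stop)
        n_placed = sum(1 for h in kept if is_placed(h.seq_id))
        rows.append(
            {
                "profile": prof.name,
                "n_all": n_all,
                "n_gt50": n_gt50,
                "n_gt75": n_gt75,
                "n_gt75_with_stops": n_stop,
                "n_placed": n_placed,
                "n_unplaced": n_all - n_placed,
                "n_raw": len(mine),
            }
        )
    if unknown_placed and placed_map is not None:
        warnings.warn(
            f"{len(unknown_placed)} sequence ids missing from placed map; treated unplaced",
            StrscapeWarning,
            stacklevel=2,
        )
    table = pd.DataFrame(rows).set_index("profile") if rows else pd.DataFrame()
    deduped.sort(key=lambda h: (h.seq_id, h.genomic_interval.start))
    return CensusReport(table=table, hits=deduped, raw_hits=raw)


# ---------------------------------------------------------------------------
# Completeness and MHCI-style region classification

def classify_copy_completeness(
    coverage: float, full_threshold: float = 1.0, partial_threshold: float = 0.60
) -> str:
    """Classify a gene copy by fractional coverage of its reference length.

    >= full_threshold -> "full_length"; >= partial_threshold -> "partial"
    (the inclusive >=60% bound used for partial receptor copies); else
    "below".
    """
    if not 0 <= coverage <= 1:
        raise ValueError("coverage must lie in [0, 1]")
    if coverage >= full_threshold:
        return "full_length"
    if coverage >= partial_threshold:
        return "partial"
    return "below"


def classify_mhc_region(domains: Iterable[str]) -> str:
    """Combination label for the alpha domains present in one region.

    E.g. {"alpha3"} -> "alpha3", {"alpha1","alpha2","alpha3"} ->
    "alpha1+2+3".
    """
    nums = sorted({d.replace("alpha", "") for d in domains})
    if not nums:
        raise ValueError("empty domain set")
    return "alpha" + "+".join(nums)


def mhc_region_census(
    hits: Sequence[tuple[str, int, str]],
    window_bp: int = 10000,
) -> list[tuple[str, tuple[int, int], str]]:
    """Group alpha-domain hits into +/- window regions and label each.

    ``hits`` are (seq_id, position, domain_label) triples with labels like
    "alpha1"/"alpha2"/"alpha3". Windows are anchored greedily left to
    right: the leftmost unassigned hit opens a region of +/- window_bp and
    absorbs every hit inside it. Returns (seq_id, (start, end), label).
    """
    out = []
    by_seq: dict[str, list[tuple[int, str]]] = {}
    for seq_id, pos, label in hits:
        by_seq.setdefault(seq_id, []).append((pos, label))
    for seq_id in sorted(by_seq):
        entries = sorted(by_seq[seq_id])
        i = 0
        while i < len(entries):
            anchor = entries[i][0]
            lo, hi = anchor - window_bp, anchor + window_bp
            members = [e for e in entries[i:] if e[0] <= hi]
            labels = {lab for _, lab in members}
            out.append((seq_id, (max(0, lo), hi), classify_mhc_region(labels)))
            i += len(members)
    return out


# ---------------------------------------------------------------------------
# Profile file format

def _write_profile_to(profile: DomainProfile, fh) -> None:
    fh.write(f"#name\t{profile.name}\n")
    fh.write(f"#length\t{profile.length}\n")
    fh.write(f"#bit_threshold\t{profile.bit_threshold:g}\n")
    fh.write(f"#consensus\t{profile.consensus}\n")
    fh.write("#alphabet\t" + "\t".join(AA_ALPHABET) + "\n")
    for row in profile.scores:
        fh.write("\t".join(f"{x:g}" for x in row) + "\n")


def write_profile(profile: DomainProfile, path: str | Path) -> None:
    """Plain-text profile: header lines then L tab-separated score rows."""
    with open(path, "w") as fh:
        _write_profile_to(profile, fh)


def write_profiles(profiles: Iterable[DomainProfile], path: str | Path) -> None:
    """Write several profiles concatenated into one text file."""
    with open(path, "w") as fh:
        for p in profiles:
            _write_profile_to(p, fh)


def read_profiles(path: str | Path) -> list[DomainProfile]:
    """Read one or more concatenated profiles from a text file."""
    profiles: list[DomainProfile] = []
    header: dict[str, str] = {}
    rows: list[list[float]] = []

    def flush() -> None:
        nonlocal header, rows
        if rows:
            profiles.append(
                DomainProfile(
                    name=header.get("name", f"profile{len(profiles)}"),
                    scores=np.array(rows),
                    bit_threshold=float(header.get("bit_threshold", 0.0)),
                    consensus=header.get("consensus", ""),
                )
            )
        header, rows = {}, []

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition("\t")
                if key == "name" and rows:
                    flush()
                if key != "alphabet":
                    header[key] = value
            else:
                rows.append([float(x) for x in line.split("\t")])
    flush()
    if not profiles:
        raise ValueError(f"no profiles found in {path}")
    return profiles
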