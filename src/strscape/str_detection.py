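"""Detection of perfect short tandem repeats (unit size 1-10 bp) and
density/frequency statistics.

An STR locus is a maximal perfect tandem array: a tract of length >=
min_len[u] whose minimal period is u, that cannot be extended by a single
base on either side while remaining perfectly periodic. Partial trailing
units count toward the array length, so ACACA is a u=2 array of 2.5
copies. Arrays never span N.

Detection is perfect-repeat only; mismatch-tolerant (imperfect) repeat
scoring is out of scope. Thresholds are configurable per unit size; the
defaults (min_len[u] = max(12, 3u) bp, min_copies[u] = min_len[u]/u) floor
out trivially short tracts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from ._intervals import intersect, merge, subtract, total_length
from .io_formats import GenomicInterval, SequenceRecord

__all__ = [
    "STRLocus",
    "DensityTable",
    "DEFAULT_MIN_LEN",
    "DEFAULT_MIN_COPIES",
    "canonical_motif",
    "reverse_complement",
    "find_strs",
    "find_strs_assembly",
    "strs_in_regions",
    "str_statistics",
    "write_str_gff3",
    "read_str_gff3",
]

DEFAULT_MIN_LEN: dict[int, int] = {u: max(12, 3 * u) for u in range(1, 11)}
DEFAULT_MIN_COPIES: dict[int, float] = {u: DEFAULT_MIN_LEN[u] / u for u in range(1, 11)}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class STRLocus:
    """One maximal perfect tandem array."""

    seq_id: str
    interval: GenomicInterval
    unit_size: int
    motif: str  # canonical motif class
    copy_number: float

    @property
    def array_bp(self) -> int:
        return self.interval.length

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


@dataclass
class DensityTable:
    """Per-unit-size STR density (bp/Mbp) and frequency (loci/Mbp).

    ``table`` is indexed by unit size 1..10 plus a "total" row. Array bp are
    overlap-resolved (smaller unit sizes claim shared bases) so the total
    row never double counts; loci counts are the raw maximal arrays.
    """

    region_label: str
    region_bp: int
    table: pd.DataFrame


def canonical_motif(unit: str) -> str:
    """Canonical representative of a repeat unit.

    Lexicographically smallest string among all rotations of the unit and
    all rotations of its reverse complement, so e.g. GA, AG, TC and CT all
    map to AG.
    """
    if not 1 <= len(unit) <= 10:
        raise ValueError(f"unit length {len(unit)} outside 1-10")
    if set(unit) - set("ACGT"):
        raise ValueError(f"unit {unit!r} contains non-ACGT characters")
    rc = reverse_complement(unit)
    candidates = {unit[i:] + unit[:i] for i in range(len(unit))}
    candidates.update(rc[i:] + rc[:i] for i in range(len(rc)))
    return min(candidates)


def _minimal_period(tract: str, max_p: int) -> int:
    """Smallest p <= max_p such that tract[i] == tract[i+p] for all i."""
    for p in range(1, max_p + 1):
        if tract[:-p] == tract[p:]:
            return p
    return max_p  # unreachable for callers passing a known period


def find_strs(
    seq: SequenceRecord,
    min_unit: int = 1,
    max_unit: int = 10,
    min_len: Optional[Mapping[int, int]] = None,
    min_copies: Optional[Mapping[int, float]] = None,
) -> list[STRLocus]:
    """All maximal perfect tandem arrays in one sequence.

    For each unit size u the match mask m[i] = (s[i] == s[i+u], neither N)
    is scanned for runs; a run of r consecutive matches is a perfectly
    u-periodic tract of r + u bases. Tracts whose minimal period is smaller
    than u are reported only at their minimal period.
    """
    if min_unit > max_unit:
        raise ValueError("min_unit > max_unit")
    if min_unit < 1 or max_unit > 10:
        raise ValueError("unit sizes must lie in 1-10")
    min_len = dict(DEFAULT_MIN_LEN if min_len is None else min_len)
    min_copies = dict(DEFAULT_MIN_COPIES if min_copies is None else min_copies)
    for u in range(min_unit, max_unit + 1):
        if u not in min_len or u not in min_copies:
            raise ValueError(f"no threshold defined for unit size {u}")

    s = seq.residues
    n = len(s)
    arr = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    is_n = arr == ord("N")
    loci: list[STRLocus] = []
    for u in range(min_unit, max_unit + 1):
        if n < u + 1:
            continue
        m = (arr[:-u] == arr[u:]) & ~is_n[:-u] & ~is_n[u:]
        if not m.any():
            continue
        # run starts/ends in the match mask
        padded = np.concatenate(([False], m, [False]))
        d = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)  # exclusive in mask coords
        runlen = ends - starts
        keep = runlen + u >= min_len[u]
        for a, b in zip(starts[keep], ends[keep]):
            start, end = int(a), int(b) + u
            tract = s[start:end]
            if u > 1 and _minimal_period(tract, u) != u:
                continue  # reported at its minimal period instead
            copies = (end - start) / u
            if copies < min_copies[u]:
                continue
            loci.append(
                STRLocus(
                    seq_id=seq.seq_id,
                    interval=GenomicInterval(seq.seq_id, start, end),
                    unit_size=u,
                    motif=canonical_motif(s[start : start + u]),
                    copy_number=copies,
                )
            )
    loci.sort(key=lambda l: (l.start, l.unit_size))
    return loci


def find_strs_assembly(records: Sequence[SequenceRecord], **kwargs) -> list[STRLocus]:
    out: list[STRLocus] = []
    for rec in records:
        out.extend(find_strs(rec, **kwargs))
    return out


def strs_in_regions(
    loci: Iterable[STRLocus], regions: Iterable[GenomicInterval]
) -> list[STRLocus]:
    """Clip STR loci to a region set (e.g. merged CDS intervals).

    Each returned locus is the intersection of an input locus with one
    merged region; array bp and copy number are recomputed from the clipped
    interval, the motif and unit size are retained. Loci entirely outside
    the regions are dropped.
    """
    by_seq: dict[str, list[tuple[int, int]]] = {}
    for r in regions:
        by_seq.setdefault(r.seq_id, []).append((r.start, r.end))
    by_seq = {k: merge(v) for k, v in by_seq.items()}
    out: list[STRLocus] = []
    for locus in loci:
        regs = by_seq.get(locus.seq_id)
        if not regs:
            continue
        for s, e in intersect([(locus.start, locus.end)], regs):
            out.append(
                STRLocus(
                    seq_id=locus.seq_id,
                    interval=GenomicInterval(locus.seq_id, s, e),
                    unit_size=locus.unit_size,
                    motif=locus.motif,
                    copy_number=(e - s) / locus.unit_size,
                )
            )
    return out


def _resolved_bp_by_unit(loci: Sequence[STRLocus]) -> dict[int, int]:
    """Array bp per unit size after overlap resolution.

    Where arrays of different unit sizes overlap, the smaller unit size
    claims the shared bases, so summing over u never double counts.
    """
    units = sorted({l.unit_size for l in loci})
    claimed: dict[str, list[tuple[int, int]]] = {}
    out: dict[int, int] = {}
    for u in units:
        per_seq: dict[str, list[tuple[int, int]]] = {}
        for l in loci:
            if l.unit_size == u:
                per_seq.setdefault(l.seq_id, []).append((l.start, l.end))
        bp = 0
        for seq_id, ivs in per_seq.items():
            ivs = merge(ivs)
            new = subtract(ivs, claimed.get(seq_id, []))
            bp += total_length(new)
            claimed[seq_id] = merge(claimed.get(seq_id, []) + ivs)
        out[u] = bp
    return out


def str_statistics(
    loci: Sequence[STRLocus],
    region_bp: int,
    region_label: str = "assembly",
    min_unit: int = 1,
    max_unit: int = 10,
) -> DensityTable:
    """Density (bp/Mbp) and frequency (loci/Mbp) per unit size.

    ``region_bp`` is the size of the region the loci were detected in (whole
    assembly, or total merged CDS length for clipped loci).
    """
    if region_bp <= 0:
        raise ValueError("region_bp must be positive")
    resolved = _resolved_bp_by_unit(loci)
    units = list(range(min_unit, max_unit + 1))
    rows = []
    for u in units:
        count = sum(1 for l in loci if l.unit_size == u)
        bp = resolved.get(u, 0)
        rows.append((u, count, bp))
    total_count = sum(r[1] for r in rows)
    total_bp = sum(r[2] for r in rows)
    rows.append(("total", total_count, total_bp))
    df = pd.DataFrame(rows, columns=["unit_size", "loci_count", "array_bp"])
    df["density_bp_per_mbp"] = 1e6 * df["array_bp"] / region_bp
    df["frequency_loci_per_mbp"] = 1e6 * df["loci_count"] / region_bp
    df = df.set_index("unit_size")
    return DensityTable(region_label=region_label, region_bp=region_bp, table=df)


# ---------------------------------------------------------------------------
# GFF3 output for STR loci

def write_str_gff3(loci: Iterable[STRLocus], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, l in enumerate(loci):
            attrs = f"ID=str{i};unit_size={l.unit_size};motif={l.motif};copies={l.copy_number:g}"
            fh.write(
                f"{l.seq_id}\tstrscape\ttandem_repeat\t{l.start + 1}\t{l.end}\t.\t+\t.\t{attrs}\n"
            )


def read_str_gff3(path: str | Path) -> list[STRLocus]:
    loci: list[STRLocus] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if f[2] != "tandem_repeat":
                continue
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            start, end = int(f[3]) - 1, int(f[4])
            loci.append(
                STRLocus(
                    seq_id=f[0],
                    interval=GenomicInterval(f[0], start, end),
                    unit_size=int(attrs["unit_size"]),
                    motif=attrs["motif"],
                    copy_number=float(attrs["copies"]),
                )
            )
    return loci
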