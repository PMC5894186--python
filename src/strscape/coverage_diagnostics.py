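"""Read-depth normalization and collapsed-copy diagnostics.

Multiple near-identical gene copies that a genome assembler merges into
one sequence ("collapsed repeats") show up as elevated read depth: a
contig holding k collapsed copies attracts roughly k times the average
depth. This module normalizes per-sequence mean depth by the assembly-wide
mean and flags domain-bearing sequences whose normalized depth exceeds a
threshold, with a naive copy-number estimate of hits x round(normalized
depth).

Depth input is a TSV (not BAM) so the module runs without alignment
tooling: either samtools-depth-style per-base rows (seq_id, pos, depth;
all positions present, including zero-depth and N positions) or a
pre-averaged summary (seq_id, mean_depth, length).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import StrscapeWarning

__all__ = [
    "CoverageRecord",
    "per_sequence_depth",
    "normalize_depth",
    "flag_collapsed",
]


@dataclass
class CoverageRecord:
    seq_id: str
    length: int
    mean_depth: float
    normalized_depth: Optional[float] = None
    flagged_collapsed: bool = False
    n_hits: int = 0
    est_copies: Optional[float] = None
    est_copies_fractional: Optional[float] = None


def per_sequence_depth(
    depth_table: str | Path | pd.DataFrame,
    kind: str = "auto",
    expected_sequences: Optional[Iterable[str]] = None,
) -> list[CoverageRecord]:
    """Per-sequence mean depth from a depth TSV.

    ``kind`` is "per-base" (seq_id, pos, depth rows for every position),
    "summary" (seq_id, mean_depth, length) or "auto" (per-base if any
    seq_id repeats). ``expected_sequences`` lists assembly sequences that
    must appear; missing ones get mean 0 with a warning (their length is
    unknown and set to 0). Records are returned un-normalized; see
    :func:`normalize_depth`.
    """
    if isinstance(depth_table, (str, Path)):
        df = pd.read_csv(
            depth_table, sep="\t", header=None, names=["seq_id", "a", "b"]
        )
    else:
        df = depth_table.copy()
        df.columns = ["seq_id", "a", "b"]
    if kind == "auto":
        kind = "per-base" if df["seq_id"].duplicated().any() else "summary"
    records: list[CoverageRecord] = []
    if kind == "per-base":
        grouped = df.groupby("seq_id", sort=False)["b"]
        for seq_id, depths in grouped:
            records.append(
                CoverageRecord(
                    seq_id=str(seq_id),
                    length=int(depths.size),
                    mean_depth=float(depths.mean()),
                )
            )
    elif kind == "summary":
        for row in df.itertuples(index=False):
            records.append(
                CoverageRecord(
                    seq_id=str(row.seq_id), length=int(row.b), mean_depth=float(row.a)
                )
            )
    else:
        raise ValueError(f"unknown depth table kind {kind!r}")
    if expected_sequences is not None:
        present = {r.seq_id for r in records}
        missing = [s for s in expected_sequences if s not in present]
        if missing:
            warnings.warn(
                f"{len(missing)} assembly sequences have no depth rows; mean set to 0",
                StrscapeWarning,
                stacklevel=2,
            )
            records.extend(
                CoverageRecord(seq_id=s, length=0, mean_depth=0.0) for s in missing
            )
    return records


def normalize_depth(records: Sequence[CoverageRecord]) -> float:
    """Set normalized_depth = mean_depth / assembly mean; returns the mean.

    The assembly mean is total depth over total length (length-weighted),
    so the length-weighted mean of normalized_depth is 1 by construction.
    """
    total_len = sum(r.length for r in records)
    if total_len == 0:
        raise ValueError("no sequence length information; cannot normalize")
    assembly_mean = sum(r.mean_depth * r.length for r in records) / total_len
    if assembly_mean <= 0:
        raise ValueError("assembly mean depth is zero")
    for r in records:
        r.normalized_depth = r.mean_depth / assembly_mean
    return assembly_mean


def flag_collapsed(
    records: Sequence[CoverageRecord],
    domain_hits: Mapping[str, int] | Iterable,
    threshold: float = 2.0,
) -> pd.DataFrame:
    """Flag putatively collapsed sequences and tabulate length vs depth.

    A sequence is flagged iff its normalized depth exceeds ``threshold``
    AND it carries at least one domain hit. ``domain_hits`` is either a
    seq_id -> hit-count mapping or an iterable of objects with a seq_id
    attribute (e.g. DomainHits). Returns the plotted-variable table
    (log10 length, normalized depth) restricted to domain-bearing
    sequences; est_copies = hits x max(1, round(normalized_depth)) is
    filled in on the records.
    """
    if threshold <= 1:
        warnings.warn(
            f"collapse threshold {threshold} <= 1: flags will be dominated by noise",
            StrscapeWarning,
            stacklevel=2,
        )
    if isinstance(domain_hits, Mapping):
        counts = dict(domain_hits)
    else:
        counts = {}
        for h in domain_hits:
            seq_id = h if isinstance(h, str) else h.seq_id
            counts[seq_id] = counts.get(seq_id, 0) + 1
    rows = []
    for r in records:
        if r.normalized_depth is None:
            raise ValueError("records must be normalized first (normalize_depth)")
        r.n_hits = counts.get(r.seq_id, 0)
        r.flagged_collapsed = r.n_hits > 0 and r.normalized_depth > threshold
        if r.n_hits > 0:
            multiplier = max(1, round(r.normalized_depth))
            r.est_copies = r.n_hits * multiplier
            r.est_copies_fractional = r.n_hits * max(1.0, r.normalized_depth)
            rows.append(
                {
                    "seq_id": r.seq_id,
                    "log10_length": float(np.log10(r.length)) if r.length else np.nan,
                    "normalized_depth": r.normalized_depth,
                    "n_hits": r.n_hits,
                    "flagged": r.flagged_collapsed,
                    "est_copies": r.est_copies,
                }
            )
    return pd.DataFrame(rows)
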