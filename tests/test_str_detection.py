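"""STR detector vs brute-force oracle, motif canonicalization, statistics."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from strscape.io_formats import GenomicInterval, SequenceRecord
from strscape.str_detection import (
    DEFAULT_MIN_COPIES,
    DEFAULT_MIN_LEN,
    STRLocus,
    canonical_motif,
    find_strs,
    read_str_gff3,
    reverse_complement,
    str_statistics,
    strs_in_regions,
    write_str_gff3,
)


def oracle_strs(s, min_len=DEFAULT_MIN_LEN, min_copies=DEFAULT_MIN_COPIES):
    """Brute force: test every (start, u) for a maximal perfect array.

    Independent of the production scanner: extends each candidate base by
    base, checks left-maximality, thresholds and minimal period directly.
    """
    out = set()
    n = len(s)
    for start in range(n):
        for u in range(1, 11):
            if start + u > n or "N" in s[start : start + u]:
                continue
            end = start + u
            while end < n and s[end] != "N" and s[end] == s[end - u]:
                end += 1
            if end - start < min_len[u] or (end - start) / u < min_copies[u]:
                continue
            if start > 0 and s[start - 1] != "N" and s[start - 1] == s[start + u - 1]:
                continue  # extendable to the left
            tract = s[start:end]
            minp = next(p for p in range(1, u + 1) if p == u or tract[:-p] == tract[p:])
            if minp != u:
                continue
            out.add((start, end, u))
    return out


def impl_strs(s):
    return {(l.start, l.end, l.unit_size) for l in find_strs(SequenceRecord("s", s))}


def test_simple_dinucleotide_array():
    loci = find_strs(SequenceRecord("s", "ACACACACACAC"))
    assert [(l.start, l.end, l.unit_size, l.motif, l.copy_number) for l in loci] == [
        (0, 12, 2, "AC", 6.0)
    ]


def test_below_threshold_and_never_at_multiple_period():
    # 6 bp of AC is under min_len[2]=12 and must not surface at u=4 or u=6
    assert find_strs(SequenceRecord("s", "ACACAC")) == []
    # a long AC array is reported once, at its minimal period
    loci = find_strs(SequenceRecord("s", "ACACACACACACACAC"))
    assert {l.unit_size for l in loci} == {2}


def test_partial_trailing_unit_counts():
    loci = find_strs(SequenceRecord("s", "ACACACACACACA"))
    (l,) = loci
    assert (l.start, l.end, l.copy_number) == (0, 13, 6.5)


def test_arrays_split_at_n():
    s = "ACACACACACAC" + "N" + "ACACACACACAC"
    loci = find_strs(SequenceRecord("s", s))
    assert {(l.start, l.end) for l in loci} == {(0, 12), (13, 25)}


def test_thresholds_must_cover_all_units():
    with pytest.raises(ValueError):
        find_strs(SequenceRecord("s", "ACGT"), min_len={2: 12}, min_copies={2: 6})
    with pytest.raises(ValueError):
        find_strs(SequenceRecord("s", "ACGT"), min_unit=5, max_unit=2)


def test_detector_equals_oracle_exhaustive_small():
    """Exhaustive over all {A,C} strings up to length 14."""
    for L in range(1, 15):
        for tup in itertools.product("AC", repeat=L):
            s = "".join(tup)
            assert impl_strs(s) == oracle_strs(s), s


def test_detector_equals_oracle_random_with_n():
    rng = np.random.default_rng(5)
    for _ in range(60):
        s = "".join(
            "ACGTN"[j] for j in rng.choice(5, size=1000, p=[0.24] * 4 + [0.04])
        )
        assert impl_strs(s) == oracle_strs(s)


def test_maximality_of_reported_loci():
    rng = np.random.default_rng(6)
    # STR-rich composite: random backbone with injected arrays
    s = "".join("ACGT"[j] for j in rng.integers(0, 4, 2000))
    s = s[:300] + "ACACACACACACA" + s[300:900] + "AGCAGCAGCAGC" + s[900:]
    for l in find_strs(SequenceRecord("s", s)):
        u, a, b = l.unit_size, l.start, l.end
        if a > 0:
            assert s[a - 1] != s[a - 1 + u] or s[a - 1] == "N"
        if b < len(s):
            assert s[b] != s[b - u] or s[b] == "N"


def test_canonical_motif_examples_and_errors():
    assert canonical_motif("GA") == "AG"
    assert canonical_motif("AT") == "AT"
    assert canonical_motif("TC") == "AG"  # revcomp rotation class of GA
    with pytest.raises(ValueError):
        canonical_motif("AN")
    with pytest.raises(ValueError):
        canonical_motif("A" * 11)


def test_trinucleotide_classes_match_enumeration():
    """The 64 trinucleotides partition under rotation + reverse complement."""

    def brute_class(unit):
        rc = reverse_complement(unit)
        return frozenset(
            {unit[i:] + unit[:i] for i in range(3)}
            | {rc[i:] + rc[:i] for i in range(3)}
        )

    units = ["".join(t) for t in itertools.product("ACGT", repeat=3)]
    brute_classes = {brute_class(u) for u in units}
    canon = {canonical_motif(u) for u in units}
    assert len(canon) == len(brute_classes)
    for u in units:
        assert canonical_motif(u) in brute_class(u)


def test_motif_spectrum_reverse_complement_symmetric():
    rng = np.random.default_rng(8)
    s = "".join("ACGT"[j] for j in rng.integers(0, 4, 3000))
    s = s[:500] + "ACACACACACAC" + s[500:1500] + "AGCAGCAGCAGCAGC" + s[1500:]
    fwd = sorted((l.motif, l.unit_size, l.array_bp) for l in find_strs(SequenceRecord("s", s)))
    rev = sorted(
        (l.motif, l.unit_size, l.array_bp)
        for l in find_strs(SequenceRecord("s", reverse_complement(s)))
    )
    assert fwd == rev


def _locus(seq_id, start, end, u):
    return STRLocus(seq_id, GenomicInterval(seq_id, start, end), u, "A" * u, (end - start) / u)


def test_clipping_examples():
    loci = [_locus("s", 100, 130, 2), _locus("s", 150, 170, 2)]
    regions = [GenomicInterval("s", 110, 200)]
    clipped = strs_in_regions(loci, regions)
    assert [(l.start, l.end, l.array_bp) for l in clipped] == [(110, 130, 20), (150, 170, 20)]


def test_clipping_matches_sweep_oracle():
    rng = np.random.default_rng(9)
    loci = [
        _locus("s", a, a + int(rng.integers(12, 40)), 2)
        for a in rng.integers(0, 5000, 200)
    ]
    regions = [
        GenomicInterval("s", int(a), int(a) + int(rng.integers(20, 200)))
        for a in rng.integers(0, 5000, 40)
    ]
    clipped_bp = sum(l.array_bp for l in strs_in_regions(loci, regions))
    # oracle: per-base membership count
    cover = np.zeros(6000, dtype=bool)
    for r in regions:
        cover[r.start : r.end] = True
    oracle_bp = 0
    for l in loci:
        oracle_bp += int(cover[l.start : l.end].sum())
    assert clipped_bp == oracle_bp


def test_statistics_arithmetic_and_errors():
    loci = [_locus("s", i * 100, i * 100 + 25, 5) for i in range(20)]
    table = str_statistics(loci, 2_000_000).table
    assert table.loc[5, "density_bp_per_mbp"] == pytest.approx(250.0)
    assert table.loc[5, "frequency_loci_per_mbp"] == pytest.approx(10.0)
    assert table.loc["total", "array_bp"] == 500
    empty = str_statistics([], 1_000_000).table
    assert (empty["density_bp_per_mbp"] == 0).all()
    with pytest.raises(ValueError):
        str_statistics(loci, 0)


def test_overlap_resolution_smaller_unit_wins():
    # u=1 (6,18) overlaps u=2 (0,12): u=1 claims the shared bases
    loci = [_locus("s", 0, 12, 2), _locus("s", 6, 18, 1)]
    table = str_statistics(loci, 1_000_000).table
    assert table.loc[1, "array_bp"] == 12
    assert table.loc[2, "array_bp"] == 6
    assert table.loc["total", "array_bp"] == 18
    assert table.loc["total", "loci_count"] == 2


def test_str_gff3_roundtrip(tmp_path):
    loci = [_locus("s1", 10, 34, 3), _locus("s2", 5, 20, 5)]
    p = tmp_path / "strs.gff3"
    write_str_gff3(loci, p)
    back = read_str_gff3(p)
    assert [(l.seq_id, l.start, l.end, l.unit_size) for l in back] == [
        (l.seq_id, l.start, l.end, l.unit_size) for l in loci
    ]


def test_planted_density_recovery_is_intensive(default_sim):
    """Density recovered from the simulation matches the planted spectrum."""
    from strscape.str_detection import find_strs_assembly

    truth, _ = default_sim
    loci = find_strs_assembly(truth.records)
    table = str_statistics(loci, truth.assembly_bp).table
    for u, target in truth.config.str_spectrum.items():
        got = table.loc[u, "density_bp_per_mbp"]
        assert got == pytest.approx(target, rel=0.01), f"u={u}"
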