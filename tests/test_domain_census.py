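"""Six-frame translation, profile scanning and family census logic."""

from __future__ import annotations

import numpy as np
import pytest
from Bio.Seq import Seq

from strscape.domain_census import (
    DomainProfile,
    census,
    classify_copy_completeness,
    classify_mhc_region,
    mhc_region_census,
    profile_scan,
    read_profiles,
    six_frame_translate,
    translate_frame,
    write_profiles,
)
from strscape.io_formats import SequenceRecord
from strscape.str_detection import reverse_complement
from strscape.synthetic_data import _codons_for

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def _random_protein(rng, n):
    return "".join(AA20[i] for i in rng.integers(0, 20, n))


def test_translate_simple_codons():
    assert translate_frame("ATGAAATAA", 1) == "MK*"
    assert translate_frame("ATGAAA", -1) == "FH"  # revcomp TTTCAT
    assert translate_frame("ATGAANA", 1) == "MX"  # N codon -> X, partial dropped


def test_six_frame_against_biopython_whole_sequence_translation():
    rng = np.random.default_rng(0)
    s = "".join("ACGT"[i] for i in rng.integers(0, 4, 999))
    frames = six_frame_translate(SequenceRecord("s", s))
    for f in (1, 2, 3):
        off = f - 1
        sub = s[off : off + 3 * ((len(s) - off) // 3)]
        assert frames[f] == str(Seq(sub).translate())
        rc = reverse_complement(s)
        sub = rc[off : off + 3 * ((len(rc) - off) // 3)]
        assert frames[-f] == str(Seq(sub).translate())


def test_too_short_sequence_warns_and_returns_empty():
    with pytest.warns(match="shorter than one codon"):
        frames = six_frame_translate(SequenceRecord("s", "AT"))
    assert all(v == "" for v in frames.values())


def test_profile_scan_consensus_is_perfect_hit():
    rng = np.random.default_rng(1)
    consensus = _random_protein(rng, 60)
    prof = DomainProfile.from_consensus("D", consensus)
    (hit,) = profile_scan(consensus, prof)
    assert hit.coverage == pytest.approx(1.0)
    assert hit.score == pytest.approx(2.0 * 60)
    assert not hit.has_internal_stop


def test_profile_scan_truncated_copy_lands_in_partial_bin():
    rng = np.random.default_rng(2)
    consensus = _random_protein(rng, 100)
    embedded = _random_protein(rng, 80) + consensus[:60] + _random_protein(rng, 80)
    prof = DomainProfile.from_consensus("D", consensus)
    hits = profile_scan(embedded, prof)
    assert len(hits) == 1
    # 60 of 100 columns align: counted in >50%, excluded from >75%
    assert 0.5 < hits[0].coverage <= 0.75
    assert hits[0].coverage == pytest.approx(0.60, abs=0.03)


def test_profile_scan_flags_internal_stop():
    rng = np.random.default_rng(3)
    consensus = _random_protein(rng, 60)
    broken = consensus[:30] + "*" + consensus[31:]
    prof = DomainProfile.from_consensus("D", consensus)
    (hit,) = profile_scan(broken, prof)
    assert hit.has_internal_stop
    assert hit.coverage == pytest.approx(1.0)


def test_profile_scan_no_hit_in_random_background():
    rng = np.random.default_rng(4)
    prof = DomainProfile.from_consensus("D", _random_protein(rng, 80))
    assert profile_scan(_random_protein(rng, 500), prof) == []


def test_profile_requires_minimum_length_and_shape():
    with pytest.raises(ValueError):
        DomainProfile("x", np.zeros((5, 21)), 1.0, "AAAAA")
    with pytest.raises(ValueError):
        DomainProfile("x", np.zeros((12, 20)), 1.0, "A" * 12)


def test_census_planted_copies_and_stop_flags(census_sim):
    truth, out = census_sim
    profiles = read_profiles(out / "profiles.txt")
    report = census(truth.records, profiles, placed_map=truth.placed)
    row = report.table.loc["FISNA-like"]
    n_pseudo = sum(1 for d in truth.domain_loci if d["pseudogene"])
    assert row["n_gt75"] == len(truth.domain_loci) == 15
    assert row["n_gt75_with_stops"] == n_pseudo == 3
    assert row["n_all"] >= row["n_gt50"] >= row["n_gt75"]
    assert row["n_placed"] + row["n_unplaced"] == row["n_all"]
    # every hit localizes to a planted domain interval
    planted = {(d["seq_id"], d["start"], d["end"]) for d in truth.domain_loci}
    for h in report.hits:
        g = h.genomic_interval
        # a lucky flank codon can extend the local segment by a column or two
        assert any(
            s == h.seq_id and g.start >= a - 9 and g.end <= b + 9 for s, a, b in planted
        )


def test_census_deduplicates_tandem_copies_across_frames():
    rng = np.random.default_rng(5)
    consensus = _random_protein(rng, 60)
    prof = DomainProfile.from_consensus("D", consensus)
    dna = _codons_for(consensus, rng)
    spacer = "".join("ACGT"[i] for i in rng.integers(0, 4, 33))
    contig = SequenceRecord("c", spacer.join([dna] * 5))
    report = census([contig], [prof])
    assert report.table.loc["D", "n_all"] == 5
    assert len(report.raw_hits) >= 5


def test_census_strand_symmetry():
    rng = np.random.default_rng(6)
    consensus = _random_protein(rng, 40)
    prof = DomainProfile.from_consensus("D", consensus)
    dna = _codons_for(consensus, rng)
    flank = "".join("ACGT"[i] for i in rng.integers(0, 4, 200))
    s = flank + dna + flank
    fwd = census([SequenceRecord("c", s)], [prof])
    rev = census([SequenceRecord("c", reverse_complement(s))], [prof])
    assert fwd.table.loc["D", "n_all"] == rev.table.loc["D", "n_all"] == 1
    assert fwd.hits[0].score == pytest.approx(rev.hits[0].score)
    # intervals mirror each other
    gi_f, gi_r = fwd.hits[0].genomic_interval, rev.hits[0].genomic_interval
    assert (gi_f.start, gi_f.end) == (len(s) - gi_r.end, len(s) - gi_r.start)


def test_census_dedup_idempotent(census_sim):
    truth, out = census_sim
    profiles = read_profiles(out / "profiles.txt")
    report = census(truth.records, profiles)
    from strscape.domain_census import _dedup_hits

    again = _dedup_hits(list(report.hits))
    assert len(again) == len(report.hits)


def test_census_empty_assembly():
    rng = np.random.default_rng(7)
    prof = DomainProfile.from_consensus("D", _random_protein(rng, 40))
    report = census([], [prof])
    assert (report.table.loc["D"] == 0).all()


@pytest.mark.parametrize(
    "cov,label",
    [(1.0, "full_length"), (0.8, "partial"), (0.60, "partial"), (0.59, "below"), (0.0, "below")],
)
def test_copy_completeness_bins(cov, label):
    assert classify_copy_completeness(cov) == label


def test_copy_completeness_rejects_out_of_range():
    with pytest.raises(ValueError):
        classify_copy_completeness(1.2)


def test_mhc_region_labels():
    assert classify_mhc_region({"alpha1", "alpha2", "alpha3"}) == "alpha1+2+3"
    assert classify_mhc_region({"alpha3"}) == "alpha3"
    assert classify_mhc_region({"alpha2", "alpha3"}) == "alpha2+3"
    with pytest.raises(ValueError):
        classify_mhc_region(set())


def test_mhc_region_census_windows():
    hits = [("c1", 1000, "alpha1"), ("c1", 2500, "alpha2"), ("c1", 4000, "alpha3")]
    regions = mhc_region_census(hits, window_bp=10_000)
    assert [r[2] for r in regions] == ["alpha1+2+3"]
    # far-apart hits resolve into separate windows, greedily left to right
    hits += [("c1", 40_000, "alpha3")]
    regions = mhc_region_census(hits, window_bp=10_000)
    assert [r[2] for r in regions] == ["alpha1+2+3", "alpha3"]


def test_mhc_region_census_planted_mixture():
    rng = np.random.default_rng(8)
    hits = []
    for i in range(10):  # complete regions on their own contigs
        base = int(rng.integers(1000, 5000))
        hits += [
            (f"full{i}", base, "alpha1"),
            (f"full{i}", base + 1500, "alpha2"),
            (f"full{i}", base + 3000, "alpha3"),
        ]
    for i in range(7):  # isolated alpha3 fragments
        hits.append((f"frag{i}", int(rng.integers(500, 2000)), "alpha3"))
    regions = mhc_region_census(hits)
    labels = [r[2] for r in regions]
    assert labels.count("alpha1+2+3") == 10
    assert labels.count("alpha3") == 7


def test_profile_file_roundtrip(tmp_path):
    rng = np.random.default_rng(9)
    profs = [
        DomainProfile.from_consensus("P1", _random_protein(rng, 30)),
        DomainProfile.from_consensus("P2", _random_protein(rng, 45), bit_threshold=20),
    ]
    p = tmp_path / "profiles.txt"
    write_profiles(profs, p)
    back = read_profiles(p)
    assert [b.name for b in back] == ["P1", "P2"]
    for a, b in zip(profs, back):
        assert b.consensus == a.consensus
        assert b.bit_threshold == pytest.approx(a.bit_threshold)
        np.testing.assert_allclose(b.scores, a.scores)
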