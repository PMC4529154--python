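"""HSSP curve, HVAL, homolog maps, and disorder-overlap statistics."""

from __future__ import annotations

import math

import numpy as np
import pytest

from disorderome import (
    ProteinSequence,
    build_homolog_map,
    disorder_overlap,
    hssp_threshold,
    hval,
    related_over_cutoffs,
    related_table,
)
from disorderome.homology import align_pair
from disorderome.io_formats import AlignmentRecord
from disorderome.synthetic import GeneratorConfig, generate_homolog_pairs

from conftest import make_track
from oracles import recount_related


class TestHsspCurve:
    def test_long_alignments_hit_twenty_percent(self):
        assert round(hssp_threshold(300)) == 20

    def test_plateau_beyond_450(self):
        assert hssp_threshold(600) == 19.5
        assert hssp_threshold(10_000) == 19.5

    def test_short_alignment_value(self):
        assert hssp_threshold(100) == pytest.approx(29.0, abs=0.1)

    def test_very_short_alignments_clamped(self):
        assert hssp_threshold(1) == 100.0

    def test_non_increasing_in_length(self):
        # the curve has a shallow minimum around L~420 and climbs < 0.04
        # points back up before the plateau cut; monotonicity holds to that
        values = [hssp_threshold(L) for L in range(1, 1000)]
        assert all(a >= b - 2e-3 for a, b in zip(values, values[1:]))
        assert all(a >= b - 0.04 for a, b in zip(values, values[2:]))

    def test_continuous_at_plateau_boundary(self):
        assert abs(hssp_threshold(450) - hssp_threshold(451)) < 0.1

    def test_invalid_length(self):
        with pytest.raises(ValueError):
            hssp_threshold(0)


class TestHval:
    def test_on_curve_is_zero(self):
        for L in (10, 100, 300, 600):
            assert hval(hssp_threshold(L), L) == pytest.approx(0.0)

    def test_offsets(self):
        assert hval(35.0, 300) == pytest.approx(35.0 - hssp_threshold(300))
        assert hval(100.0, 600) == pytest.approx(80.5)

    def test_strictly_increasing_in_identity(self):
        values = [hval(p, 250) for p in np.linspace(0, 100, 21)]
        assert all(b > a for a, b in zip(values, values[1:]))


class TestHomologMap:
    def test_cutoff_inclusion(self):
        alignments = [
            AlignmentRecord("P1", "Q1", 40.0, 300),  # hval ~ 20 -> kept at 10
            AlignmentRecord("P2", "Q2", 25.0, 300),  # hval ~ 5 -> dropped at 10
        ]
        pairs = build_homolog_map(alignments, cutoff=10.0).pairs
        assert [(a, b) for a, b, _ in pairs] == [("P1", "Q1")]

    def test_self_hits_excluded(self):
        alignments = [AlignmentRecord("P1", "P1", 100.0, 300)]
        assert build_homolog_map(alignments, cutoff=-1000.0).pairs == []

    def test_very_low_cutoff_keeps_everything_else(self):
        alignments = [
            AlignmentRecord("P1", "Q1", 1.0, 50),
            AlignmentRecord("P2", "Q2", 5.0, 400),
            AlignmentRecord("P3", "P3", 99.0, 100),
        ]
        assert len(build_homolog_map(alignments, cutoff=-1e9).pairs) == 2

    def test_symmetric_duplicates_collapse_to_higher_hval(self):
        alignments = [
            AlignmentRecord("P1", "Q1", 40.0, 300),
            AlignmentRecord("Q1", "P1", 45.0, 300),
        ]
        pairs = build_homolog_map(alignments, cutoff=0.0).pairs
        assert len(pairs) == 1
        assert pairs[0][2] == pytest.approx(hval(45.0, 300))

    def test_raising_cutoff_never_adds_pairs(self):
        rng = np.random.default_rng(2)
        alignments = [
            AlignmentRecord(f"P{i}", f"Q{i}", float(rng.uniform(5, 95)), int(rng.integers(40, 500)))
            for i in range(100)
        ]
        sizes = [len(build_homolog_map(alignments, c).pairs) for c in (-20, -10, 0, 10, 20, 30)]
        assert sizes == sorted(sizes, reverse=True)


def two_org_fixture():
    """Four proteins per organism, two related pairs, controlled disorder."""
    long = np.concatenate([np.zeros(10), np.ones(40), np.zeros(10)]).astype(np.int8)
    flat = np.zeros(60, dtype=np.int8)
    tracks_a = {
        "A1": make_track(long, "A1"), "A2": make_track(flat, "A2"),
        "A3": make_track(flat, "A3"), "A4": make_track(long, "A4"),
    }
    tracks_b = {
        "B1": make_track(flat, "B1"), "B2": make_track(long, "B2"),
        "B3": make_track(flat, "B3"), "B4": make_track(flat, "B4"),
    }
    alignments = [
        AlignmentRecord("A1", "B1", 60.0, 300),
        AlignmentRecord("A2", "B2", 55.0, 300),
    ]
    return tracks_a, tracks_b, alignments


class TestRelatedTable:
    def test_fractions_and_binomial_stderr(self):
        tracks_a, tracks_b, alignments = two_org_fixture()
        stats = related_table(build_homolog_map(alignments, 0.0), tracks_a, tracks_b)
        assert stats.a.pct_related == 50.0
        assert stats.a.stderr_related == pytest.approx(100 * math.sqrt(0.25 / 4))
        # A1 is related and long-disordered; A2 related but ordered
        assert stats.a.pct_related_disordered == 25.0
        assert stats.b.pct_related == 50.0
        assert stats.b.pct_related_disordered == 25.0

    def test_no_pairs_all_zero(self):
        tracks_a, tracks_b, alignments = two_org_fixture()
        stats = related_table(build_homolog_map(alignments, 1000.0), tracks_a, tracks_b)
        assert stats.a.pct_related == 0.0
        assert stats.b.pct_related_disordered == 0.0
        assert stats.a.stderr_related == 0.0

    def test_missing_track_named(self):
        tracks_a, tracks_b, alignments = two_org_fixture()
        del tracks_a["A1"]
        alignments.append(AlignmentRecord("A1", "B3", 60.0, 300))
        with pytest.raises(ValueError, match="A1"):
            related_table(build_homolog_map(alignments, 0.0), tracks_a, tracks_b)

    def test_matches_brute_force_recount_on_synthetic_pairs(self):
        cfg = GeneratorConfig(seed=9)
        pairset = generate_homolog_pairs(
            cfg, n_pairs=25, pide_target=50.0, aligned_length=200,
            disordered_in="a_only", n_unrelated_a=15, n_unrelated_b=5,
        )
        homolog_map = build_homolog_map(pairset.alignments, cutoff=0.0)
        stats = related_table(homolog_map, pairset.tracks_a, pairset.tracks_b)
        from disorderome.regions import has_long_disorder

        long_a = {t.protein_id for t in pairset.tracks_a if has_long_disorder(t, 30)}
        long_b = {t.protein_id for t in pairset.tracks_b if has_long_disorder(t, 30)}
        ids_a = {t.protein_id for t in pairset.tracks_a}
        ids_b = {t.protein_id for t in pairset.tracks_b}
        n_rel_a, n_rel_dis_a, n_rel_b, n_rel_dis_b = recount_related(
            [(a, b) for a, b, _ in homolog_map.pairs], ids_a, ids_b, long_a, long_b
        )
        assert stats.a.n_related == n_rel_a == 25
        assert stats.a.n_related_disordered == n_rel_dis_a == 25
        assert stats.b.n_related == n_rel_b == 25
        assert stats.b.n_related_disordered == n_rel_dis_b == 0


class TestDisorderOverlap:
    def test_constructed_a_only_pattern(self):
        tracks_a, tracks_b, alignments = two_org_fixture()
        overlap = disorder_overlap(build_homolog_map(alignments, 0.0), tracks_a, tracks_b)
        assert overlap.disordered_in_a_only == 1  # A1-B1
        assert overlap.disordered_in_b_only == 1  # A2-B2
        assert overlap.both == 0
        assert overlap.neither == 0

    def test_independence_expectation_is_product(self):
        # proteome disorder fraction 0.5 (A1, A4 of 4), 2 related proteins
        tracks_a, tracks_b, alignments = two_org_fixture()
        overlap = disorder_overlap(build_homolog_map(alignments, 0.0), tracks_a, tracks_b)
        assert overlap.n_related_a == 2
        assert overlap.expected_disordered_a == pytest.approx(2 * 0.5)
        assert overlap.observed_disordered_a == 1

    def test_empty_map(self):
        tracks_a, tracks_b, alignments = two_org_fixture()
        overlap = disorder_overlap(build_homolog_map(alignments, 1e9), tracks_a, tracks_b)
        assert (overlap.n_pairs, overlap.both, overlap.neither) == (0, 0, 0)
        assert overlap.expected_disordered_a == 0.0


def test_related_pct_non_increasing_over_cutoff_grid():
    cfg = GeneratorConfig(seed=17)
    pairset = generate_homolog_pairs(
        cfg, n_pairs=40, pide_target=35.0, aligned_length=250,
        disordered_in="a_only", n_unrelated_a=20, n_unrelated_b=20,
    )
    # add some weaker alignments so the grid actually thins the map
    rng = np.random.default_rng(1)
    extra = [
        AlignmentRecord(f"A_h{i + 1:04d}", f"B_u{(i % 20) + 1:04d}",
                        float(rng.uniform(10, 60)), int(rng.integers(60, 400)))
        for i in range(40)
    ]
    table = related_over_cutoffs(
        pairset.alignments + extra, pairset.tracks_a, pairset.tracks_b,
        cutoffs=(-20, -10, 0, 10, 20, 30), org_a="A", org_b="B",
    )
    for org in ("A", "B"):
        series = table[table["org"] == org].sort_values("hval_cutoff")["pct_related"].tolist()
        assert series == sorted(series, reverse=True)
        dis = table[table["org"] == org].sort_values("hval_cutoff")["pct_related_disordered"]
        assert (dis <= table[table["org"] == org].sort_values("hval_cutoff")["pct_related"] + 1e-9).all()


class TestBuiltInAligner:
    def test_identical_sequences_full_identity(self):
        seq = ProteinSequence("x", "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ" * 3)
        record = align_pair(seq, ProteinSequence("y", seq.sequence))
        assert record.pide == pytest.approx(100.0)
        assert record.aligned_length == seq.length

    def test_substituted_copy_has_matching_identity(self):
        rng = np.random.default_rng(4)
        letters = rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 200)
        mutant = letters.copy()
        mutant[::4] = "W"  # heavy-handed but local alignment should span most of it
        record = align_pair(ProteinSequence("a", "".join(letters)), ProteinSequence("b", "".join(mutant)))
        assert 60.0 <= record.pide <= 90.0

    def test_length_limit(self):
        big = ProteinSequence("big", "A" * 2001)
        with pytest.raises(ValueError, match="2000"):
            align_pair(big, big)
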