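"""Synthetic proteome generator: calibration, determinism, homolog construction."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from disorderome import hssp_threshold, hval, summarize_proteome
from disorderome.synthetic import (
    GeneratorConfig,
    calibrate_entry_probability,
    generate_habitat_panel,
    generate_homolog_pairs,
    generate_proteome,
    long_run_probability,
)


def exact_long_run_probability(length, p_enter, p_stay_d, min_run):
    """Enumerate every 0/1 chain of the given length with its stationary
    Markov probability; sum those containing a disordered run >= min_run."""
    q = 1.0 - p_stay_d
    pi_d = p_enter / (p_enter + q)
    total = 0.0
    for states in itertools.product((0, 1), repeat=length):
        prob = pi_d if states[0] == 1 else 1.0 - pi_d
        for prev, cur in zip(states, states[1:]):
            if prev == 1:
                prob *= p_stay_d if cur == 1 else q
            else:
                prob *= p_enter if cur == 1 else 1.0 - p_enter
        longest = max(
            (len(list(g)) for v, g in itertools.groupby(states) if v == 1), default=0
        )
        if longest >= min_run:
            total += prob
    return total


class TestRunLengthModel:
    @pytest.mark.parametrize("p_enter, p_stay_d, min_run", [
        (0.3, 0.7, 3),
        (0.1, 0.9, 4),
        (0.5, 0.5, 2),
    ])
    def test_dynamic_program_matches_exact_enumeration(self, p_enter, p_stay_d, min_run):
        lengths = np.array([1, 2, 5, 8, 10])
        dp = long_run_probability(lengths, p_enter, p_stay_d, min_run)
        exact = [exact_long_run_probability(int(L), p_enter, p_stay_d, min_run) for L in lengths]
        assert dp == pytest.approx(exact, abs=1e-12)

    def test_monotone_in_entry_probability(self):
        lengths = np.full(1, 300)
        values = [
            float(long_run_probability(lengths, p, 0.97, 30)[0])
            for p in (0.0005, 0.001, 0.005, 0.02, 0.1, 0.5)
        ]
        assert values == sorted(values)

    def test_calibration_hits_target(self):
        lengths = np.random.default_rng(0).integers(100, 600, 200)
        p_enter = calibrate_entry_probability(0.2, lengths, 0.97)
        realized = float(long_run_probability(lengths, p_enter, 0.97, 30).mean())
        assert realized == pytest.approx(0.2, abs=1e-6)

    def test_infeasible_target_reports_attainable_range(self):
        lengths = np.full(50, 35)  # barely longer than the run threshold
        with pytest.raises(ValueError, match="attainable"):
            calibrate_entry_probability(0.99, lengths, 0.5)


class TestGenerateProteome:
    def test_deterministic(self):
        cfg = GeneratorConfig(seed=123, n_proteins=50)
        seqs1, tracks1 = generate_proteome(cfg)
        seqs2, tracks2 = generate_proteome(cfg)
        assert [s.sequence for s in seqs1] == [s.sequence for s in seqs2]
        assert all(np.array_equal(a.scores, b.scores) for a, b in zip(tracks1, tracks2))
        assert all(np.array_equal(a.states, b.states) for a, b in zip(tracks1, tracks2))

    def test_no_disorder_persistence_means_no_long_runs(self):
        cfg = GeneratorConfig(seed=3, n_proteins=100, p_stay_disordered=0.0, p_stay_ordered=0.9)
        _, tracks = generate_proteome(cfg, include_sequences=False)
        profile = summarize_proteome(tracks, "o")
        assert profile.pct_long[30] == 0.0
        assert max(t.states.max(initial=0) for t in tracks) == 1  # disorder occurs, runs of 1

    def test_target_recovery_within_binomial_error(self):
        cfg = GeneratorConfig(seed=7, n_proteins=500, target_pct_long30=20.0)
        _, tracks = generate_proteome(cfg, include_sequences=False)
        profile = summarize_proteome(tracks, "o")
        se = 100 * math.sqrt(0.2 * 0.8 / 500)
        assert abs(profile.pct_long[30] - 20.0) <= 2 * se

    def test_scores_respect_binarize_faithfulness(self):
        cfg = GeneratorConfig(seed=11, n_proteins=20)
        _, tracks = generate_proteome(cfg, include_sequences=False)
        for track in tracks:
            assert np.array_equal((track.scores >= 0.5).astype(np.int8), track.states)

    def test_sequences_match_track_lengths(self):
        cfg = GeneratorConfig(seed=5, n_proteins=30)
        seqs, tracks = generate_proteome(cfg)
        assert [s.length for s in seqs] == [t.length for t in tracks]

    def test_composition_bias_enriches_disordered_state(self):
        cfg = GeneratorConfig(
            seed=19, n_proteins=150, target_pct_long30=40.0,
            composition_bias={"P": 5.0},
        )
        seqs, tracks = generate_proteome(cfg)
        p_dis = p_ord = n_dis = n_ord = 0
        for seq, track in zip(seqs, tracks):
            arr = np.frombuffer(seq.sequence.encode(), dtype="S1").astype("U1")
            mask = track.states == 1
            p_dis += (arr[mask] == "P").sum(); n_dis += mask.sum()
            p_ord += (arr[~mask] == "P").sum(); n_ord += (~mask).sum()
        assert p_dis / n_dis > 2 * (p_ord / n_ord)

    def test_invalid_noise_rejected(self):
        with pytest.raises(ValueError, match="score_noise"):
            GeneratorConfig(seed=1, score_noise=0.6)


class TestHabitatPanel:
    def test_same_seed_identical_panels(self):
        cfg = GeneratorConfig(seed=55, n_proteins=20)
        groups = [("halophile", 2, 2.0), ("mesophile", 2, 0.0)]
        p1 = generate_habitat_panel(cfg, groups)
        p2 = generate_habitat_panel(cfg, groups)
        for org in p1.tracks:
            assert all(
                np.array_equal(a.states, b.states)
                for a, b in zip(p1.tracks[org], p2.tracks[org])
            )

    def test_group_effects_shift_targets(self):
        cfg = GeneratorConfig(seed=56, n_proteins=20)
        panel = generate_habitat_panel(cfg, [("halophile", 2, 2.0), ("mesophile", 2, 0.0)])
        halo = [t for o, t in panel.targets.items() if o.startswith("halophile")]
        meso = [t for o, t in panel.targets.items() if o.startswith("mesophile")]
        assert set(meso) == {14.6}
        assert set(halo) == {14.6 + 2 * 4.2}

    def test_habitat_labels_attached(self):
        cfg = GeneratorConfig(seed=57, n_proteins=20)
        panel = generate_habitat_panel(cfg, [("halophile", 2, 0.0), ("mesophile", 3, 0.0)])
        labels = [o.habitat_class for o in panel.organisms]
        assert labels.count("halophile") == 2 and labels.count("mesophile") == 3

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError):
            generate_habitat_panel(GeneratorConfig(seed=1), [("only", 3, 0.0)])

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            generate_habitat_panel(GeneratorConfig(seed=1), [("a", 0, 0.0), ("b", 2, 0.0)])


class TestHomologPairs:
    def test_realized_identity_within_a_point(self):
        cfg = GeneratorConfig(seed=31)
        pairset = generate_homolog_pairs(cfg, 10, pide_target=35.0, aligned_length=300)
        for rec, sa, sb in zip(pairset.alignments, pairset.sequences_a, pairset.sequences_b):
            matches = sum(x == y for x, y in zip(sa.sequence, sb.sequence))
            realized = 100 * matches / 300
            assert abs(realized - 35.0) <= 1.0
            assert rec.pide == pytest.approx(realized)

    def test_emitted_hval_matches_curve(self):
        cfg = GeneratorConfig(seed=32)
        pairset = generate_homolog_pairs(cfg, 3, pide_target=35.0, aligned_length=300)
        for rec in pairset.alignments:
            assert hval(rec.pide, rec.aligned_length) == pytest.approx(
                rec.pide - hssp_threshold(300)
            )

    def test_full_identity_limit(self):
        cfg = GeneratorConfig(seed=33)
        pairset = generate_homolog_pairs(cfg, 2, pide_target=100.0, aligned_length=120)
        for sa, sb, rec in zip(pairset.sequences_a, pairset.sequences_b, pairset.alignments):
            assert sa.sequence == sb.sequence
            assert rec.pide == 100.0
            assert hval(rec.pide, 120) == pytest.approx(100.0 - hssp_threshold(120))

    def test_disorder_pattern_placement(self):
        from disorderome.regions import has_long_disorder

        cfg = GeneratorConfig(seed=34)
        for pattern, expect_a, expect_b in [
            ("a_only", True, False), ("b_only", False, True),
            ("both", True, True), ("neither", False, False),
        ]:
            pairset = generate_homolog_pairs(cfg, 4, 50.0, 200, disordered_in=pattern)
            assert all(has_long_disorder(t, 30) is expect_a for t in pairset.tracks_a)
            assert all(has_long_disorder(t, 30) is expect_b for t in pairset.tracks_b)

    def test_too_short_for_disorder_run(self):
        with pytest.raises(ValueError, match="too short"):
            generate_homolog_pairs(GeneratorConfig(seed=1), 2, 50.0, 35, disordered_in="a_only")

    def test_invalid_identity_target(self):
        with pytest.raises(ValueError):
            generate_homolog_pairs(GeneratorConfig(seed=1), 2, 0.0, 100)
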