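import math

import numpy as np
import pytest

from oracles import brute_force_best_alignment
from trscout.msa_io import revcomp_dna
from trscout.profile_model import build_profile, consensus_sequence
from trscout.structure_scan import (Hit, ScanConfig, calibrate_null,
                                    dinucleotide_shuffle, empirical_evalue,
                                    hits_to_bed, hits_to_table, scan,
                                    score_trace, score_window)
from trscout.synthetic_data import FamilySpec, plant, sample_family


SMALL_CFG = ScanConfig(gap_open=-2.0, gap_extend=-0.7, pair_bonus_canonical=1.5,
                       pair_penalty_broken=-1.0, max_insert_per_gap_region=3,
                       min_window=1, score_threshold=0.0)


def oracle_score(profile, window, cfg):
    return brute_force_best_alignment(
        profile.col_freqs, profile.gap_freq, profile.background,
        profile.pairs.nested, window, cfg.gap_open, cfg.gap_extend,
        cfg.max_insert_per_gap_region, cfg.pair_bonus_canonical,
        cfg.pair_penalty_broken)


class TestScoreWindow:
    def test_consensus_window_hits_closed_form(self):
        """An ungapped consensus window scores max column log-odds plus the
        pair bonuses (all consensus pairs close canonically here)."""
        from trscout.msa_io import StructuredAlignment
        aln = StructuredAlignment(
            rows=[("a", "GGACAUCC"), ("b", "GGACAUCC"),
                  ("c", "GGACAUCC"), ("d", "CGACAUCG")],
            consensus_structure="((....))")
        profile = build_profile(aln, pseudocount=0.0)
        cfg = ScanConfig(min_window=1, score_threshold=0.0)
        cons = consensus_sequence(profile)
        lo = profile.log_odds()
        expected = sum(lo[c].max() for c in range(profile.length))
        expected += 2 * cfg.pair_bonus_canonical
        score, trace = score_window(profile, cons, cfg)
        assert score == pytest.approx(expected, abs=1e-9)

    def test_all_ambiguous_window_scores_only_penalties(
            self, random_profile_factory):
        profile = random_profile_factory(6, pairs=[(0, 5)])
        score, trace = score_window(profile, "N" * 6, SMALL_CFG)
        assert score == pytest.approx(oracle_score(profile, "N" * 6, SMALL_CFG))
        assert score <= 0

    def test_short_window_returns_sentinel(self, random_profile_factory):
        profile = random_profile_factory(8, pairs=[])
        cfg = ScanConfig(min_window=5)
        assert score_window(profile, "ACG", cfg) is None

    def test_trace_rescoring_is_self_consistent(self, random_profile_factory):
        rng = np.random.default_rng(7)
        profile = random_profile_factory(7, pairs=[(0, 6), (1, 5)], seed=2)
        for _ in range(5):
            window = "".join(rng.choice(list("ACGU"), size=9))
            score, trace = score_window(profile, window, SMALL_CFG)
            assert score == pytest.approx(
                score_trace(profile, window, trace, SMALL_CFG), abs=1e-6)

    def test_pseudoknot_layer_scored_additively(self, random_profile_factory):
        """The PK term equals the nested-only score plus the post-hoc
        adjustment computed on the optimal trace."""
        nested_only = random_profile_factory(8, pairs=[(0, 7), (1, 6)], seed=5)
        with_pk = random_profile_factory(8, pairs=[(0, 7), (1, 6)], seed=5,
                                         pk_pairs=[(2, 4)])
        rng = np.random.default_rng(11)
        for _ in range(5):
            window = "".join(rng.choice(list("ACGU"), size=8))
            s0, trace = score_window(nested_only, window, SMALL_CFG)
            s1, trace1 = score_window(with_pk, window, SMALL_CFG)
            matched = {c: w for op, c, w in trace if op == "M"}
            if 2 in matched and 4 in matched:
                pair = (window[matched[2]], window[matched[4]])
                adj = (SMALL_CFG.pair_bonus_canonical
                       if pair in {("A", "U"), ("U", "A"), ("G", "C"),
                                   ("C", "G"), ("G", "U"), ("U", "G")}
                       else SMALL_CFG.pair_penalty_broken)
            else:
                adj = SMALL_CFG.pair_penalty_broken
            assert s1 == pytest.approx(s0 + adj, abs=1e-6)


class TestDPOracleEquivalence:
    """The structure-guided DP must agree exactly with brute-force
    enumeration of every monotone alignment (small instances)."""

    @pytest.mark.parametrize("length,pairs,win_len", [
        (2, [], 2),
        (3, [(0, 2)], 5),
        (4, [(0, 3), (1, 2)], 4),
        (5, [(1, 4)], 7),
        (6, [(0, 5), (1, 4)], 6),
        (6, [(0, 2), (3, 5)], 8),
        (7, [(0, 6), (2, 4)], 9),
        (8, [(0, 7), (1, 6), (3, 5)], 10),
        (8, [(0, 3), (4, 7)], 12),
    ])
    def test_matches_enumeration(self, random_profile_factory, length, pairs,
                                 win_len):
        rng = np.random.default_rng(length * 100 + win_len)
        profile = random_profile_factory(length, pairs, seed=length)
        for _ in range(3):
            window = "".join(rng.choice(list("ACGUN"), size=win_len,
                                        p=[0.23, 0.23, 0.23, 0.23, 0.08]))
            dp, _trace = score_window(profile, window, SMALL_CFG)
            assert dp == pytest.approx(oracle_score(profile, window, SMALL_CFG),
                                       abs=1e-9)

    def test_banded_dp_matches_unbanded_at_wide_band(
            self, random_profile_factory):
        profile = random_profile_factory(6, pairs=[(0, 5), (1, 4)], seed=8)
        rng = np.random.default_rng(0)
        window = "".join(rng.choice(list("ACGU"), size=8))
        import dataclasses
        banded = dataclasses.replace(SMALL_CFG, dp_band=20)
        s1, _ = score_window(profile, window, SMALL_CFG)
        s2, _ = score_window(profile, window, banded)
        assert s1 == pytest.approx(s2)


class TestPairMonotonicity:
    def test_adding_satisfied_pair_never_decreases_score(
            self, random_profile_factory):
        """Canonical pair bonus is non-negative, so a window whose optimal
        trace closes the new pair canonically can only gain."""
        rng = np.random.default_rng(3)
        base = random_profile_factory(6, pairs=[], seed=6)
        paired = random_profile_factory(6, pairs=[(0, 5)], seed=6)
        for _ in range(10):
            window = "".join(rng.choice(list("ACGU"), size=6))
            s_base, trace = score_window(base, window, SMALL_CFG)
            matched = {c: w for op, c, w in trace if op == "M"}
            if 0 in matched and 5 in matched and \
                    (window[matched[0]], window[matched[5]]) in {
                        ("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"),
                        ("G", "U"), ("U", "G")}:
                s_paired, _ = score_window(paired, window, SMALL_CFG)
                assert s_paired >= s_base - 1e-9


@pytest.fixture(scope="module")
def planted_setup():
    spec = FamilySpec(seed=42, subst_rate=0.05, compensatory_prob=0.95,
                      indel_rate=0.0)
    fam = sample_family(spec)
    profile = build_profile(fam.to_alignment(),
                            feature_cols=spec.feature_cols)
    genomes, truth = plant(fam, 2500, seed=7)
    return spec, fam, profile, genomes, truth


class TestScan:
    def test_planted_intervals_are_top_hits(self, planted_setup):
        spec, fam, profile, genomes, truth = planted_setup
        cfg = ScanConfig(score_threshold=20.0)
        hits = scan(profile, genomes, cfg)
        by_target = {}
        for h in hits:
            by_target.setdefault(h.target_id, h)  # first = best (sorted)
        for _, row in truth.iterrows():
            top = by_target[row.genome_id]
            assert (top.start, top.end, top.strand) == \
                (row.start, row.end, row.strand)

    def test_strand_symmetry(self, planted_setup):
        """Scanning the reverse-complemented genome flips strand and mirrors
        coordinates but preserves scores."""
        spec, fam, profile, genomes, truth = planted_setup
        cfg = ScanConfig(score_threshold=20.0)
        gid, seq = genomes[0]
        fwd = scan(profile, [(gid, seq)], cfg)
        rev = scan(profile, [(gid, revcomp_dna(seq))], cfg)
        n = len(seq)
        assert len(fwd) == len(rev)
        for hf, hr in zip(fwd, rev):
            assert hf.score == pytest.approx(hr.score, abs=1e-9)
            assert (hf.start, hf.end) == (n - hr.end, n - hr.start)
            assert {hf.strand, hr.strand} == {"+", "-"}

    def test_empty_targets_empty_hits(self, planted_setup):
        _, _, profile, _, _ = planted_setup
        assert scan(profile, [], ScanConfig()) == []

    def test_hits_sorted_by_score(self, planted_setup):
        spec, fam, profile, genomes, truth = planted_setup
        hits = scan(profile, genomes, ScanConfig(score_threshold=20.0))
        scores = [h.score for h in hits]
        assert scores == sorted(scores, reverse=True)

    def test_hit_tables_render(self, planted_setup):
        spec, fam, profile, genomes, truth = planted_setup
        hits = scan(profile, genomes[:1], ScanConfig(score_threshold=20.0))
        table = hits_to_table(hits)
        assert table.startswith("target\t")
        bed = hits_to_bed(hits)
        assert bed.split("\t")[0] == hits[0].target_id

    def test_hit_requires_valid_interval(self):
        with pytest.raises(ValueError):
            Hit(target_id="x", start=5, end=5, strand="+", score=1.0, trace=[])


class TestNullCalibration:
    def test_shuffle_preserves_dinucleotide_counts(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=300,
                                 p=[0.4, 0.1, 0.2, 0.3]))

        def dinucs(s):
            counts = {}
            for a, b in zip(s, s[1:]):
                counts[a + b] = counts.get(a + b, 0) + 1
            return counts

        for k in range(20):
            shuf = dinucleotide_shuffle(seq, rng)
            assert dinucs(shuf) == dinucs(seq)
            assert shuf[0] == seq[0] and shuf[-1] == seq[-1]

    def test_shuffles_differ_from_input(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), size=300))
        assert dinucleotide_shuffle(seq, rng) != seq

    def test_zero_shuffles_rejected(self, planted_setup):
        _, _, profile, genomes, _ = planted_setup
        with pytest.raises(ValueError, match="null_shuffles"):
            calibrate_null(profile, genomes[:1], ScanConfig(null_shuffles=0))

    def test_evalue_monotone_nonincreasing(self):
        null = [1.0, 2.0, 5.0, 9.0]
        es = [empirical_evalue(s, null) for s in (0.0, 1.5, 5.0, 10.0)]
        assert es == sorted(es, reverse=True)
        assert es[0] == 1.0 and es[-1] == 0.0

    def test_threshold_above_null_max_gives_no_background_hits(self):
        """Score threshold calibrated from the shuffled-null maximum keeps a
        background-only genome hit-free."""
        spec = FamilySpec(seed=5, subst_rate=0.05, indel_rate=0.0)
        fam = sample_family(spec)
        profile = build_profile(fam.to_alignment(),
                                feature_cols=spec.feature_cols)
        rng = np.random.default_rng(123)
        background = [("bg", "".join(rng.choice(list("ACGT"), size=1500)))]
        cfg = ScanConfig(null_shuffles=30, seed=9, score_threshold=-1e12)
        null_scores = calibrate_null(profile, background, cfg)
        threshold = max(null_scores) + 1.0
        hits = scan(profile, background,
                    ScanConfig(score_threshold=threshold))
        assert hits == []
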