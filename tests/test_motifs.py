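"""PWM parsing, MATCH-style scoring and the ordered module search."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from enhmap.annotate import GeneModel
from enhmap.intervals import ParseError
from enhmap.motifs import (
    PWM,
    Segment,
    best_ordered_module,
    compare_score_groups,
    control_segments,
    extract_segments,
    match_score,
    pwm_from_consensus,
    read_pwm,
    revcomp,
    scan_scores,
    write_jaspar,
)

from test_binding import make_bi


def brute_force_match(pwm, window):
    """Independent arithmetic for one window's matrix-similarity score."""
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    cur = lo = hi = 0.0
    for i, b in enumerate(window.upper()):
        w = [pwm.info[i] * pwm.freq[i, k] for k in range(4)]
        cur += min(w) if b == "N" else w[idx[b]]
        lo += min(w)
        hi += max(w)
    return 0.0 if hi <= lo else (cur - lo) / (hi - lo)


class TestPwmConstruction:
    def test_uniform_column_has_zero_information(self):
        pwm = PWM.from_counts("u", np.full((3, 4), 25.0))
        assert np.allclose(pwm.info, 0.0)

    def test_degenerate_column_approaches_ln4(self):
        counts = np.array([[100.0, 0, 0, 0]])
        pwm = PWM.from_counts("d", counts, pseudocount=1e-9)
        assert pwm.info[0] == pytest.approx(math.log(4), abs=1e-6)

    def test_information_vector_matches_hand_arithmetic(self):
        counts = np.array([[8.0, 0, 0, 0], [2.0, 2, 2, 2], [0.0, 6, 2, 0]])
        pwm = PWM.from_counts("toy", counts, pseudocount=0.01)
        for i in range(3):
            f = counts[i] / counts[i].sum() + 0.01
            f = f / f.sum()
            expected = sum(x * math.log(4 * x) for x in f)
            assert pwm.info[i] == pytest.approx(expected)

    def test_jaspar_round_trip(self, tmp_path):
        counts = np.array([[10.0, 2, 3, 5], [1.0, 1, 17, 1], [4.0, 4, 4, 8]])
        path = tmp_path / "toy.jaspar"
        write_jaspar("toy", counts, path)
        pwm = read_pwm(path)
        assert pwm.length == 3
        ref = PWM.from_counts("toy", counts)
        assert np.allclose(pwm.freq, ref.freq)

    def test_malformed_matrix_rejected(self, tmp_path):
        path = tmp_path / "bad.jaspar"
        path.write_text(">bad bad\nA [ 1 2 ]\nC [ 1 2 ]\n")
        with pytest.raises(ParseError):
            read_pwm(path)


class TestMatchScore:
    def test_consensus_scores_one_anticonsensus_zero(self):
        pwm = pwm_from_consensus("m", "TGACGTCA")
        assert match_score(pwm, "TGACGTCA") == pytest.approx(1.0)
        worst = "".join(
            "ACGT"[int(np.argmin(pwm.freq[i]))] for i in range(pwm.length)
        )
        assert match_score(pwm, worst) == pytest.approx(0.0)

    def test_all_64_trimers_match_brute_force(self):
        counts = np.array([[8.0, 1, 1, 0], [0.0, 5, 3, 2], [1.0, 1, 1, 7]])
        pwm = PWM.from_counts("t", counts)
        scores = {}
        for trimer in itertools.product("ACGT", repeat=3):
            w = "".join(trimer)
            scores[w] = match_score(pwm, w)
            assert scores[w] == pytest.approx(brute_force_match(pwm, w))
        assert max(scores.values()) == pytest.approx(1.0)
        assert min(scores.values()) == pytest.approx(0.0)

    def test_case_insensitive_and_n_no_higher_than_worst_base(self):
        pwm = pwm_from_consensus("m", "GTTGCC")
        assert match_score(pwm, "gttgcc") == match_score(pwm, "GTTGCC")
        with_n = match_score(pwm, "GTNGCC")
        worst_scores = [
            match_score(pwm, "GT" + b + "GCC") for b in "ACGT"
        ]
        assert with_n <= min(worst_scores) + 1e-12

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            match_score(pwm_from_consensus("m", "ACGT"), "ACG")

    def test_scan_matches_per_window_scores(self):
        pwm = pwm_from_consensus("m", "TGAC")
        seq = "TTTGACGTACGTTGAC"
        scores = scan_scores(pwm, seq)
        for i in range(len(seq) - 3):
            assert scores[i] == pytest.approx(match_score(pwm, seq[i : i + 4]))


class TestExtractSegments:
    def test_window_centred_on_summit(self):
        genome = {"toy": "ACGT" * 2500}
        bi = make_bi(900, 1100)
        bi.summit = 1000
        (seg,) = extract_segments([bi], genome)
        assert seg.start == 925 and len(seg.sequence) == 150
        assert seg.sequence == genome["toy"][925:1075].upper()

    def test_summit_near_contig_edge_dropped(self, caplog):
        genome = {"toy": "ACGT" * 2500}
        bi = make_bi(0, 60)
        bi.summit = 10
        assert extract_segments([bi], genome) == []


class TestBestOrderedModule:
    def test_planted_consensus_in_order_scores_one(self):
        pwms = [
            pwm_from_consensus("RFX5", "GTTGCCATGGCAAC"),
            pwm_from_consensus("CREB", "TGACGTCA"),
            pwm_from_consensus("NFY", "AGCCAATCA"),
        ]
        spacer = "TT" * 10
        seq = (
            "GTTGCCATGGCAAC" + spacer + "TGACGTCA" + spacer + "AGCCAATCA"
        ).ljust(150, "T")
        hit = best_ordered_module(seq, pwms)
        assert hit.order_valid and hit.avg_score == pytest.approx(1.0)
        starts = [p.start for p in hit.placements]
        assert starts == [0, 34, 62]

    def test_all_n_segment_scores_zero(self):
        pwms = [pwm_from_consensus("a", "ACGT"), pwm_from_consensus("b", "GGCC")]
        hit = best_ordered_module("N" * 150, pwms)
        assert hit.avg_score == pytest.approx(0.0)

    def test_reverse_orientation_found(self):
        pwms = [pwm_from_consensus("a", "GTTGCC"), pwm_from_consensus("b", "TGACGT")]
        fwd = ("GTTGCC" + "AA" * 5 + "TGACGT").ljust(60, "A")
        hit = best_ordered_module(revcomp(fwd), pwms)
        assert hit.avg_score == pytest.approx(1.0)
        assert all(p.strand == "-" for p in hit.placements)

    def test_sum_of_lengths_exceeding_segment_rejected(self):
        pwms = [pwm_from_consensus("a", "A" * 80), pwm_from_consensus("b", "C" * 80)]
        with pytest.raises(ValueError):
            best_ordered_module("A" * 150, pwms)

    def test_matches_exhaustive_placement_oracle(self, rng):
        bases = np.array(list("ACGT"))
        pwms = [
            pwm_from_consensus("m1", "GTAC", strength=0.8),
            pwm_from_consensus("m2", "CCGG", strength=0.8),
            pwm_from_consensus("m3", "TTAA", strength=0.8),
        ]
        for _ in range(20):
            seq = "".join(rng.choice(bases, size=60))
            hit = best_ordered_module(seq, pwms)
            # cubic enumeration over ordered non-overlapping placements,
            # both orientations, forward preferred on ties
            best = (-1.0, None, None)
            for strand, s in (("+", seq), ("-", revcomp(s) if False else revcomp(seq))):
                arr = [scan_scores(p, s) for p in pwms]
                n = len(s)
                for i in range(n - 3):
                    for j in range(i + 4, n - 3):
                        for k in range(j + 4, n - 3):
                            avg = (arr[0][i] + arr[1][j] + arr[2][k]) / 3
                            if avg > best[0] + 1e-12:
                                best = (avg, strand, (i, j, k))
            assert hit.avg_score == pytest.approx(best[0])

    def test_scrambling_one_motif_lowers_score(self, rng):
        pwms = [
            pwm_from_consensus("RFX5", "GTTGCCATGGCAAC"),
            pwm_from_consensus("CREB", "TGACGTCA"),
            pwm_from_consensus("NFY", "AGCCAATCA"),
        ]
        background = "".join(np.random.default_rng(7).choice(list("ACGT"), size=150))
        def plant(motifs):
            s = list(background)
            pos = 10
            for m in motifs:
                s[pos : pos + len(m)] = m
                pos += len(m) + 15
            return "".join(s)

        intact = plant(["GTTGCCATGGCAAC", "TGACGTCA", "AGCCAATCA"])
        scrambled = plant(["GTTGCCATGGCAAC", "ATCGGACT", "AGCCAATCA"])
        full = best_ordered_module(intact, pwms).avg_score
        broken = best_ordered_module(scrambled, pwms).avg_score
        assert full == pytest.approx(1.0)
        assert broken < full


class TestControlSegments:
    def _toy(self, rng, n_genes=30, contig_len=100_000):
        bases = np.array(list("ACGT"))
        genome = {"toy": "".join(rng.choice(bases, size=contig_len))}
        genes = [
            GeneModel(f"g{i}", "toy", 11_000 + i * 1_500, "+" if i % 2 else "-")
            for i in range(n_genes)
        ]
        return genome, genes

    def test_deterministic_given_seed(self, rng):
        genome, genes = self._toy(rng)
        a = control_segments(genes, genome, n_genes=10, seed=42)
        b = control_segments(genes, genome, n_genes=10, seed=42)
        assert [s.sequence for s in a] == [s.sequence for s in b]
        c = control_segments(genes, genome, n_genes=10, seed=43)
        assert [s.sequence for s in a] != [s.sequence for s in c]

    def test_all_segments_have_required_length(self, rng):
        genome, genes = self._toy(rng)
        segs = control_segments(genes, genome, n_genes=20, seed=0)
        assert all(len(s.sequence) == 150 for s in segs)

    def test_start_offsets_uniform_over_window(self, rng):
        genome, genes = self._toy(rng, n_genes=50)
        offsets = []
        for seed in range(200):
            for s in control_segments(genes, genome, n_genes=50, seed=seed):
                g = next(g for g in genes if s.source == f"control|{g.gene_id}")
                if g.strand == "+":
                    off = s.start - (g.tss - 10_000)
                else:
                    off = (g.tss + 10_000 + 1) - (s.start + 150)
                offsets.append(off)
        # 10,000 draws over window offsets [0, 10_000]
        counts, _ = np.histogram(offsets, bins=20, range=(0, 10_001))
        chi = stats.chisquare(counts)
        assert chi.pvalue > 0.01


class TestCompareScoreGroups:
    def test_identical_groups_not_significant(self):
        res = compare_score_groups([1, 2, 3], [1, 2, 3])
        assert res.pvalue > 0.9

    def test_fully_separated_small_groups_exact_p(self):
        # U = 0; exact two-sided p over all C(6,3)=20 arrangements is 0.1
        res = compare_score_groups([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.pvalue == pytest.approx(0.1)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_score_groups([], [1.0])

    def test_matches_exact_enumeration_small_groups(self, rng):
        # tie-free groups of sizes <= 5: exact p by enumeration
        for _ in range(5):
            vals = rng.permutation(np.arange(1.0, 9.0))
            a, b = vals[:4], vals[4:]
            res = compare_score_groups(a, b)
            # enumerate all assignments of ranks to group a
            from itertools import combinations

            allv = np.concatenate([a, b])
            ranks = stats.rankdata(allv)
            ra = ranks[:4].sum()
            u_obs = ra - 4 * 5 / 2
            us = []
            for comb in combinations(range(8), 4):
                r = ranks[list(comb)].sum()
                us.append(r - 4 * 5 / 2)
            us = np.array(us)
            # two-sided: double the smaller tail (point mass included)
            p_le = np.mean(us <= u_obs)
            p_ge = np.mean(us >= u_obs)
            expected = min(1.0, 2 * min(p_le, p_ge))
            assert res.pvalue == pytest.approx(expected)
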