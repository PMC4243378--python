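"""Allele counting from SAM, ASB pooling, PWM deltas and eQTL OLS."""

import numpy as np
import pytest
from scipy import stats

from enhmap.allelic import (
    AlleleCounts,
    allele_pwm_delta,
    asb_test,
    count_alleles,
    eqtl_association,
    integrate_trans_network,
    read_allele_counts,
    EqtlResult,
)
from enhmap.motifs import pwm_from_consensus
from enhmap.synthetic_data import generate_allelic_reads, write_allele_counts, write_sam


def ac(count_a, count_b, individual="i", snp_id="rs1"):
    return AlleleCounts(
        snp_id=snp_id,
        chrom="toy",
        pos=500,
        allele_a="A",
        allele_b="G",
        count_a=count_a,
        count_b=count_b,
        individual=individual,
    )


class TestCountAlleles:
    def test_generated_reads_recover_planted_counts_exactly(self, rng, tmp_path):
        (counts,) = generate_allelic_reads(
            ratio=0.66, depth=100, n_individuals=1, seed=5
        )
        sam = write_sam(counts, tmp_path / "x.sam", seed=6)
        got = count_alleles(str(sam), ("rs_sim1", counts.chrom, counts.pos, "A", "G"))
        assert (got.count_a, got.count_b) == (counts.count_a, counts.count_b)
        assert got.count_other == 0

    def test_all_reads_single_allele(self, tmp_path):
        c = ac(10, 0)
        sam = write_sam(c, tmp_path / "a.sam", seed=1)
        got = count_alleles(str(sam), ("rs1", "toy", 500, "A", "G"))
        assert (got.count_a, got.count_b) == (10, 0)

    def test_no_covering_reads(self, tmp_path):
        c = ac(5, 5)
        sam = write_sam(c, tmp_path / "a.sam", seed=1)
        got = count_alleles(str(sam), ("rs1", "toy", 90_000, "A", "G"))
        assert (got.count_a, got.count_b) == (0, 0)

    def test_position_off_reference_rejected(self, tmp_path):
        c = ac(2, 2)
        sam = write_sam(c, tmp_path / "a.sam", seed=1)
        with pytest.raises(ValueError, match="beyond end"):
            count_alleles(str(sam), ("rs1", "toy", 500_000, "A", "G"))
        with pytest.raises(ValueError, match="absent"):
            count_alleles(str(sam), ("rs1", "chrMissing", 500, "A", "G"))

    def test_quality_and_flag_filters(self, tmp_path):
        # one good read (A), one low-MAPQ (A), one duplicate-flagged (A),
        # one third-allele read (C)
        lines = [
            "@HD\tVN:1.6\tSO:unsorted",
            "@SQ\tSN:toy\tLN:1000",
            "r1\t0\ttoy\t491\t60\t21M\t*\t0\t0\t" + "C" * 10 + "A" + "C" * 10 + "\t" + "I" * 21,
            "r2\t0\ttoy\t491\t5\t21M\t*\t0\t0\t" + "C" * 10 + "A" + "C" * 10 + "\t" + "I" * 21,
            "r3\t1024\ttoy\t491\t60\t21M\t*\t0\t0\t" + "C" * 10 + "A" + "C" * 10 + "\t" + "I" * 21,
            "r4\t0\ttoy\t491\t60\t21M\t*\t0\t0\t" + "T" * 10 + "C" + "T" * 10 + "\t" + "I" * 21,
        ]
        sam = tmp_path / "f.sam"
        sam.write_text("\n".join(lines) + "\n")
        got = count_alleles(str(sam), ("rs1", "toy", 500, "A", "G"))
        assert got.count_a == 1 and got.count_b == 0 and got.count_other == 1

    def test_counts_table_round_trip(self, tmp_path):
        counts = generate_allelic_reads(depth=50, n_individuals=3, seed=2)
        path = tmp_path / "counts.tsv"
        write_allele_counts(counts, path)
        back = read_allele_counts(path)
        assert [(c.count_a, c.count_b) for c in back] == [
            (c.count_a, c.count_b) for c in counts
        ]


class TestAsbTest:
    def test_balanced_fractions_not_significant(self):
        res = asb_test([ac(50, 50, "a"), ac(50, 50, "b"), ac(50, 50, "c")])
        assert res.mean_pct == pytest.approx(50.0)
        assert res.pvalue == pytest.approx(1.0)

    def test_degenerate_all_one_reported_with_warning(self):
        with pytest.warns(UserWarning, match="degenerate"):
            res = asb_test([ac(20, 0, "a"), ac(20, 0, "b"), ac(20, 0, "c")])
        assert res.mean_pct == pytest.approx(100.0)
        assert res.sd_pct == 0.0
        assert 0 < res.pvalue < 1e-200

    def test_label_symmetry(self):
        counts = [ac(70, 30, "a"), ac(55, 45, "b"), ac(66, 34, "c"), ac(61, 39, "d")]
        swapped = [
            AlleleCounts(
                snp_id=c.snp_id,
                chrom=c.chrom,
                pos=c.pos,
                allele_a=c.allele_b,
                allele_b=c.allele_a,
                count_a=c.count_b,
                count_b=c.count_a,
                individual=c.individual,
            )
            for c in counts
        ]
        r1, r2 = asb_test(counts), asb_test(swapped)
        assert r1.mean_pct == pytest.approx(100 - r2.mean_pct)
        assert r1.sd_pct == pytest.approx(r2.sd_pct)
        assert r1.pvalue == pytest.approx(r2.pvalue)

    def test_fewer_than_two_usable_individuals_rejected(self):
        with pytest.raises(ValueError):
            asb_test([ac(10, 5, "a")])
        with pytest.raises(ValueError):
            asb_test([ac(10, 5, "a"), ac(0, 0, "b")])

    def test_per_individual_binomial_pvalues(self):
        res = asb_test([ac(80, 20, "a"), ac(50, 50, "b")])
        expected = stats.binomtest(80, 100, 0.5).pvalue
        assert res.binomial_p[0] == pytest.approx(expected)
        assert res.binomial_p[1] == pytest.approx(1.0)


class TestAllelePwmDelta:
    def test_worst_base_substitution_lowers_score(self):
        pwm = pwm_from_consensus("m", "GGGGAAAT")
        ref = "GGGGAAAT"
        worst = int(np.argmin(pwm.freq[0]))
        alt = "ACGT"[worst] + ref[1:]
        s_ref, s_alt, delta = allele_pwm_delta(pwm, ref, alt)
        assert s_ref == pytest.approx(1.0) and delta > 0

    def test_identical_windows_rejected(self):
        pwm = pwm_from_consensus("m", "ACGT")
        with pytest.raises(ValueError):
            allele_pwm_delta(pwm, "ACGT", "ACGT")
        with pytest.raises(ValueError):
            allele_pwm_delta(pwm, "ACGT", "TGCA")

    def test_probe_pair_favours_ancestral_allele(self):
        # EMSA-style probe pair differing at one position, scored with a toy
        # NF-KB-like matrix whose consensus covers the A-allele core
        pwm = pwm_from_consensus("NFKB", "GGGGAAATGTCT")
        probe_a = "AGCTGAAAAGGGGAAATGTCTGAAA"
        probe_g = "AGCTGAAAAGGGGGAATGTCTGAAA"
        s_a, s_g, delta = allele_pwm_delta(pwm, probe_a, probe_g)
        assert s_a == pytest.approx(1.0)
        assert delta > 0


class TestEqtlAssociation:
    def test_constant_dosage_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            eqtl_association([1, 1, 1, 1], [0.1, 0.2, 0.3, 0.4])

    def test_exact_linear_relation_recovers_slope(self):
        rng = np.random.default_rng(0)
        g = rng.binomial(2, 0.4, 50).astype(float)
        y = 2.0 * g
        res = eqtl_association(g, y)
        assert res.beta == pytest.approx(2.0)
        assert res.pvalue < 1e-50

    def test_covariates_absorb_confounding(self):
        rng = np.random.default_rng(1)
        n = 200
        g = rng.binomial(2, 0.3, n).astype(float)
        pc = rng.normal(size=n)
        y = 0.0 * g + 3.0 * pc + rng.normal(0, 0.1, n)
        naive = eqtl_association(g, y)
        adjusted = eqtl_association(g, y, covariates=pc[:, None])
        assert abs(adjusted.beta) < 0.1
        assert adjusted.se < naive.se

    def test_rank_deficient_design_rejected(self):
        rng = np.random.default_rng(2)
        g = rng.binomial(2, 0.3, 30).astype(float)
        with pytest.raises(ValueError, match="rank deficient"):
            eqtl_association(g, rng.normal(size=30), covariates=np.column_stack([g, g]))

    def test_cis_trans_labels_follow_1mb_window(self):
        rng = np.random.default_rng(3)
        g = rng.binomial(2, 0.3, 30).astype(float)
        y = rng.normal(size=30)
        near = eqtl_association(
            g, y, snp_pos=("chr16", 10_900_000), gene_tss=("chr16", 10_500_000)
        )
        far = eqtl_association(
            g, y, snp_pos=("chr16", 10_900_000), gene_tss=("chr16", 12_000_000)
        )
        other = eqtl_association(
            g, y, snp_pos=("chr16", 10_900_000), gene_tss=("chr6", 10_900_000)
        )
        assert (near.label, far.label, other.label) == ("cis", "trans", "trans")

    def test_permuted_dosage_pvalues_uniform(self):
        rng = np.random.default_rng(11)
        n = 100
        g = rng.binomial(2, 0.3, n).astype(float)
        y = 0.8 * g + rng.normal(0, 1, n)
        pvals = []
        for _ in range(400):
            perm = rng.permutation(g)
            if np.ptp(perm) == 0:
                continue
            pvals.append(eqtl_association(perm, y).pvalue)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestIntegrateTransNetwork:
    def _results(self, entries):
        return [
            EqtlResult("rs1", g, 0.5, 0.1, p, label, 100) for g, p, label in entries
        ]

    def test_empty_results(self):
        table = integrate_trans_network([], 0.05, {"g1"})
        assert len(table) == 0 and table.attrs["n_supported"] == 0

    def test_threshold_one_passes_everything_trans(self):
        res = self._results(
            [("g1", 0.9, "trans"), ("g2", 0.5, "trans"), ("c1", 0.001, "cis")]
        )
        table = integrate_trans_network(res, 1.0, {"g1"})
        assert set(table.gene_id) == {"g1", "g2"}

    def test_planted_network_support_counts(self):
        entries = [(f"s{i}", 1e-6, "trans") for i in range(8)]
        entries += [(f"u{i}", 1e-6, "trans") for i in range(4)]
        entries += [(f"bg{i}", 0.4, "trans") for i in range(20)]
        table = integrate_trans_network(
            self._results(entries), 3e-4, {f"s{i}" for i in range(8)}
        )
        assert len(table) == 12
        assert table.attrs["n_supported"] == 8
        assert table.attrs["n_unsupported"] == 4
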