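"""QC filters: exact HWE test, call rate, sex check, platform
intersection, fixed-order bookkeeping."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from multihet import qc
from multihet.containers import GenotypeMatrix
from multihet.simulate import SimulationConfig, draw_truth, \
    simulate_genotypes
from multihet.studies import qc_fixture


def oracle_hwe(n_aa, n_ab, n_bb):
    """Exact-arithmetic enumeration over all attainable heterozygote
    counts: weight(h) = 2**h * n! / (a! h! c!), p = tail/total."""
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    rare = min(n_a, n_b)
    weights = {}
    for h in range(rare % 2, rare + 1, 2):
        a = (n_a - h) // 2
        c = (n_b - h) // 2
        weights[h] = (2 ** h) * math.factorial(n) // (
            math.factorial(a) * math.factorial(h) * math.factorial(c))
    total = sum(weights.values())
    obs = weights[n_ab]
    tail = sum(w for w in weights.values() if w <= obs)
    return Fraction(tail, total)


class TestHweExactTest:
    def test_monomorphic_p_is_one(self):
        assert qc.hwe_exact_test(0, 0, 25) == 1.0
        assert qc.hwe_exact_test(25, 0, 0) == 1.0

    def test_two_homozygotes(self):
        # (1,0,1): attainable h in {0,2} with weights 2 and 4 -> p = 1/3
        assert qc.hwe_exact_test(1, 0, 1) == pytest.approx(1 / 3)

    def test_all_counts_zero_rejected(self):
        with pytest.raises(ValueError):
            qc.hwe_exact_test(0, 0, 0)
        with pytest.raises(ValueError):
            qc.hwe_exact_test(-1, 2, 0)

    @given(st.integers(0, 30), st.integers(0, 30), st.integers(0, 30))
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_matches_enumeration_oracle(self, n_aa, n_ab, n_bb):
        if n_aa + n_ab + n_bb == 0:
            return
        p = qc.hwe_exact_test(n_aa, n_ab, n_bb)
        assert p == pytest.approx(float(oracle_hwe(n_aa, n_ab, n_bb)),
                                  abs=1e-10)

    def test_distribution_normalized(self):
        for n_a, n_b in [(10, 10), (7, 13), (1, 49), (0, 20)]:
            _, probs = qc.het_count_distribution(n_a, n_b)
            assert probs.sum() == pytest.approx(1.0)

    def test_midp_smaller_than_standard(self):
        assert qc.hwe_exact_test(5, 10, 5, midp=True) < \
            qc.hwe_exact_test(5, 10, 5)


class TestCallRateFilter:
    def make(self, missing_per_sample):
        m = 100
        g = np.zeros((len(missing_per_sample), m), dtype=np.int8)
        for i, k in enumerate(missing_per_sample):
            g[i, :k] = -1
        return GenotypeMatrix(g, [f"i{i}" for i in
                                  range(len(missing_per_sample))],
                              [f"s{j}" for j in range(m)])

    def test_strict_inequality_boundary(self):
        # 96/100 excluded, exactly 97/100 retained
        geno = self.make([4, 3, 0])
        rep = qc.filter_sample_call_rate(geno, 0.97)
        assert rep.samples_excluded_for(qc.LOW_CALL_RATE) == ["i0"]

    def test_no_missingness_no_exclusions(self):
        rep = qc.filter_sample_call_rate(self.make([0, 0]), 0.97)
        assert rep.excluded_samples == []

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            qc.filter_sample_call_rate(
                GenotypeMatrix(np.zeros((0, 0), dtype=np.int8), [], []),
                0.97)


class TestHweFilterInControls:
    def test_monomorphic_in_controls_retained(self):
        g = np.array([[0, 1], [0, 1], [0, 1], [1, 1]], dtype=np.int8)
        geno = GenotypeMatrix(g, ["a", "b", "c", "d"], ["s0", "s1"])
        samples = pd.DataFrame({
            "case_status": ["control", "control", "control", "case"]},
            index=["a", "b", "c", "d"])
        rep = qc.filter_hwe_in_controls(geno, samples, alpha=1e-4)
        assert rep.snps_excluded_for(qc.HWE_FAIL) == []

    def test_all_controls_heterozygous_excluded(self):
        n_ctl = 50
        g = np.ones((n_ctl + 5, 1), dtype=np.int8)
        ids = [f"i{i}" for i in range(n_ctl + 5)]
        geno = GenotypeMatrix(g, ids, ["s0"])
        samples = pd.DataFrame(
            {"case_status": ["control"] * n_ctl + ["case"] * 5},
            index=ids)
        assert float(oracle_hwe(0, n_ctl, 0)) < 1e-4
        rep = qc.filter_hwe_in_controls(geno, samples, alpha=1e-4)
        assert rep.snps_excluded_for(qc.HWE_FAIL) == ["s0"]

    def test_no_controls_rejected(self):
        g = GenotypeMatrix(np.zeros((2, 2), dtype=np.int8),
                           ["a", "b"], ["s0", "s1"])
        samples = pd.DataFrame({"case_status": ["case", "case"]},
                               index=["a", "b"])
        with pytest.raises(ValueError, match="control"):
            qc.filter_hwe_in_controls(g, samples)

    def test_type1_error_conservative(self):
        # HWE-true simulated genotypes: exclusion rate <= alpha within
        # binomial error (the exact test is conservative)
        alpha = 0.01
        m = 8000
        c = SimulationConfig(n_individuals=150, n_snps=m, f_mean=0.0,
                             f_sd=0.0, maf_low=0.1, missing_rate=0.0,
                             seed=9)
        truth = draw_truth(c)
        geno = simulate_genotypes(truth.subpop_freqs, truth, c)
        samples = pd.DataFrame({"case_status": "control"},
                               index=geno.sample_ids)
        rep = qc.filter_hwe_in_controls(geno, samples, alpha=alpha)
        frac = len(rep.snps_excluded_for(qc.HWE_FAIL)) / m
        assert frac <= alpha + 3 * np.sqrt(alpha * (1 - alpha) / m)
        assert frac >= alpha / 20  # it does reject sometimes


class TestSexCheck:
    def build(self, x_rows, reported, n_x=60):
        # x_rows: per-sample heterozygous X count
        n = len(x_rows)
        g = np.zeros((n, 20 + n_x), dtype=np.int8)
        for i, k in enumerate(x_rows):
            g[i, 20:20 + k] = 1
        ids = [f"i{i}" for i in range(n)]
        geno = GenotypeMatrix(g, ids, [f"s{j}" for j in range(20 + n_x)])
        ann = pd.DataFrame({
            "chrom": ["1"] * 20 + ["X"] * n_x,
            "pos": np.arange(1, 21 + n_x),
            "is_autosomal": [True] * 20 + [False] * n_x,
            "gene_id": None, "is_nonsynonymous": False, "platforms": "",
        }, index=geno.snp_ids)
        samples = pd.DataFrame({"reported_sex": reported,
                                "case_status": "control"}, index=ids)
        return geno, ann, samples

    def test_consistent_male_retained(self):
        geno, ann, samples = self.build([0], ["male"])
        rep = qc.check_sex_consistency(geno, ann, samples)
        assert rep.excluded_samples == []

    def test_heterozygous_reported_male_excluded(self):
        geno, ann, samples = self.build([0, 18, 30], ["male", "male",
                                                      "female"])
        rep = qc.check_sex_consistency(geno, ann, samples, hi=0.20)
        assert rep.samples_excluded_for(qc.SEX_MISMATCH) == ["i1"]

    def test_all_autosomal_panel_skips(self):
        geno, ann, samples = self.build([0], ["male"], n_x=60)
        ann["is_autosomal"] = True
        rep = qc.check_sex_consistency(geno, ann, samples)
        assert rep.excluded_samples == []
        assert any("skipped" in m for m in rep.messages)

    def test_indeterminate_retained_with_warning(self):
        geno, ann, samples = self.build([6], ["male"])  # rate 0.1
        rep = qc.check_sex_consistency(geno, ann, samples)
        assert rep.excluded_samples == []
        assert any("indeterminate" in m for m in rep.messages)


class TestPlatformIntersection:
    def ann(self, platform_lists):
        return pd.DataFrame({
            "chrom": "1", "pos": np.arange(1, len(platform_lists) + 1),
            "is_autosomal": True, "gene_id": None,
            "is_nonsynonymous": False, "platforms": platform_lists,
        }, index=pd.Index([f"s{i}" for i in range(len(platform_lists))],
                          name="snp_id"))

    def test_identical_sets_remove_nothing(self):
        rep = qc.intersect_platforms(self.ann(["A,B", "A,B", "A,B"]))
        assert rep.excluded_snps == []

    def test_set_algebra(self):
        # platform A has {s0,s1,s2}, B has {s1,s2,s3}: keep {s1,s2}
        rep = qc.intersect_platforms(
            self.ann(["A", "A,B", "A,B", "B"]))
        assert rep.snps_excluded_for(qc.PLATFORM_MISMATCH) == ["s0", "s3"]

    def test_single_platform_rejected(self):
        with pytest.raises(ValueError, match="2 named platform"):
            qc.intersect_platforms(self.ann(["A", "A"]))

    def test_empty_intersection_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            qc.intersect_platforms(self.ann(["A", "B"]))


class TestRunQc:
    def test_idempotent(self):
        geno, ann, samples, _ = qc_fixture()
        g1, a1, s1, rep1 = qc.run_qc(geno, ann, samples)
        g2, a2, s2, rep2 = qc.run_qc(g1, a1, s1)
        assert rep2.excluded_samples == []
        assert rep2.excluded_snps == []
        assert g2.n_samples == g1.n_samples
        assert g2.n_snps == g1.n_snps

    def test_first_reason_wins(self):
        geno, ann, samples, _ = qc_fixture()
        _, _, _, rep = qc.run_qc(geno, ann, samples)
        seen = {}
        for sid, reason in rep.excluded_samples + rep.excluded_snps:
            assert sid not in seen
            seen[sid] = reason
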