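"""Generator checks: allele frequencies, genotypes, annotation,
outcome/matching semantics, biomarkers, reproducibility."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from multihet import het
from multihet.simulate import (ConfigurationError, SimulationConfig,
                               assign_outcomes_and_match, draw_truth,
                               simulate_allele_frequencies,
                               simulate_annotation, simulate_biomarkers,
                               simulate_cohort, simulate_genotypes)


def cfg(**kw):
    base = dict(n_individuals=100, n_snps=500, seed=0)
    base.update(kw)
    return SimulationConfig(**base)


class TestAlleleFrequencies:
    def test_zero_divergence_identity(self):
        c = cfg(n_subpops=3, fst=0.0)
        p, sub = simulate_allele_frequencies(c)
        assert sub.shape == (3, c.n_snps)
        assert np.array_equal(sub, np.broadcast_to(p, sub.shape))

    def test_degenerate_maf_interval(self):
        c = cfg(maf_low=0.3, maf_high=0.3)
        p, _ = simulate_allele_frequencies(c)
        assert np.allclose(p, 0.3)

    def test_balding_nichols_variance(self):
        # sample variance of drifted p matches fst * p * (1-p)
        c = cfg(n_snps=10_000, n_subpops=2, fst=0.1,
                maf_low=0.3, maf_high=0.3, seed=3)
        _, sub = simulate_allele_frequencies(c)
        expected = 0.1 * 0.3 * 0.7
        assert sub.min() >= 0 and sub.max() <= 1
        assert np.var(sub[0]) == pytest.approx(expected, rel=0.10)

    @pytest.mark.parametrize("bad", [
        dict(maf_low=0.0), dict(maf_low=0.4, maf_high=0.3),
        dict(maf_high=0.6), dict(f_mean=1.0), dict(fst=1.0),
        dict(n_subpops=0), dict(controls_per_case=0),
        dict(missing_rate=1.0), dict(f_mean=0.5, f_sd=0.6),
    ])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ConfigurationError):
            c = cfg(**bad)
            if "f_sd" in bad:  # Beta constraint raised at draw time
                draw_truth(c)


class TestGenotypes:
    def test_full_autozygosity_kills_heterozygosity(self):
        c = cfg(f_mean=0.9, f_sd=0.0, missing_rate=0.0)
        truth = draw_truth(c)
        truth.f[:] = 1.0
        g = simulate_genotypes(truth.subpop_freqs, truth, c)
        assert (g.genotypes == 1).sum() == 0

    def test_hardy_weinberg_het_fraction(self):
        # F=0, p=0.5: heterozygote fraction 2pq = 0.5
        c = cfg(n_individuals=200, n_snps=500, f_mean=0.0, f_sd=0.0,
                maf_low=0.5, maf_high=0.5, missing_rate=0.0, seed=2)
        truth = draw_truth(c)
        g = simulate_genotypes(truth.subpop_freqs, truth, c)
        frac = (g.genotypes == 1).mean()
        se = np.sqrt(0.25 / g.genotypes.size)
        assert abs(frac - 0.5) < 4 * se

    def test_inbreeding_het_fraction(self):
        # (1-F) * 2pq with F=0.2, p=0.3 -> 0.336
        c = cfg(n_individuals=200, n_snps=1000, f_mean=0.2, f_sd=0.0,
                maf_low=0.3, maf_high=0.3, missing_rate=0.0, seed=4)
        truth = draw_truth(c)
        g = simulate_genotypes(truth.subpop_freqs, truth, c)
        frac = (g.genotypes == 1).mean()
        expected = 0.8 * 2 * 0.3 * 0.7
        se = np.sqrt(expected * (1 - expected) / g.genotypes.size)
        assert abs(frac - expected) < 4 * se

    def test_missingness_rate(self):
        c = cfg(n_individuals=300, n_snps=1000, missing_rate=0.05, seed=5)
        truth = draw_truth(c)
        g = simulate_genotypes(truth.subpop_freqs, truth, c)
        frac = (g.genotypes == -1).mean()
        assert frac == pytest.approx(0.05, rel=0.1)


class TestAnnotation:
    def test_zero_genic_fraction(self):
        ann, genes = simulate_annotation(cfg(genic_fraction=0.0))
        assert genes.empty
        assert ann["gene_id"].isna().all()

    def test_nonsynonymous_inside_gene_bodies(self):
        c = cfg(n_snps=20_000, seed=6)
        ann, genes = simulate_annotation(c)
        ns = ann[ann["is_nonsynonymous"]]
        assert len(ns) > 0
        assert ns["gene_id"].notna().all()
        bodies = genes.set_index("gene_id")
        for sid, row in ns.iterrows():
            b = bodies.loc[row["gene_id"]]
            assert b["start"] <= row["pos"] <= b["end"]
            assert b["chrom"] == row["chrom"]

    def test_full_array_scale_genic_count(self):
        # 692,794 SNPs with default fractions: genic stratum size within
        # 1% of 562,289 after the flank-extension rule
        c = cfg(n_snps=692_794, seed=8)
        ann, genes = simulate_annotation(c)
        stratum = het.define_genic_stratum(ann, genes)
        assert len(stratum.snp_ids) == pytest.approx(562_289, rel=0.01)

    def test_positions_increase_within_chromosome(self):
        ann, _ = simulate_annotation(cfg(n_snps=2000))
        for _, sub in ann.groupby("chrom"):
            assert sub["pos"].is_monotonic_increasing


@pytest.fixture(scope="module")
def cohort():
    return simulate_cohort(
        SimulationConfig(n_individuals=600, n_snps=1500,
                         baseline_prevalence=0.03, n_periods=8,
                         seed=11))


class TestOutcomesAndMatching:

    def test_complete_sets_have_one_case_two_controls(self, cohort):
        s = cohort.samples
        by_set = s.groupby("matched_set_id")["case_status"]
        n_cases = by_set.apply(lambda x: (x == "case").sum())
        n_controls = by_set.apply(lambda x: (x == "control").sum())
        assert (n_cases == 1).all()
        assert n_controls.max() <= 2
        # most sets are complete (converters may vacate a slot)
        assert (n_controls == 2).mean() > 0.5

    def test_controls_match_case_band_and_smoking(self, cohort):
        s = cohort.samples
        for _, grp in s.groupby("matched_set_id"):
            case = grp[grp["case_status"] == "case"].iloc[0]
            ctl = grp[grp["case_status"] == "control"]
            assert (ctl["age_band"] == case["age_band"]).all()
            assert (ctl["smoking"] == case["smoking"]).all()

    def test_risk_set_property(self, cohort):
        # a control's own event time (if any) is strictly later than
        # its case's event time
        s = cohort.samples
        for _, grp in s.groupby("matched_set_id"):
            t_case = grp.loc[grp["case_status"] == "case",
                             "event_time"].iloc[0]
            ctl_t = grp.loc[grp["case_status"] == "control", "event_time"]
            assert (ctl_t.dropna() > t_case).all()

    def test_null_effect_leaves_het_balanced(self):
        # beta=0: case and control het counts differ only by noise
        hits = 0
        for seed in range(20):
            c = simulate_cohort(
                SimulationConfig(n_individuals=400, n_snps=1500,
                                 baseline_prevalence=0.04, n_periods=6,
                                 beta_per_2000=0.0, seed=100 + seed),
                with_biomarkers=False)
            counts = c.cohort_het_counts.loc[c.samples.index]
            ca = counts[c.samples["case_status"] == "case"]
            co = counts[c.samples["case_status"] == "control"]
            p = stats.ttest_ind(ca, co, equal_var=False).pvalue
            hits += p >= 0.01
        assert hits >= 18


class TestBiomarkers:
    def test_noiseless_linear_recovery(self):
        c = SimulationConfig(n_individuals=300, n_snps=800,
                             baseline_prevalence=0.05, n_periods=5,
                             biomarker_gamma_per_2000=1.0,
                             biomarker_noise_sd=0.0, seed=21)
        cohort = simulate_cohort(c)
        s = cohort.samples
        het_c = cohort.cohort_het_counts.loc[s.index]
        resid = (s["hdl"]
                 - c.biomarker_age_coef * (s["age"] - 60.0)
                 - c.biomarker_smoking_coef * s["smoking"])
        assert np.allclose(resid, het_c / 2000.0)

    def test_missing_subset_exact_size(self):
        c = SimulationConfig(n_individuals=300, n_snps=500,
                             baseline_prevalence=0.05, n_periods=5,
                             biomarker_missing_fraction=0.5, seed=22)
        cohort = simulate_cohort(c)
        n = len(cohort.samples)
        n_obs = cohort.samples["crp"].notna().sum()
        assert n_obs == n - round(0.5 * n)


class TestReproducibility:
    def test_identical_config_bit_identical_output(self):
        c = SimulationConfig(n_individuals=150, n_snps=600,
                             baseline_prevalence=0.05, n_periods=5,
                             missing_rate=0.01, seed=33)
        a = simulate_cohort(c)
        b = simulate_cohort(c)
        assert np.array_equal(a.genotypes.genotypes, b.genotypes.genotypes)
        pd.testing.assert_frame_equal(a.samples, b.samples)
        assert np.array_equal(a.truth.f, b.truth.f)
        assert np.array_equal(a.truth.subpop_freqs, b.truth.subpop_freqs)

    def test_het_count_sd_order_of_magnitude(self, small_cohort):
        # with f_sd small the count SD stays within an order of magnitude
        # of the binomial + inbreeding-variance prediction
        counts = small_cohort.cohort_het_counts
        m = small_cohort.config.n_snps
        p = small_cohort.truth.ancestral_freq
        mean_2pq = np.mean(2 * p * (1 - p))
        binom = np.sqrt(m * mean_2pq * (1 - mean_2pq))
        inbr = small_cohort.config.f_sd * m * mean_2pq
        predicted = np.sqrt(binom ** 2 + inbr ** 2)
        assert predicted / 3 < counts.std() < predicted * 3
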