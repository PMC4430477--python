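"""Replicated simulation studies of the pipeline's statistical behaviour.

These functions re-run the generator + analysis many times to measure
calibration properties: confidence-interval coverage and type-I error
under the null, recovery of a planted heterozygosity effect, the effect
of population-stratification confounding with and without eigenvector
adjustment, and the false-positive rate of the biomarker screen. They
back both the test suite and the reproduction script.

Replicates use a scaled-down SNP panel (the panel size only sets the SD
of the heterozygosity exposure; the calibration properties under study
do not depend on it) and skip the QC stage, which is a no-op for clean
simulated data with no missingness.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import assoc, het, strat
from .simulate import (SimulationConfig, assign_outcomes_and_match,
                       draw_truth, simulate_annotation,
                       simulate_biomarkers, simulate_genotypes)

Z95 = assoc.Z95


def _study_design_config(n_snps: int = 20_000, seed: int = 0,
                         **overrides) -> SimulationConfig:
    """Cohort sized to yield roughly 435 cases with 2 matched controls
    each under the default per-period hazard."""
    base = dict(n_individuals=2600, n_snps=n_snps,
                baseline_prevalence=0.022, n_periods=8,
                missing_rate=0.0, seed=seed)
    base.update(overrides)
    return SimulationConfig(**base)


def _one_replicate(config: SimulationConfig, k: int = 3,
                   snp_step: int = 10, adjust: bool = True,
                   ) -> assoc.AssociationResult:
    """simulate -> het -> PCA -> logistic fit for the all-SNPs stratum."""
    rng = config.rng()
    truth = draw_truth(config, rng)
    geno = simulate_genotypes(truth.subpop_freqs, truth, config, rng)
    het_all = (geno.genotypes == 1).sum(axis=1)
    samples = assign_outcomes_and_match(geno, truth, config, rng,
                                        het_counts=het_all)
    sub = geno.subset_samples(samples.index)
    counts = pd.Series(het_all, index=geno.sample_ids).loc[samples.index]
    n_ok = (sub.genotypes != -1).sum(axis=1)
    table = pd.DataFrame({"n_het": counts, "n_nonmissing": n_ok,
                          "proportion": counts / n_ok},
                         index=samples.index)
    covariates = ["age", "smoking"]
    if adjust:
        eig = strat.compute_eigenvectors(sub, k=k, snp_step=snp_step)
        samples = strat.attach_eigenvectors(samples, eig)
        covariates += list(eig.coords.columns)
    return assoc.fit_chd_model(samples, table, het.ALL_AUTOSOMAL,
                               unit=2000.0, covariates=covariates)


@dataclass
class CalibrationSummary:
    n_replicates: int
    coverage: float          # fraction of 95% CIs covering the true OR
    type1_error: float       # fraction of p < 0.05 (null replicates)
    mean_beta: float         # mean log-OR per 2000 loci
    empirical_se: float      # SE of that mean across replicates
    mean_n_cases: float


def null_calibration_study(n_replicates: int = 200, n_snps: int = 20_000,
                           seed: int = 0, beta_per_2000: float = 0.0,
                           snp_step: int = 10) -> CalibrationSummary:
    """Coverage of the 95% CI and type-I error (or bias) of the CHD model
    across study-sized replicates with a known planted effect."""
    rng = np.random.default_rng(seed)
    covered, rejected, betas, n_cases = [], [], [], []
    for _ in range(n_replicates):
        cfg = _study_design_config(
            n_snps=n_snps, seed=int(rng.integers(2 ** 31)),
            beta_per_2000=beta_per_2000)
        res = _one_replicate(cfg, snp_step=snp_step)
        if not res.converged:
            continue
        true_or = float(np.exp(beta_per_2000))
        covered.append(res.ci_low <= true_or <= res.ci_high)
        rejected.append(res.p_value < 0.05)
        betas.append(res.beta_per_unit)
        n_cases.append(res.n_cases)
    betas = np.asarray(betas)
    return CalibrationSummary(
        n_replicates=len(betas),
        coverage=float(np.mean(covered)),
        type1_error=float(np.mean(rejected)),
        mean_beta=float(betas.mean()),
        empirical_se=float(betas.std(ddof=1) / np.sqrt(len(betas))),
        mean_n_cases=float(np.mean(n_cases)))


def effect_recovery_study(n_replicates: int = 100, n_snps: int = 20_000,
                          seed: int = 1,
                          beta_per_2000: float = float(np.log(1.25)),
                          ) -> CalibrationSummary:
    """Parameter recovery with a planted log-OR per 2000 heterozygous
    loci (defaults to ln 1.25)."""
    return null_calibration_study(n_replicates=n_replicates,
                                  n_snps=n_snps, seed=seed,
                                  beta_per_2000=beta_per_2000)


@dataclass
class ConfoundingSummary:
    n_replicates: int
    unadjusted_type1: float
    adjusted_type1: float


def stratification_confounding_study(n_replicates: int = 200,
                                     seed: int = 2,
                                     fst: float = 0.15,
                                     risk_shift: float = 1.5,
                                     n_snps: int = 2000,
                                     n_individuals: int = 1500,
                                     ) -> ConfoundingSummary:
    """Planted confounding: two subpopulations whose disease risk differs
    by ``risk_shift`` log-odds and no true heterozygosity effect.

    Because drifted allele frequencies shift each subpopulation's mean
    heterozygosity, the unadjusted model picks up a spurious
    heterozygosity-disease association; including the top eigenvectors
    restores nominal type-I error.
    """
    rng = np.random.default_rng(seed)
    unadj, adj = [], []
    for _ in range(n_replicates):
        s = int(rng.integers(2 ** 31))
        cfg = SimulationConfig(
            n_individuals=n_individuals, n_snps=n_snps,
            n_subpops=2, fst=fst,
            subpop_risk=(-risk_shift / 2, risk_shift / 2),
            baseline_prevalence=0.03, n_periods=8,
            missing_rate=0.0, seed=s)
        r_u = _one_replicate(cfg, adjust=False)
        r_a = _one_replicate(cfg, snp_step=5, adjust=True)
        if r_u.converged:
            unadj.append(r_u.p_value < 0.05)
        if r_a.converged:
            adj.append(r_a.p_value < 0.05)
    return ConfoundingSummary(n_replicates=min(len(unadj), len(adj)),
                              unadjusted_type1=float(np.mean(unadj)),
                              adjusted_type1=float(np.mean(adj)))


def biomarker_null_study(n_replicates: int = 20, n_snps: int = 15_000,
                         n_individuals: int = 900, seed: int = 3,
                         alpha: float = 0.05) -> tuple[float, int]:
    """Fraction of nominally significant heterozygosity-trait tests in a
    13-trait x 3-strata grid with all trait slopes zero.

    Returns ``(significant_fraction, n_tests)``.
    """
    rng = np.random.default_rng(seed)
    n_sig = 0
    n_tests = 0
    for _ in range(n_replicates):
        cfg = SimulationConfig(
            n_individuals=n_individuals, n_snps=n_snps,
            baseline_prevalence=0.03, n_periods=8, missing_rate=0.0,
            biomarker_gamma_per_2000=0.0,
            seed=int(rng.integers(2 ** 31)))
        crng = cfg.rng()
        truth = draw_truth(cfg, crng)
        geno = simulate_genotypes(truth.subpop_freqs, truth, cfg, crng)
        ann, genes = simulate_annotation(cfg, crng)
        het_all = pd.Series((geno.genotypes == 1).sum(axis=1),
                            index=geno.sample_ids)
        samples = assign_outcomes_and_match(geno, truth, cfg, crng,
                                            het_counts=het_all.to_numpy())
        samples = simulate_biomarkers(samples, het_all, cfg, crng)
        sub = geno.subset_samples(samples.index)
        strata = [het.autosomal_stratum(ann),
                  het.define_genic_stratum(ann, genes),
                  het.nonsynonymous_stratum(ann)]
        profile = het.compute_het_profile(sub, strata)
        eig = strat.compute_eigenvectors(sub, k=3, snp_step=10)
        samples = strat.attach_eigenvectors(samples, eig)
        for trait in cfg.biomarker_names:
            for st in strata:
                res = assoc.fit_biomarker_model(samples, profile, trait,
                                                st.name)
                n_tests += 1
                n_sig += res.p_value < alpha
    return n_sig / n_tests, n_tests


@dataclass
class HetIdentitySummary:
    mean_proportion: float
    expected_proportion: float   # (1 - mean F) * mean(2 p (1-p))
    mc_se: float                 # Monte-Carlo SE of the mean proportion
    slope: float                 # regression of proportion on true F
    slope_se: float
    expected_slope: float        # -mean(2 p (1-p))


def het_inbreeding_identity_study(n_individuals: int = 500,
                                  n_snps: int = 50_000, seed: int = 4,
                                  f_mean: float = 0.05,
                                  f_sd: float = 0.05,
                                  ) -> HetIdentitySummary:
    """Check the heterozygosity-inbreeding identity on one simulation:
    E[het proportion | F] = (1 - F) * mean_j 2 p_j (1 - p_j)."""
    import statsmodels.api as sm
    cfg = SimulationConfig(n_individuals=n_individuals, n_snps=n_snps,
                           f_mean=f_mean, f_sd=f_sd, maf_low=0.05,
                           missing_rate=0.0, seed=seed)
    rng = cfg.rng()
    truth = draw_truth(cfg, rng)
    geno = simulate_genotypes(truth.subpop_freqs, truth, cfg, rng)
    prop = (geno.genotypes == 1).mean(axis=1)
    p = truth.ancestral_freq
    mean_2pq = float(np.mean(2 * p * (1 - p)))
    expected = (1 - truth.f.mean()) * mean_2pq
    mc_se = float(prop.std(ddof=1) / np.sqrt(len(prop)))
    fit = sm.OLS(prop, sm.add_constant(truth.f)).fit()
    return HetIdentitySummary(
        mean_proportion=float(prop.mean()),
        expected_proportion=float(expected), mc_se=mc_se,
        slope=float(fit.params[1]), slope_se=float(fit.bse[1]),
        expected_slope=-mean_2pq)


def qc_fixture(n_controls: int = 14, n_cases: int = 6,
               n_autosomal: int = 140, n_x: int = 60,
               seed: int = 5):
    """Construct a 20 x 200 genotype panel with planted QC violations.

    Returns ``(geno, annotation, samples, planted)`` where ``planted``
    names the expected exclusions: two low-call-rate individuals (plus
    one exactly at the 0.97 boundary, retained), one sex-mismatched
    reported male, ten platform-private SNPs, and two SNPs violating HWE
    in controls only (all 14 controls homozygous, alleles split 7/7,
    exact p = 8.6e-5 < 1e-4; cases at those SNPs are heterozygous and
    must not influence the filter). The call-rate and sex violations sit
    among the cases so the HWE control counts stay at 14.
    """
    from .containers import GenotypeMatrix
    from .simulate import sample_ids, snp_ids

    rng = np.random.default_rng(seed)
    n = n_controls + n_cases
    m = n_autosomal + n_x
    p = rng.uniform(0.35, 0.5, size=m)
    g = rng.binomial(2, p, size=(n, m)).astype(np.int8)

    ids = sample_ids(n)
    sids = snp_ids(m)
    status = np.array(["control"] * n_controls + ["case"] * n_cases)
    sex = np.array(["female"] * n, dtype=object)
    xcols = np.arange(n_autosomal, m)
    # females: guarantee clearly heterozygous X (rate 0.4 >= hi)
    g[:, xcols[:24]] = 1
    # honest males among the cases: homozygous X throughout
    males = [n_controls, n_controls + 1]
    for i in males:
        sex[i] = "male"
        g[i, xcols] = np.where(g[i, xcols] == 1, 0, g[i, xcols])
    # planted sex mismatch: reported male with heterozygous X calls
    mismatch = n_controls + 2
    sex[mismatch] = "male"

    # low call rate (cases): strictly below 0.97 -> excluded
    low1, low2 = n_controls + 3, n_controls + 4
    g[low1, rng.choice(m, 8, replace=False)] = -1
    g[low2, rng.choice(m, 12, replace=False)] = -1
    # a control exactly at the boundary (194/200 = 0.97) is retained;
    # its missing calls avoid the planted HWE columns
    boundary = 0
    g[boundary, 50 + rng.choice(m - 50, 6, replace=False)] = -1

    # HWE violations in controls only
    hwe_snps = [10, 11]
    half = n_controls // 2
    for j in hwe_snps:
        g[:n_controls, j] = [0] * half + [2] * (n_controls - half)
        g[n_controls:, j] = 1

    platforms = np.full(m, "A,B", dtype=object)
    private = list(range(120, 130))
    platforms[private] = "A"

    ann = pd.DataFrame({
        "chrom": ["1"] * n_autosomal + ["X"] * n_x,
        "pos": np.arange(1, m + 1) * 1000,
        "is_autosomal": [True] * n_autosomal + [False] * n_x,
        "gene_id": None, "is_nonsynonymous": False,
        "platforms": platforms,
    }, index=sids)
    samples = pd.DataFrame({
        "age": 60.0, "smoking": 0, "reported_sex": sex,
        "case_status": status, "matched_set_id": 0,
    }, index=ids)
    planted = {
        "low_call_rate": [ids[low1], ids[low2]],
        "boundary_kept": ids[boundary],
        "sex_mismatch": [ids[mismatch]],
        "platform_mismatch": [sids[j] for j in private],
        "hwe_fail": [sids[j] for j in hwe_snps],
    }
    return (GenotypeMatrix(g, ids, sids), ann, samples, planted)
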