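"""Genotyping quality control.

Filters run in a fixed, logged order — sample call rate, sex consistency,
cross-platform SNP intersection, Hardy-Weinberg equilibrium in controls —
and each excluded item carries the first (and only) reason that fired.
Re-running QC on already-filtered data is a no-op.

The HWE test is the exact conditional test: given the allele counts at a
biallelic site, the heterozygote count ``n_Aa`` has probability
proportional to ``2**n_Aa * n! / (n_AA! n_Aa! n_aa!)``, and the two-sided
p-value sums the probabilities of all attainable configurations no more
probable than the observed one.
"""

from __future__ import annotations

import logging
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .containers import GenotypeMatrix, QcReport, MISSING

logger = logging.getLogger(__name__)

LOW_CALL_RATE = "low_call_rate"
SEX_MISMATCH = "sex_mismatch"
HWE_FAIL = "hwe_fail"
PLATFORM_MISMATCH = "platform_mismatch"


def het_count_distribution(n_a: int, n_b: int
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Exact conditional distribution of the heterozygote count.

    Given ``n_a`` copies of one allele and ``n_b`` of the other
    (``n_a + n_b = 2n``), returns the attainable heterozygote counts and
    their probabilities. Probabilities sum to 1.
    """
    if n_a < 0 or n_b < 0 or n_a + n_b == 0 or (n_a + n_b) % 2:
        raise ValueError("invalid allele counts")
    rare = min(n_a, n_b)
    h = np.arange(rare % 2, rare + 1, 2)
    logw = (h * np.log(2.0)
            - gammaln(h + 1)
            - gammaln((n_a - h) / 2 + 1)
            - gammaln((n_b - h) / 2 + 1))
    logw -= logw.max()
    w = np.exp(logw)
    return h, w / w.sum()


@lru_cache(maxsize=100_000)
def _cached_distribution(n_a: int, n_b: int):
    return het_count_distribution(n_a, n_b)


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int,
                   midp: bool = False) -> float:
    """Two-sided exact Hardy-Weinberg p-value from genotype counts.

    Counts are homozygote / heterozygote / other-homozygote. The tail is
    the standard "no more probable" rule; with ``midp`` only half the
    observed configuration's probability is counted.
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("at least one genotyped individual is required")
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    h, probs = _cached_distribution(min(n_a, n_b), max(n_a, n_b))
    p_obs = probs[np.searchsorted(h, n_ab)]
    tail = probs[probs <= p_obs * (1 + 1e-12)].sum()
    if midp:
        tail -= 0.5 * p_obs
    return float(min(tail, 1.0))


def filter_sample_call_rate(geno: GenotypeMatrix,
                            min_rate: float = 0.97,
                            report: Optional[QcReport] = None) -> QcReport:
    """Exclude individuals whose genotype call rate is strictly below
    ``min_rate`` (an individual exactly at the threshold is kept)."""
    if not (0 < min_rate <= 1):
        raise ValueError("min_rate must be in (0, 1]")
    if geno.n_samples == 0 or geno.n_snps == 0:
        raise ValueError("empty genotype matrix")
    report = report or QcReport()
    report.thresholds["min_call_rate"] = min_rate
    rates = geno.call_rates()
    for sid in rates.index[rates.to_numpy() < min_rate]:
        report.excluded_samples.append((sid, LOW_CALL_RATE))
    return report

def check_sex_consistency(geno: GenotypeMatrix, annotation: pd.DataFrame,
                          samples: pd.DataFrame,
                          lo: float = 0.02, hi: float = 0.20,
                          min_x_snps: int = 50,
                          report: Optional[QcReport] = None) -> QcReport:
    """Exclude individuals whose X-heterozygosity contradicts reported sex.

    Sex is inferred from the heterozygosity rate over X-linked SNPs
    (males are hemizygous, so called X genotypes should be homozygous):
    rate >= ``hi`` implies female, <= ``lo`` implies male, in between is
    indeterminate (retained with a warning). With fewer than
    ``min_x_snps`` X SNPs the check is skipped with a logged warning.
    """
    report = report or QcReport()
    report.thresholds.update({"sex_lo": lo, "sex_hi": hi})
    x_ids = annotation.index[~annotation["is_autosomal"].astype(bool)]
    x_ids = x_ids.intersection(geno.snp_ids)
    if len(x_ids) < min_x_snps:
        msg = (f"sex check skipped: only {len(x_ids)} X-linked SNPs "
               f"(need >= {min_x_snps})")
        logger.warning(msg)
        report.messages.append(msg)
        return report
    g = geno.genotypes[:, geno.snp_indexer(x_ids)]
    n_ok = (g != MISSING).sum(axis=1)
    with np.errstate(invalid="ignore"):
        rate = np.where(n_ok > 0, (g == 1).sum(axis=1) / n_ok, np.nan)
    inferred = np.where(rate >= hi, "female",
                        np.where(rate <= lo, "male", "indeterminate"))
    already = {s for s, _ in report.excluded_samples}
    for i, sid in enumerate(geno.sample_ids):
        if sid in already or sid not in samples.index:
            continue
        rep = samples.loc[sid, "reported_sex"]
        if inferred[i] == "indeterminate":
            msg = (f"sample {sid}: indeterminate X-heterozygosity "
                   f"{rate[i]:.3f}; retained")
            logger.warning(msg)
            report.messages.append(msg)
        elif pd.notna(rep) and inferred[i] != rep:
            report.excluded_samples.append((sid, SEX_MISMATCH))
    return report


def intersect_platforms(annotation: pd.DataFrame,
                        platforms: Optional[Sequence[str]] = None,
                        report: Optional[QcReport] = None) -> QcReport:
    """Restrict analysis to SNPs present on every genotyping platform.

    ``platforms`` defaults to all labels seen in the annotation's
    ``platforms`` column (comma-separated membership); at least two named
    platforms are required for the intersection to mean anything.
    """
    report = report or QcReport()
    sets = annotation["platforms"].fillna("").astype(str).str.split(",")
    sets = sets.apply(lambda xs: frozenset(x for x in xs if x))
    if platforms is None:
        platforms = sorted(set().union(*sets)) if len(sets) else []
    if len(platforms) < 2:
        raise ValueError("need >= 2 named platform SNP sets")
    required = frozenset(platforms)
    keep = sets.apply(lambda s: required <= s)
    if not keep.any():
        raise ValueError("platform intersection is empty")
    already = {s for s, _ in report.excluded_snps}
    for sid in annotation.index[~keep]:
        if sid not in already:
            report.excluded_snps.append((sid, PLATFORM_MISMATCH))
    return report


def filter_hwe_in_controls(geno: GenotypeMatrix, samples: pd.DataFrame,
                           alpha: float = 1e-4,
                           report: Optional[QcReport] = None) -> QcReport:
    """Exclude SNPs with exact HWE p < ``alpha`` computed in controls only.

    Genotype counts are tallied over control individuals; failing SNPs are
    removed for everyone (cases included). Monomorphic SNPs have p = 1 and
    are retained.
    """
    report = report or QcReport()
    report.thresholds["hwe_alpha"] = alpha
    excluded_samples = {s for s, _ in report.excluded_samples}
    ctl_ids = [s for s in samples.index[samples["case_status"] == "control"]
               if s not in excluded_samples]
    if len(ctl_ids) == 0:
        raise ValueError("no controls available for the HWE filter")
    ctl = geno.subset_samples(ctl_ids).genotypes
    n_aa = (ctl == 0).sum(axis=0)
    n_ab = (ctl == 1).sum(axis=0)
    n_bb = (ctl == 2).sum(axis=0)
    already = {s for s, _ in report.excluded_snps}
    total = n_aa + n_ab + n_bb
    for j in np.flatnonzero(total >= 1):
        sid = geno.snp_ids[j]
        if sid in already:
            continue
        p = hwe_exact_test(int(n_aa[j]), int(n_ab[j]), int(n_bb[j]))
        if p < alpha:
            report.excluded_snps.append((sid, HWE_FAIL))
    return report


def run_qc(geno: GenotypeMatrix, annotation: pd.DataFrame,
           samples: pd.DataFrame,
           min_call_rate: float = 0.97,
           hwe_alpha: float = 1e-4,
           skip_sex_check: bool = False,
           platforms: Optional[Sequence[str]] = None,
           skip_platform_intersection: bool = False,
           sex_lo: float = 0.02, sex_hi: float = 0.20,
           ) -> tuple[GenotypeMatrix, pd.DataFrame, pd.DataFrame, QcReport]:
    """Apply all QC rules in fixed order and return filtered data.

    Order: sample call rate -> sex consistency -> platform intersection ->
    HWE in controls (tallied after sample exclusions). Idempotent: running
    it again on its own output excludes nothing.
    """
    report = QcReport(n_samples_before=geno.n_samples,
                      n_snps_before=geno.n_snps)
    filter_sample_call_rate(geno, min_call_rate, report)
    if not skip_sex_check:
        check_sex_consistency(geno, annotation, samples,
                              lo=sex_lo, hi=sex_hi, report=report)
    if not skip_platform_intersection:
        intersect_platforms(annotation, platforms, report)

    bad_samples = {s for s, _ in report.excluded_samples}
    bad_snps = {s for s, _ in report.excluded_snps}
    keep_samples = [s for s in geno.sample_ids if s not in bad_samples]
    keep_snps = [s for s in geno.snp_ids if s not in bad_snps]
    g1 = geno.subset_samples(keep_samples).subset_snps(keep_snps)
    s1 = samples.loc[samples.index.intersection(pd.Index(keep_samples))]

    filter_hwe_in_controls(g1, s1, hwe_alpha, report)
    bad_snps = {s for s, _ in report.excluded_snps}
    keep_snps = [s for s in g1.snp_ids if s not in bad_snps]
    g2 = g1.subset_snps(keep_snps)
    a2 = annotation.loc[annotation.index.intersection(pd.Index(keep_snps))]

    report.n_samples_after = g2.n_samples
    report.n_snps_after = g2.n_snps
    report.check_counts()
    logger.info("QC: %d/%d samples and %d/%d SNPs retained",
                g2.n_samples, report.n_samples_before,
                g2.n_snps, report.n_snps_before)
    return g2, a2, s1, report
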