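"""Per-individual multilocus heterozygosity over SNP strata.

Three strata are analysed: all autosomal SNPs, SNPs within protein-coding
genes plus strand-oriented flanks (70 kb upstream / 20 kb downstream by
default), and nonsynonymous SNPs only. Effects are reported per a fixed
number of heterozygous SNPs (2000 for the first two strata, 25 for
nonsynonymous — roughly one standard deviation of each count).

Counts use each individual's own non-missing denominator: a missing call
contributes to neither the heterozygote count nor the denominator of the
proportion. Count and proportion are both first-class outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import (GenotypeMatrix, HetProfile, StratumDefinition,
                         MISSING)

ALL_AUTOSOMAL = "all_autosomal"
GENIC = "genic"
NONSYNONYMOUS = "nonsynonymous"

#: default SNPs-per-reporting-unit by stratum (~1 SD of each count on a
#: ~700k-SNP panel)
DEFAULT_UNITS = {ALL_AUTOSOMAL: 2000.0, GENIC: 2000.0, NONSYNONYMOUS: 25.0}


def autosomal_stratum(annotation: pd.DataFrame,
                      scale_unit: float = 2000.0) -> StratumDefinition:
    ids = annotation.index[annotation["is_autosomal"].astype(bool)]
    return StratumDefinition(ALL_AUTOSOMAL, ids, scale_unit)


def nonsynonymous_stratum(annotation: pd.DataFrame,
                          scale_unit: float = 25.0) -> StratumDefinition:
    mask = (annotation["is_nonsynonymous"].astype(bool) &
            annotation["is_autosomal"].astype(bool))
    return StratumDefinition(NONSYNONYMOUS, annotation.index[mask],
                             scale_unit)


def _merge_intervals(lo: np.ndarray, hi: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(lo, kind="stable")
    lo, hi = lo[order], hi[order]
    mlo, mhi = [], []
    for a, b in zip(lo, hi):
        if mhi and a <= mhi[-1]:
            mhi[-1] = max(mhi[-1], b)
        else:
            mlo.append(a)
            mhi.append(b)
    return np.asarray(mlo), np.asarray(mhi)


def define_genic_stratum(annotation: pd.DataFrame, genes: pd.DataFrame,
                         upstream_kb: float = 70.0,
                         downstream_kb: float = 20.0,
                         scale_unit: float = 2000.0) -> StratumDefinition:
    """SNPs within gene bodies extended by strand-oriented flanks.

    A SNP is genic iff its position falls inside ``[start - up, end + down]``
    for some gene on its chromosome, where for minus-strand genes the
    extensions are mirrored (``up`` beyond ``end``, ``down`` before
    ``start``). Intervals are clamped at position 1 and merged, and each
    SNP is counted once (set semantics).

    ``genes`` needs columns ``gene_id, chrom, start, end, strand`` with
    1-based inclusive coordinates.
    """
    if (genes["start"] > genes["end"]).any():
        bad = genes.loc[genes["start"] > genes["end"], "gene_id"].iloc[0]
        raise ValueError(f"gene {bad!r} has start > end")
    up = int(round(upstream_kb * 1000))
    down = int(round(downstream_kb * 1000))
    plus = genes["strand"].astype(str) != "-"
    lo = pd.Series(np.maximum(
        np.where(plus, genes["start"] - up, genes["start"] - down), 1),
        index=genes.index)
    hi = pd.Series(np.where(plus, genes["end"] + down, genes["end"] + up),
                   index=genes.index)

    auto = annotation["is_autosomal"].astype(bool)
    member = np.zeros(len(annotation), dtype=bool)
    for chrom, gsub in genes.groupby("chrom"):
        mlo, mhi = _merge_intervals(lo.loc[gsub.index].to_numpy(),
                                    hi.loc[gsub.index].to_numpy())
        snps = (annotation["chrom"].astype(str) == str(chrom)) & auto
        p = annotation.loc[snps, "pos"].to_numpy()
        # position is inside a merged interval iff the nearest interval
        # start at or below it has an end at or above it
        j = np.searchsorted(mlo, p, side="right") - 1
        inside = (j >= 0) & (p <= mhi[np.clip(j, 0, None)])
        member[np.flatnonzero(snps.to_numpy())[inside]] = True
    return StratumDefinition(GENIC, annotation.index[member], scale_unit)


def count_heterozygous(geno: GenotypeMatrix,
                       stratum: StratumDefinition) -> pd.DataFrame:
    """Heterozygous-locus counts per individual over one stratum.

    Returns a DataFrame indexed by sample id with ``n_het``,
    ``n_nonmissing`` and ``proportion`` columns. The stratum is
    intersected with the SNPs present in the matrix (it must not be empty
    after intersection).
    """
    ids = stratum.snp_ids.intersection(geno.snp_ids)
    if len(ids) == 0:
        raise ValueError(f"stratum {stratum.name!r} is empty on this panel")
    cols = geno.snp_indexer(ids)
    g = geno.genotypes[:, cols]
    n_het = (g == 1).sum(axis=1)
    n_ok = (g != MISSING).sum(axis=1)
    with np.errstate(invalid="ignore"):
        prop = np.where(n_ok > 0, n_het / n_ok, np.nan)
    return pd.DataFrame({"n_het": n_het, "n_nonmissing": n_ok,
                         "proportion": prop}, index=geno.sample_ids)


def compute_het_profile(geno: GenotypeMatrix,
                        strata: list[StratumDefinition]) -> HetProfile:
    """Tidy per-individual, per-stratum heterozygosity table."""
    frames = []
    units = {}
    for st in strata:
        df = count_heterozygous(geno, st).reset_index()
        df.insert(1, "stratum", st.name)
        frames.append(df)
        units[st.name] = st.scale_unit
    return HetProfile(pd.concat(frames, ignore_index=True), units)


@dataclass
class RescaledEffect:
    beta_per_unit: float
    se_per_unit: float
    odds_ratio: float
    ci_low: float
    ci_high: float


def rescale_effect(beta_per_snp: float, se_per_snp: float,
                   scale_unit: float, z: float = 1.959963984540054
                   ) -> RescaledEffect:
    """Re-express a per-SNP log-odds effect per ``scale_unit`` SNPs.

    The transform is linear, so the SE scales identically and Wald CI
    endpoints move monotonically: OR = exp(beta * unit),
    CI = exp((beta +/- z*SE) * unit).
    """
    if not (np.isfinite(beta_per_snp) and np.isfinite(se_per_snp)):
        raise ValueError("beta and SE must be finite")
    b = beta_per_snp * scale_unit
    se = se_per_snp * scale_unit
    return RescaledEffect(b, se, float(np.exp(b)),
                          float(np.exp(b - z * se)),
                          float(np.exp(b + z * se)))


def auto_unit(counts: pd.Series) -> float:
    """Observed 1-SD reporting unit (the rationale behind 2000/25)."""
    sd = float(np.std(counts.to_numpy(dtype=float), ddof=1))
    if sd <= 0:
        raise ValueError("heterozygosity counts have zero variance")
    return sd
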