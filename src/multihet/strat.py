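"""Principal-component covariates for population-stratification adjustment.

Genotypes are centred per SNP at twice the observed allele frequency and
scaled by the binomial SD ``sqrt(2 p (1 - p))`` (monomorphic SNPs are
dropped), and the top eigenvectors of the resulting individual-by-
individual covariance are used as ancestry covariates — three of them by
default. A fixed sign convention (the largest-magnitude coordinate of
each component is positive) makes the output reproducible.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.linalg import eigh

from .containers import EigenvectorSet, GenotypeMatrix, MISSING


def compute_eigenvectors(geno: GenotypeMatrix, k: int = 3,
                         snp_step: int = 10) -> EigenvectorSet:
    """Top-``k`` principal components of the standardized genotypes.

    ``snp_step`` thins the panel (every ``snp_step``-th SNP) for speed;
    stratification signal is dense across the genome, so a thinned panel
    recovers the same axes. Missing genotypes are mean-imputed (i.e. they
    contribute zero after centring).
    """
    n = geno.n_samples
    if n < k + 1:
        raise ValueError(f"need at least k+1={k + 1} individuals for "
                         f"{k} components")
    g = geno.genotypes[:, ::max(1, snp_step)].astype(np.float64)
    miss = g == MISSING
    g[miss] = np.nan
    p = np.nanmean(g, axis=0) / 2.0
    ok = np.isfinite(p) & (p > 0) & (p < 1)
    if ok.sum() < k:
        raise ValueError("not enough polymorphic SNPs for PCA")
    g = g[:, ok]
    p = p[ok]
    z = (g - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    z[~np.isfinite(z)] = 0.0
    m = z.shape[1]
    cov = z @ z.T / m
    vals, vecs = eigh(cov, subset_by_index=(n - k, n - 1))
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    for j in range(k):
        i = np.argmax(np.abs(vecs[:, j]))
        if vecs[i, j] < 0:
            vecs[:, j] = -vecs[:, j]
    total = np.trace(cov)
    coords = pd.DataFrame(vecs, index=geno.sample_ids,
                          columns=[f"EV{j + 1}" for j in range(k)])
    return EigenvectorSet(coords=coords,
                          variance_explained=vals / total,
                          n_snps_used=m)


def flag_ancestry_outliers(eig: EigenvectorSet,
                           sd_multiple: float = 6.0) -> list[str]:
    """Individuals beyond ``sd_multiple`` SDs from the mean on any
    component (a generic stand-in for reference-panel ancestry checks).
    Exclusion is opt-in: callers decide what to do with the list."""
    x = eig.coords.to_numpy()
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    with np.errstate(invalid="ignore"):
        out = (np.abs(x - mu) > sd_multiple * sd).any(axis=1)
    return list(eig.coords.index[out])


def attach_eigenvectors(samples: pd.DataFrame,
                        eig: EigenvectorSet) -> pd.DataFrame:
    """Merge EV columns into a sample table (inner alignment on ids)."""
    out = samples.copy()
    for c in eig.coords.columns:
        out[c] = eig.coords[c].reindex(out.index)
    return out
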