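"""Shared in-memory data model for the heterozygosity pipeline.

Genotypes are stored as an individuals x SNPs ``int8`` matrix of
non-reference allele counts (0, 1, 2) with ``-1`` for a missing call.
Heterozygosity therefore depends only on ``code == 1``, so the choice of
which allele is "reference" at a SNP is irrelevant to every downstream
statistic (flipping 0 <-> 2 at any site leaves all results unchanged).

SNP annotation and per-sample covariates travel as pandas DataFrames with
a documented, validated schema rather than bespoke classes; the small
classes here exist where shape/consistency invariants need enforcing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING = np.int8(-1)

#: mandatory columns of a SNP annotation table (index: snp_id)
ANNOTATION_COLUMNS = ("chrom", "pos", "is_autosomal", "gene_id",
                      "is_nonsynonymous", "platforms")

#: mandatory columns of a sample covariate table (index: sample_id)
SAMPLE_COLUMNS = ("age", "smoking", "reported_sex", "case_status",
                  "matched_set_id")


class SchemaError(ValueError):
    """A table is missing mandatory columns or violates its schema."""


class GenotypeMatrix:
    """Individuals x SNPs matrix of allele-count codes {0, 1, 2, -1}.

    Parameters
    ----------
    genotypes:
        ``(n_samples, n_snps)`` integer array; coerced to ``int8``.
    sample_ids, snp_ids:
        Unique ordered identifiers for the two axes.
    """

    def __init__(self, genotypes: np.ndarray, sample_ids: Sequence[str],
                 snp_ids: Sequence[str]):
        g = np.asarray(genotypes)
        if g.ndim != 2:
            raise ValueError("genotypes must be 2-D (individuals x SNPs)")
        self.genotypes = g.astype(np.int8, copy=False)
        self.sample_ids = pd.Index(sample_ids, name="sample_id")
        self.snp_ids = pd.Index(snp_ids, name="snp_id")
        if len(self.sample_ids) != g.shape[0]:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {g.shape[0]} rows")
        if len(self.snp_ids) != g.shape[1]:
            raise ValueError(
                f"{len(self.snp_ids)} snp ids for {g.shape[1]} columns")
        if not self.sample_ids.is_unique:
            raise ValueError("sample ids are not unique")
        if not self.snp_ids.is_unique:
            raise ValueError("snp ids are not unique")
        # codes are int8, so range-checking is equivalent to (and much
        # cheaper than) membership in {-1, 0, 1, 2}
        if self.genotypes.size and (self.genotypes.min() < -1 or
                                    self.genotypes.max() > 2):
            bad = (self.genotypes < -1) | (self.genotypes > 2)
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid genotype code {self.genotypes[i, j]} at "
                f"({self.sample_ids[i]}, {self.snp_ids[j]})")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    def subset_samples(self, ids: Iterable[str]) -> "GenotypeMatrix":
        idx = self.sample_ids.get_indexer(pd.Index(ids))
        if (idx < 0).any():
            raise KeyError("unknown sample id(s) in subset")
        return GenotypeMatrix(self.genotypes[idx], self.sample_ids[idx],
                              self.snp_ids)

    def subset_snps(self, ids: Iterable[str]) -> "GenotypeMatrix":
        idx = self.snp_ids.get_indexer(pd.Index(ids))
        if (idx < 0).any():
            raise KeyError("unknown snp id(s) in subset")
        return GenotypeMatrix(self.genotypes[:, idx], self.sample_ids,
                              self.snp_ids[idx])

    def snp_indexer(self, ids: Iterable[str]) -> np.ndarray:
        idx = self.snp_ids.get_indexer(pd.Index(ids))
        if (idx < 0).any():
            raise KeyError("unknown snp id(s)")
        return idx

    def call_rates(self) -> pd.Series:
        """Per-individual fraction of non-missing genotype calls."""
        ok = (self.genotypes != MISSING).mean(axis=1)
        return pd.Series(ok, index=self.sample_ids, name="call_rate")

    def __repr__(self) -> str:  # pragma: no cover
        return (f"GenotypeMatrix({self.n_samples} individuals x "
                f"{self.n_snps} SNPs)")


def validate_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    """Validate (and lightly coerce) a SNP annotation table.

    Index must be unique snp ids; ``is_nonsynonymous`` implies a non-null
    ``gene_id``; positions are 1-based and positive.
    """
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise SchemaError(f"annotation is missing column(s): {missing}")
    if not ann.index.is_unique:
        raise SchemaError("annotation snp ids are not unique")
    if (ann["pos"] < 1).any():
        raise SchemaError("annotation positions must be positive (1-based)")
    ns = ann["is_nonsynonymous"].astype(bool)
    if (ns & ann["gene_id"].isna()).any():
        raise SchemaError("nonsynonymous SNP with null gene_id")
    return ann


def validate_samples(samples: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise SchemaError(f"sample table is missing column(s): {missing}")
    if not samples.index.is_unique:
        raise SchemaError("sample ids are not unique")
    bad = set(samples["case_status"].dropna().unique()) - {"case", "control"}
    if bad:
        raise SchemaError(f"invalid case_status values: {sorted(bad)}")
    return samples


def biomarker_columns(samples: pd.DataFrame) -> list[str]:
    """Columns not part of the core schema (treated as biomarkers)."""
    core = set(SAMPLE_COLUMNS) | {"age_band", "event_time", "subpop"}
    return [c for c in samples.columns
            if c not in core and not c.startswith("EV")]


@dataclass
class StratumDefinition:
    """A named SNP stratum with its effect-reporting unit.

    ``scale_unit`` is the number of heterozygous SNPs per reported unit
    (2000 for the all-autosomal and genic strata, 25 for nonsynonymous,
    chosen to be ~1 SD of the respective count).
    """
    name: str
    snp_ids: pd.Index
    scale_unit: float

    def __post_init__(self):
        self.snp_ids = pd.Index(self.snp_ids)
        if self.scale_unit <= 0:
            raise ValueError("scale_unit must be positive")


@dataclass
class HetProfile:
    """Per-individual heterozygosity over one or more SNP strata.

    ``table`` is tidy: one row per (sample_id, stratum) with columns
    ``n_het``, ``n_nonmissing``, ``proportion``.
    """
    table: pd.DataFrame
    units: dict = field(default_factory=dict)  # stratum -> scale_unit

    def stratum(self, name: str) -> pd.DataFrame:
        sub = self.table[self.table["stratum"] == name]
        if sub.empty:
            raise KeyError(f"no stratum named {name!r}")
        return sub.set_index("sample_id")

    def counts(self, name: str) -> pd.Series:
        return self.stratum(name)["n_het"]

    def proportions(self, name: str) -> pd.Series:
        return self.stratum(name)["proportion"]

    @property
    def strata(self) -> list[str]:
        return list(dict.fromkeys(self.table["stratum"]))


@dataclass
class EigenvectorSet:
    """Top-k principal-component coordinates for stratification adjustment."""
    coords: pd.DataFrame            # index sample_id, columns EV1..EVk
    variance_explained: np.ndarray  # fraction per component
    n_snps_used: int

    @property
    def k(self) -> int:
        return self.coords.shape[1]


@dataclass
class AssociationResult:
    """Logistic-regression effect of heterozygosity on disease."""
    stratum: str
    unit: float
    exposure: str                 # "count" or "proportion"
    beta_per_unit: float
    se_per_unit: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    n_cases: int
    n_controls: int
    covariates: list[str]
    converged: bool

    def __post_init__(self):
        if np.isfinite(self.beta_per_unit):
            assert self.ci_low <= self.odds_ratio <= self.ci_high


@dataclass
class BiomarkerResult:
    """Linear (or mixed) model effect of heterozygosity on a trait."""
    trait: str
    stratum: str
    unit: float
    beta_per_unit: float
    se_per_unit: float
    p_value: float
    n: int
    covariates: list[str]
    model_form: str               # "fixed-only" or "random-intercept-by-set"


@dataclass
class QcReport:
    """Bookkeeping for the fixed-order QC filters.

    Every excluded item carries exactly one primary reason: filters run in
    the fixed order call_rate -> sex -> platform -> HWE, and the first rule
    to fire wins.
    """
    excluded_samples: list[tuple[str, str]] = field(default_factory=list)
    excluded_snps: list[tuple[str, str]] = field(default_factory=list)
    thresholds: dict = field(default_factory=dict)
    n_samples_before: int = 0
    n_samples_after: int = 0
    n_snps_before: int = 0
    n_snps_after: int = 0
    messages: list[str] = field(default_factory=list)

    def samples_excluded_for(self, reason: str) -> list[str]:
        return [s for s, r in self.excluded_samples if r == reason]

    def snps_excluded_for(self, reason: str) -> list[str]:
        return [s for s, r in self.excluded_snps if r == reason]

    def check_counts(self) -> None:
        assert self.n_samples_after == (
            self.n_samples_before - len(self.excluded_samples))
        assert self.n_snps_after == (
            self.n_snps_before - len(self.excluded_snps))

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        samples = pd.DataFrame(self.excluded_samples,
                               columns=["sample_id", "reason"])
        snps = pd.DataFrame(self.excluded_snps, columns=["snp_id", "reason"])
        return samples, snps
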