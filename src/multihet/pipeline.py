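"""End-to-end pipeline: simulate -> QC -> heterozygosity -> PCA -> models.

`run_all` drives the whole analysis from a single configuration and
returns (and optionally writes) every intermediate product plus a
machine-readable run manifest (seed, thresholds, versions).
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__, assoc, het, io, qc, strat
from .containers import (AssociationResult, BiomarkerResult, HetProfile,
                         QcReport, biomarker_columns)
from .simulate import SimulationConfig, SimulatedCohort, simulate_cohort

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    cohort: SimulatedCohort
    qc_report: QcReport
    het_profile: HetProfile
    eigenvectors: strat.EigenvectorSet
    samples: pd.DataFrame
    chd_results: list[AssociationResult]
    biomarker_results: list[BiomarkerResult]
    table1: pd.DataFrame
    table2: pd.DataFrame
    manifest: dict


def analyse(geno, annotation, genes, samples,
            k_eigenvectors: int = 3, pca_snp_step: int = 10,
            exposure: str = "count", random_intercept: bool = False,
            min_call_rate: float = 0.97, hwe_alpha: float = 1e-4,
            skip_sex_check: bool = False,
            skip_platform_intersection: bool = True,
            upstream_kb: float = 70.0, downstream_kb: float = 20.0,
            with_biomarkers: bool = True):
    """QC, heterozygosity strata, PCA and association on given data.

    Returns a dict of intermediate products (see keys in the code); used
    by both the CLI and :func:`run_all`.
    """
    g, ann, smp, report = qc.run_qc(
        geno, annotation, samples,
        min_call_rate=min_call_rate, hwe_alpha=hwe_alpha,
        skip_sex_check=skip_sex_check,
        skip_platform_intersection=skip_platform_intersection)

    strata = [het.autosomal_stratum(ann)]
    if genes is not None and len(genes):
        strata.append(het.define_genic_stratum(
            ann, genes, upstream_kb=upstream_kb,
            downstream_kb=downstream_kb))
    if ann["is_nonsynonymous"].any():
        strata.append(het.nonsynonymous_stratum(ann))
    profile = het.compute_het_profile(g, strata)

    eig = strat.compute_eigenvectors(g, k=k_eigenvectors,
                                     snp_step=pca_snp_step)
    smp = strat.attach_eigenvectors(smp, eig)

    chd = []
    for st in strata:
        chd.append(assoc.fit_chd_model(smp, profile, st.name,
                                       exposure=exposure))
    bio = []
    if with_biomarkers:
        for trait in biomarker_columns(smp):
            for st in strata:
                try:
                    bio.append(assoc.fit_biomarker_model(
                        smp, profile, trait, st.name,
                        random_intercept=random_intercept))
                except ValueError as exc:
                    logger.warning("biomarker model skipped: %s", exc)
    table1, table2 = assoc.build_reports(profile, smp, chd, bio)
    return {"genotypes": g, "annotation": ann, "samples": smp,
            "qc_report": report, "het_profile": profile,
            "eigenvectors": eig, "chd_results": chd,
            "biomarker_results": bio, "table1": table1, "table2": table2}


def run_all(config: SimulationConfig, out_dir: Optional[Path] = None,
            **analysis_kwargs) -> PipelineResult:
    """Simulate a cohort and run the full analysis on it."""
    cohort = simulate_cohort(config)
    res = analyse(cohort.genotypes, cohort.annotation, cohort.genes,
                  cohort.samples, **analysis_kwargs)
    manifest = {
        "multihet_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": config.seed,
        "n_individuals": config.n_individuals,
        "n_snps": config.n_snps,
        "thresholds": res["qc_report"].thresholds,
        "n_cases": int((res["samples"]["case_status"] == "case").sum()),
        "n_controls": int(
            (res["samples"]["case_status"] == "control").sum()),
    }
    result = PipelineResult(
        cohort=cohort, qc_report=res["qc_report"],
        het_profile=res["het_profile"], eigenvectors=res["eigenvectors"],
        samples=res["samples"], chd_results=res["chd_results"],
        biomarker_results=res["biomarker_results"],
        table1=res["table1"], table2=res["table2"], manifest=manifest)
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _write_outputs(result: PipelineResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    io.write_covariates(out / "samples.tsv", result.samples)
    result.het_profile.table.to_csv(out / "het_profile.tsv", sep="\t",
                                    index=False)
    exc_s, exc_v = result.qc_report.to_frames()
    exc_s.to_csv(out / "qc_excluded_samples.tsv", sep="\t", index=False)
    exc_v.to_csv(out / "qc_excluded_snps.tsv", sep="\t", index=False)
    result.table1.to_csv(out / "table1.tsv", sep="\t", index=False)
    result.table2.to_csv(out / "table2.tsv", sep="\t", index=False)
    (out / "table1.md").write_text(assoc.table_to_markdown(result.table1))
    if len(result.table2):
        (out / "table2.md").write_text(
            assoc.table_to_markdown(result.table2))
    (out / "manifest.json").write_text(
        json.dumps(result.manifest, indent=2, default=str) + "\n")
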