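"""Association models: disease on heterozygosity, biomarkers on
heterozygosity.

Disease risk is modelled by unconditional logistic regression of case
status on standardized heterozygosity with adjustment for the matching
factors (age, smoking) and the ancestry eigenvectors; matching is handled
by covariate adjustment rather than conditioning, which converges more
reliably and gives similar estimates on matched data. Biomarkers are
modelled linearly with the same covariates plus case-control status,
optionally with a per-matched-set random intercept (REML).

Effects are reported per ``unit`` heterozygous SNPs (2000, or 25 for the
nonsynonymous stratum) with Wald confidence intervals and p-values.
"""

from __future__ import annotations

import logging
import warnings
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .containers import (AssociationResult, BiomarkerResult, HetProfile)

logger = logging.getLogger(__name__)

Z95 = 1.959963984540054


def _exposure(het_stratum: pd.DataFrame, unit: float,
              exposure: str) -> pd.Series:
    """Per-unit exposure from a stratum's count table.

    ``count``: n_het / unit. ``proportion``: the proportion rescaled by
    the median non-missing denominator so its coefficient stays on the
    per-unit-of-SNPs scale; with uniform missingness the two exposures are
    exactly proportional and give identical z-statistics.
    """
    if exposure == "count":
        return het_stratum["n_het"] / unit
    if exposure == "proportion":
        denom = float(het_stratum["n_nonmissing"].median())
        return het_stratum["proportion"] * denom / unit
    raise ValueError(f"unknown exposure {exposure!r}")


def _covariate_frame(samples: pd.DataFrame,
                     covariates: Sequence[str]) -> pd.DataFrame:
    missing = [c for c in covariates if c not in samples.columns]
    if missing:
        raise ValueError(f"missing covariate column(s): {missing}")
    return samples[list(covariates)].astype(float)


def default_covariates(samples: pd.DataFrame) -> list[str]:
    evs = sorted((c for c in samples.columns if c.startswith("EV")),
                 key=lambda c: int(c[2:]))
    return ["age", "smoking"] + evs


def fit_chd_model(samples: pd.DataFrame,
                  het: Union[HetProfile, pd.DataFrame],
                  stratum: str, unit: Optional[float] = None,
                  exposure: str = "count",
                  covariates: Optional[Sequence[str]] = None,
                  ) -> AssociationResult:
    """Logistic regression of case status on per-unit heterozygosity.

    Rows with any missing covariate are dropped (and counted in the log).
    Non-convergence or separation is flagged on the result rather than
    raised, so no estimate is reported silently.
    """
    if isinstance(het, HetProfile):
        if unit is None:
            unit = het.units.get(stratum, 2000.0)
        het_stratum = het.stratum(stratum)
    else:
        het_stratum = het
        if unit is None:
            unit = 2000.0
    if covariates is None:
        covariates = default_covariates(samples)

    x = _exposure(het_stratum, unit, exposure).reindex(samples.index)
    cov = _covariate_frame(samples, covariates)
    y = (samples["case_status"] == "case").astype(float)
    design = pd.concat([x.rename("het_per_unit"), cov], axis=1)
    ok = design.notna().all(axis=1) & y.notna()
    if (~ok).any():
        logger.info("dropping %d individuals with missing exposure or "
                    "covariates", int((~ok).sum()))
    design, y = design[ok], y[ok]
    n_cases = int(y.sum())
    n_controls = int((1 - y).sum())
    if n_cases == 0 or n_controls == 0:
        raise ValueError("need both cases and controls to fit the model")

    X = sm.add_constant(design, has_constant="add")
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error",
                                  sm.tools.sm_exceptions.PerfectSeparationWarning)
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        converged = bool(fit.mle_retvals.get("converged", False))
        beta = float(fit.params["het_per_unit"])
        se = float(fit.bse["het_per_unit"])
    except Exception as exc:  # separation / singular design
        logger.warning("CHD model failed to converge: %s", exc)
        converged, beta, se = False, np.nan, np.nan
    if not np.isfinite(beta) or not np.isfinite(se):
        converged = False
        beta = se = np.nan
    if converged:
        zstat = beta / se
        p = 2.0 * stats.norm.sf(abs(zstat))
        res = AssociationResult(
            stratum=stratum, unit=unit, exposure=exposure,
            beta_per_unit=beta, se_per_unit=se,
            odds_ratio=float(np.exp(beta)),
            ci_low=float(np.exp(beta - Z95 * se)),
            ci_high=float(np.exp(beta + Z95 * se)),
            p_value=float(p), n_cases=n_cases, n_controls=n_controls,
            covariates=list(covariates), converged=True)
    else:
        res = AssociationResult(
            stratum=stratum, unit=unit, exposure=exposure,
            beta_per_unit=np.nan, se_per_unit=np.nan, odds_ratio=np.nan,
            ci_low=np.nan, ci_high=np.nan, p_value=np.nan,
            n_cases=n_cases, n_controls=n_controls,
            covariates=list(covariates), converged=False)
    return res


def fit_biomarker_model(samples: pd.DataFrame,
                        het: Union[HetProfile, pd.DataFrame],
                        trait: str, stratum: str,
                        unit: Optional[float] = None,
                        exposure: str = "count",
                        random_intercept: bool = False,
                        covariates: Optional[Sequence[str]] = None,
                        ) -> BiomarkerResult:
    """Linear (optionally mixed) model of a trait on heterozygosity.

    Adjusts for age, smoking, eigenvectors and case-control status; with
    ``random_intercept`` a per-matched-set random intercept is added and
    the model is fit by REML.
    """
    if isinstance(het, HetProfile):
        if unit is None:
            unit = het.units.get(stratum, 2000.0)
        het_stratum = het.stratum(stratum)
    else:
        het_stratum = het
        if unit is None:
            unit = 2000.0
    if covariates is None:
        covariates = default_covariates(samples)
    if trait not in samples.columns:
        raise ValueError(f"trait {trait!r} not found in sample table")

    x = _exposure(het_stratum, unit, exposure).reindex(samples.index)
    cov = _covariate_frame(samples, covariates)
    is_case = (samples["case_status"] == "case").astype(float)
    y = samples[trait].astype(float)
    design = pd.concat([x.rename("het_per_unit"), cov,
                        is_case.rename("is_case")], axis=1)
    ok = design.notna().all(axis=1) & y.notna()
    design, y = design[ok], y[ok]
    if len(y) < 10:
        raise ValueError(f"trait {trait!r}: fewer than 10 non-missing "
                         "observations")
    if float(np.var(y)) == 0.0:
        raise ValueError(f"trait {trait!r} has zero variance")

    X = sm.add_constant(design, has_constant="add")
    if random_intercept:
        groups = samples.loc[ok.index[ok], "matched_set_id"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.MixedLM(y, X, groups=groups).fit(reml=True)
        form = "random-intercept-by-set"
    else:
        fit = sm.OLS(y, X).fit()
        form = "fixed-only"
    beta = float(fit.params["het_per_unit"])
    se = float(fit.bse["het_per_unit"])
    p = float(fit.pvalues["het_per_unit"])
    return BiomarkerResult(trait=trait, stratum=stratum, unit=unit,
                           beta_per_unit=beta, se_per_unit=se, p_value=p,
                           n=int(len(y)),
                           covariates=list(covariates) + ["is_case"],
                           model_form=form)


def subgroup_filter(samples: pd.DataFrame,
                    predicate: Union[str, Callable[[pd.DataFrame],
                                                   pd.Series]],
                    ) -> pd.DataFrame:
    """Restrict the sample table to a subgroup.

    ``predicate`` is ``"age_lt_65"`` (strictly below 65 at blood draw) or
    a callable returning a boolean mask. Matched sets broken by the
    filter are kept as-is: the analysis model is unconditional, so set
    integrity is not required.
    """
    if predicate == "age_lt_65":
        mask = samples["age"] < 65
    elif callable(predicate):
        mask = predicate(samples).astype(bool)
    else:
        raise ValueError(f"unknown predicate {predicate!r}")
    out = samples[mask]
    if out.empty:
        raise ValueError("subgroup is empty")
    return out


def build_reports(het: HetProfile, samples: pd.DataFrame,
                  assoc_results: Sequence[AssociationResult],
                  biomarker_results: Sequence[BiomarkerResult] = (),
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Render summary tables of the analysis.

    The first table gives, per stratum, case and control mean +/- SD
    heterozygous-locus counts with a two-sided Welch t-test p-value for
    the mean difference, then the adjusted OR (95% CI) per reporting
    unit. The second gives, per trait x stratum, beta +/- SE per unit.
    """
    rows = []
    cases = samples.index[samples["case_status"] == "case"]
    controls = samples.index[samples["case_status"] == "control"]
    by_stratum = {r.stratum: r for r in assoc_results}
    for name in het.strata:
        counts = het.counts(name)
        ca = counts.reindex(cases).dropna()
        co = counts.reindex(controls).dropna()
        t_p = np.nan
        if len(ca) > 1 and len(co) > 1:
            t_p = float(stats.ttest_ind(ca, co, equal_var=False).pvalue)
        row = {
            "stratum": name,
            "case_mean": float(ca.mean()), "case_sd": float(ca.std()),
            "control_mean": float(co.mean()), "control_sd": float(co.std()),
            "mean_diff_p": t_p, "mean_diff_test": "welch_t",
        }
        r = by_stratum.get(name)
        if r is not None:
            row.update(unit=r.unit, odds_ratio=r.odds_ratio,
                       ci_low=r.ci_low, ci_high=r.ci_high,
                       or_p=r.p_value, n_cases=r.n_cases,
                       n_controls=r.n_controls)
        rows.append(row)
    table1 = pd.DataFrame(rows)

    table2 = pd.DataFrame([{
        "trait": b.trait, "stratum": b.stratum, "unit": b.unit,
        "beta_per_unit": b.beta_per_unit, "se_per_unit": b.se_per_unit,
        "p_value": b.p_value, "n": b.n, "model_form": b.model_form,
    } for b in biomarker_results])
    return table1, table2


def table_to_markdown(df: pd.DataFrame, float_fmt: str = "{:.4g}") -> str:
    """Small GitHub-markdown renderer (no tabulate dependency)."""
    def fmt(v):
        if isinstance(v, float):
            return "" if np.isnan(v) else float_fmt.format(v)
        return str(v)
    cols = list(df.columns)
    lines = ["| " + " | ".join(cols) + " |",
             "| " + " | ".join("---" for _ in cols) + " |"]
    for _, row in df.iterrows():
        lines.append("| " + " | ".join(fmt(row[c]) for c in cols) + " |")
    return "\n".join(lines) + "\n"
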