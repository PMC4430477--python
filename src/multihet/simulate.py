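"""Synthetic nested case-control cohorts with known inbreeding structure.

The generator emulates the statistical structure a genome-wide
heterozygosity analysis assumes, with every piece of ground truth kept:

* an array-like panel of independent biallelic autosomal SNPs with allele
  frequencies drawn uniformly on ``[maf_low, maf_high]``;
* population structure via the Balding-Nichols model: subpopulation
  frequencies drawn around the ancestral frequency with variance
  ``fst * p * (1 - p)``;
* per-individual inbreeding coefficients ``F`` drawn from a Beta
  distribution re-parameterised by mean and SD — the variance in ``F``
  (identity disequilibrium) is what makes multilocus heterozygosity an
  informative proxy for inbreeding;
* genotypes that are autozygous (homozygous, identical by descent) with
  probability ``F_i`` and Hardy-Weinberg otherwise, so the expected
  heterozygosity at frequency ``p`` is ``(1 - F_i) * 2 p (1 - p)``;
* disease generated in discrete time with a logistic hazard whose
  log-odds shift by ``beta_per_2000`` per 2000 extra heterozygous loci;
* risk-set sampling: each incident case is matched to ``controls_per_case``
  individuals still event-free at the case's event time, drawn from the
  same age band and smoking stratum; a control who later becomes a case
  ("converter") is counted once, as a case;
* optional continuous biomarkers linear in heterozygosity (slope zero by
  default) with age and smoking terms and Gaussian noise.

Identical ``SimulationConfig`` (including ``seed``) gives bit-identical
output.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit

from .containers import GenotypeMatrix, validate_annotation

logger = logging.getLogger(__name__)

#: trait panel mirroring a cardiovascular risk-factor battery
#: (lipids, inflammatory markers, adhesion molecules, adiponectin, BMI)
DEFAULT_BIOMARKERS = (
    "hdl", "ldl", "triglycerides", "crp", "il6", "fibrinogen",
    "homocysteine", "e_selectin", "icam1", "vcam1",
    "adiponectin_total", "adiponectin_hmw", "bmi",
)

#: stratum proportions matching a ~700k-SNP array where ~81% of SNPs fall
#: within protein-coding genes plus flanks and ~0.7% are nonsynonymous
DEFAULT_GENIC_FRACTION = 562289 / 692794
DEFAULT_NONSYN_FRACTION = 4760 / 692794


class ConfigurationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Knobs of the cohort generator; defaults are the study conditions.

    ``baseline_prevalence`` is the per-period event probability of the
    discrete-time logistic hazard; follow-up lasts ``n_periods`` periods.
    """

    n_individuals: int
    n_snps: int
    maf_low: float = 0.01
    maf_high: float = 0.5
    f_mean: float = 0.002
    f_sd: float = 0.008
    n_subpops: int = 1
    fst: float = 0.0
    beta_per_2000: float = 0.0
    baseline_prevalence: float = 0.02
    n_periods: int = 10
    controls_per_case: int = 2
    missing_rate: float = 0.002
    seed: int = 0
    # matching / demographics
    age_min: float = 45.0
    age_max: float = 75.0
    age_band_years: float = 2.0
    smoking_prevalence: float = 0.25
    reported_sex: str = "female"
    # annotation
    n_chromosomes: int = 4
    genic_fraction: float = DEFAULT_GENIC_FRACTION
    nonsyn_fraction: float = DEFAULT_NONSYN_FRACTION
    genic_block_snps: int = 400
    platform_private_snps: int = 0
    # confounding lever: per-subpopulation log-odds shift of disease risk
    subpop_risk: Optional[Sequence[float]] = None
    # biomarkers
    biomarker_names: Sequence[str] = DEFAULT_BIOMARKERS
    biomarker_gamma_per_2000: float = 0.0
    biomarker_noise_sd: float = 1.0
    biomarker_missing_fraction: float = 0.0
    biomarker_age_coef: float = 0.05
    biomarker_smoking_coef: float = 0.3

    def __post_init__(self):
        if self.n_individuals < 1 or self.n_snps < 1:
            raise ConfigurationError("n_individuals and n_snps must be >= 1")
        if not (0 < self.maf_low <= self.maf_high <= 0.5):
            raise ConfigurationError(
                f"need 0 < maf_low <= maf_high <= 0.5, got "
                f"[{self.maf_low}, {self.maf_high}]")
        if not (0 <= self.f_mean < 1):
            raise ConfigurationError("f_mean must be in [0, 1)")
        if self.f_sd < 0:
            raise ConfigurationError("f_sd must be >= 0")
        if not (0 <= self.fst < 1):
            raise ConfigurationError("fst must be in [0, 1)")
        if self.n_subpops < 1:
            raise ConfigurationError("n_subpops must be >= 1")
        if not (0 < self.baseline_prevalence < 1):
            raise ConfigurationError("baseline_prevalence must be in (0, 1)")
        if not (0 <= self.missing_rate < 1):
            raise ConfigurationError("missing_rate must be in [0, 1)")
        if self.controls_per_case < 1:
            raise ConfigurationError("controls_per_case must be >= 1")
        if not (0 <= self.genic_fraction <= 1):
            raise ConfigurationError("genic_fraction must be in [0, 1]")
        if self.subpop_risk is not None and \
                len(self.subpop_risk) != self.n_subpops:
            raise ConfigurationError(
                "subpop_risk must have one entry per subpopulation")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def to_file(self, path) -> None:
        d = dataclasses.asdict(self)
        d["biomarker_names"] = list(self.biomarker_names)
        if self.subpop_risk is not None:
            d["subpop_risk"] = list(self.subpop_risk)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_file(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(**d)


@dataclass
class CohortTruth:
    """Ground truth of a simulated cohort, for parameter-recovery tests."""
    f: np.ndarray                  # per-individual inbreeding coefficient
    subpop: np.ndarray             # per-individual subpopulation label
    beta_per_2000: float
    ancestral_freq: np.ndarray     # per-SNP ancestral allele frequency
    subpop_freqs: np.ndarray       # (n_subpops, n_snps) drifted frequencies

    def __post_init__(self):
        if not ((self.subpop_freqs >= 0) & (self.subpop_freqs <= 1)).all():
            raise ValueError("drifted frequencies must lie in [0, 1]")


@dataclass
class SimulatedCohort:
    """Bundle returned by :func:`simulate_cohort`."""
    genotypes: GenotypeMatrix      # nested case-control sample only
    samples: pd.DataFrame          # covariates/outcomes for that sample
    annotation: pd.DataFrame
    genes: pd.DataFrame
    truth: CohortTruth
    cohort_het_counts: pd.Series   # all cohort individuals, pre-sampling
    config: SimulationConfig


def _beta_parameters(mean: float, sd: float) -> tuple[float, float]:
    var = sd * sd
    if var >= mean * (1 - mean):
        raise ConfigurationError(
            f"f_sd={sd} too large for f_mean={mean} (Beta constraint)")
    common = mean * (1 - mean) / var - 1.0
    return mean * common, (1 - mean) * common


def sample_ids(n: int) -> pd.Index:
    return pd.Index([f"ind{i:06d}" for i in range(n)], name="sample_id")


def snp_ids(m: int) -> pd.Index:
    return pd.Index([f"snp{j:07d}" for j in range(m)], name="snp_id")


def simulate_allele_frequencies(
        config: SimulationConfig,
        rng: Optional[np.random.Generator] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ancestral and per-subpopulation allele frequencies.

    Returns ``(ancestral, subpop_freqs)`` where ``subpop_freqs`` has shape
    ``(n_subpops, n_snps)``. Under Balding-Nichols each subpopulation
    frequency is Beta-distributed around the ancestral ``p`` with variance
    ``fst * p * (1 - p)``; with ``fst == 0`` all subpopulations equal the
    ancestral frequency exactly.
    """
    rng = config.rng() if rng is None else rng
    p = rng.uniform(config.maf_low, config.maf_high, size=config.n_snps)
    if config.n_subpops == 1 or config.fst == 0.0:
        sub = np.broadcast_to(p, (config.n_subpops, config.n_snps)).copy()
        return p, sub
    scale = (1.0 - config.fst) / config.fst
    a = p * scale
    b = (1.0 - p) * scale
    sub = rng.beta(a, b, size=(config.n_subpops, config.n_snps))
    return p, sub


def draw_truth(config: SimulationConfig,
               rng: Optional[np.random.Generator] = None) -> CohortTruth:
    """Draw per-individual inbreeding and subpopulation labels plus
    allele frequencies into a :class:`CohortTruth`."""
    rng = config.rng() if rng is None else rng
    p, sub = simulate_allele_frequencies(config, rng)
    n = config.n_individuals
    if config.f_sd == 0.0:
        f = np.full(n, config.f_mean)
    elif config.f_mean == 0.0:
        f = np.zeros(n)
    else:
        a, b = _beta_parameters(config.f_mean, config.f_sd)
        f = rng.beta(a, b, size=n)
    f = np.clip(f, 0.0, 1.0 - 1e-9)
    labels = rng.integers(config.n_subpops, size=n)
    return CohortTruth(f=f, subpop=labels, beta_per_2000=config.beta_per_2000,
                       ancestral_freq=p, subpop_freqs=sub)


def _bernoulli_indices(rng: np.random.Generator, m: int,
                       prob: float) -> np.ndarray:
    """Indices of successes of m iid Bernoulli(prob) trials.

    Drawn as a Binomial(m, prob) count followed by a uniform sample of
    distinct indices (Floyd's algorithm — O(count), not O(m)); exactly
    equivalent to thinning the full index range.
    """
    count = int(rng.binomial(m, prob))
    if count == 0:
        return np.empty(0, dtype=np.int64)
    if count > m // 2:
        return rng.permutation(m)[:count]
    chosen: set[int] = set()
    for j in range(m - count, m):
        t = int(rng.integers(0, j + 1))
        chosen.add(j if t in chosen else t)
    return np.fromiter(chosen, dtype=np.int64, count=count)


def simulate_genotypes(freqs: np.ndarray, truth: CohortTruth,
                       config: SimulationConfig,
                       rng: Optional[np.random.Generator] = None,
                       ) -> GenotypeMatrix:
    """Simulate the genotype matrix given frequencies and truth.

    ``freqs`` is the ``(n_subpops, n_snps)`` drifted-frequency matrix
    (``truth.subpop_freqs``). For individual ``i`` at SNP ``j`` with
    subpopulation frequency ``p``: with probability ``F_i`` the genotype is
    autozygous (code 2 with probability ``p``, else 0); otherwise it is a
    Hardy-Weinberg draw. Calls are then masked missing independently at
    ``missing_rate``.
    """
    rng = config.rng() if rng is None else rng
    freqs = np.atleast_2d(np.asarray(freqs, dtype=np.float64))
    n, m = config.n_individuals, config.n_snps
    if freqs.shape[1] != m:
        raise ConfigurationError("frequency matrix does not match n_snps")
    if len(truth.f) != n:
        raise ConfigurationError("truth does not match n_individuals")
    g = np.empty((n, m), dtype=np.int8)
    f32 = np.float32
    # chunk rows so scratch uniforms stay bounded; chunk size depends only
    # on m, keeping the RNG stream (hence output) reproducible
    chunk = max(1, int(2.0e7 // m))
    for k in range(freqs.shape[0]):
        rows = np.flatnonzero(truth.subpop == k)
        if rows.size == 0:
            continue
        p = freqs[k]
        q2 = ((1.0 - p) ** 2).astype(f32)
        t2 = (q2 + (2.0 * p * (1.0 - p)).astype(f32)).astype(f32)
        for s in range(0, rows.size, chunk):
            r = rows[s:s + chunk]
            u = rng.random((r.size, m), dtype=f32)
            blk = (u >= q2).astype(np.int8)
            blk += u >= t2
            # autozygous loci: the iid Bernoulli(F_i) mask is drawn
            # sparsely (binomial count, then a uniform distinct-index
            # sample), which is distributionally identical and cheap for
            # realistic F
            for i, row in enumerate(r):
                fi = truth.f[row]
                if fi <= 0:
                    continue
                cols = _bernoulli_indices(rng, m, fi)
                if cols.size:
                    blk[i, cols] = \
                        (rng.random(cols.size) < p[cols]).astype(np.int8) * 2
            if config.missing_rate > 0:
                for i in range(r.size):
                    cols = _bernoulli_indices(rng, m,
                                              config.missing_rate)
                    if cols.size:
                        blk[i, cols] = -1
            g[r] = blk
    return GenotypeMatrix(g, sample_ids(n), snp_ids(m))


def simulate_annotation(config: SimulationConfig,
                        rng: Optional[np.random.Generator] = None,
                        flank_up_kb: float = 70.0,
                        flank_down_kb: float = 20.0,
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Place SNPs on synthetic chromosomes and build a gene table.

    SNPs sit at increasing positions on ``n_chromosomes`` autosomes. Genes
    are laid out in alternating blocks sized so that, after the
    flank-extended genic interval rule (``flank_up_kb`` upstream /
    ``flank_down_kb`` downstream, strand-oriented), the genic stratum
    covers ``genic_fraction`` of SNPs. A random subset of SNPs strictly
    inside gene bodies is flagged nonsynonymous (so nonsynonymous implies
    genic by construction).
    """
    rng = config.rng() if rng is None else rng
    m = config.n_snps
    up = int(flank_up_kb * 1000)
    down = int(flank_down_kb * 1000)
    n_chrom = max(2, config.n_chromosomes)
    per = np.full(n_chrom, m // n_chrom)
    per[:m % n_chrom] += 1

    chroms = np.empty(m, dtype=object)
    pos = np.empty(m, dtype=np.int64)
    gene_id = np.full(m, None, dtype=object)
    gene_rows = []
    body = np.zeros(m, dtype=bool)

    gfrac = config.genic_fraction
    gblock = config.genic_block_snps
    if 0 < gfrac < 1:
        gap = max(1, round(gblock * (1 - gfrac) / gfrac))
    else:
        gap = 0
    period = gblock + gap

    offset = 0
    n_genes = 0
    for c in range(n_chrom):
        nc = per[c]
        spacing = rng.integers(3000, 5001, size=nc)
        p_chr = 100_000 + np.cumsum(spacing)
        sl = slice(offset, offset + nc)
        chroms[sl] = str(c + 1)
        pos[sl] = p_chr
        if gfrac > 0:
            start_idx = np.arange(0, nc, period) if gfrac < 1 else \
                np.array([0])
            if gfrac == 1:
                blocks = [(0, nc)]
            else:
                blocks = [(i, min(i + gblock, nc)) for i in start_idx]
            for lo, hi in blocks:
                first, last = p_chr[lo], p_chr[hi - 1]
                if last - first <= up + down + 1000:
                    continue  # too short to host flanks; stays intergenic
                strand = "+" if rng.random() < 0.5 else "-"
                if strand == "+":
                    gstart, gend = first + up, last - down
                else:
                    gstart, gend = first + down, last - up
                gid = f"gene{n_genes:05d}"
                n_genes += 1
                gene_rows.append((gid, str(c + 1), gstart, gend, strand))
                inside = (p_chr[lo:hi] >= gstart) & (p_chr[lo:hi] <= gend)
                idx = np.arange(offset + lo, offset + hi)[inside]
                gene_id[idx] = gid
                body[idx] = True
        offset += nc

    is_ns = np.zeros(m, dtype=bool)
    n_ns = round(config.nonsyn_fraction * m)
    pool = np.flatnonzero(body)
    if n_ns > 0 and pool.size:
        take = min(n_ns, pool.size)
        is_ns[rng.choice(pool, size=take, replace=False)] = True

    platforms = np.full(m, "A,B", dtype=object)
    if config.platform_private_snps > 0:
        priv = rng.choice(m, size=min(config.platform_private_snps, m),
                          replace=False)
        platforms[priv[::2]] = "A"
        platforms[priv[1::2]] = "B"

    ann = pd.DataFrame({
        "chrom": chroms,
        "pos": pos,
        "is_autosomal": True,
        "gene_id": gene_id,
        "is_nonsynonymous": is_ns,
        "platforms": platforms,
    }, index=snp_ids(m))
    genes = pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "start",
                                             "end", "strand"])
    return validate_annotation(ann), genes


def _event_times(het: np.ndarray, subpop: np.ndarray,
                 config: SimulationConfig,
                 rng: np.random.Generator) -> np.ndarray:
    """Geometric event times from the discrete-time logistic hazard.

    Returns float array; ``inf`` means no event ever.
    """
    eta = np.full(het.shape, logit(config.baseline_prevalence))
    if config.beta_per_2000 != 0.0:
        eta = eta + config.beta_per_2000 * (het - het.mean()) / 2000.0
    if config.subpop_risk is not None:
        eta = eta + np.asarray(config.subpop_risk)[subpop]
    p = expit(eta)
    u = rng.random(het.shape[0])
    with np.errstate(divide="ignore"):
        t = np.ceil(np.log1p(-u) / np.log1p(-p))
    t[p <= 0] = np.inf
    t[p >= 1] = 1.0
    return t


def assign_outcomes_and_match(geno: GenotypeMatrix, truth: CohortTruth,
                              config: SimulationConfig,
                              rng: Optional[np.random.Generator] = None,
                              het_counts: Optional[np.ndarray] = None,
                              ) -> pd.DataFrame:
    """Generate outcomes and draw the risk-set-sampled matched sample.

    Event risk is logistic in centred heterozygosity (per 2000 loci). Each
    case (event within follow-up) is matched, in event-time order, to
    ``controls_per_case`` controls still event-free at the case's event
    time from the same age band and smoking stratum; controls are used at
    most once and converters are retained once, as cases. Matched sets
    with no eligible control are dropped and logged.

    Returns the covariate table of the nested case-control sample; the
    attrs carry ``n_dropped_sets`` and ``n_converters``.
    """
    rng = config.rng() if rng is None else rng
    n = geno.n_samples
    if het_counts is None:
        het_counts = (geno.genotypes == 1).sum(axis=1)
    het_counts = np.asarray(het_counts, dtype=np.float64)

    age = rng.uniform(config.age_min, config.age_max, size=n)
    band = np.floor((age - config.age_min) /
                    config.age_band_years).astype(int)
    smoking = (rng.random(n) < config.smoking_prevalence).astype(int)
    etime = _event_times(het_counts, truth.subpop, config, rng)
    is_case = etime <= config.n_periods

    case_idx = np.flatnonzero(is_case)
    order = np.lexsort((case_idx, etime[case_idx]))
    case_idx = case_idx[order]

    used_as_control = np.zeros(n, dtype=bool)
    control_set = {}
    case_set = {}
    dropped = 0
    for set_id, c in enumerate(case_idx):
        t = etime[c]
        eligible = ((band == band[c]) & (smoking == smoking[c]) &
                    ~used_as_control & (etime > t))
        eligible[c] = False
        pool = np.flatnonzero(eligible)
        if pool.size == 0:
            dropped += 1
            logger.info("matched set for case %s dropped: no eligible "
                        "control in age band %d / smoking %d",
                        geno.sample_ids[c], band[c], smoking[c])
            continue
        take = min(config.controls_per_case, pool.size)
        chosen = rng.choice(pool, size=take, replace=False)
        used_as_control[chosen] = True
        case_set[c] = set_id
        for idx in chosen:
            control_set[idx] = set_id

    # converters: sampled as a control, later became a case -> keep once
    converters = [i for i in control_set if is_case[i]]
    for i in converters:
        del control_set[i]

    rows = []
    for i, sid in case_set.items():
        rows.append((i, "case", sid))
    for i, sid in control_set.items():
        rows.append((i, "control", sid))
    rows.sort()
    idx = [r[0] for r in rows]
    samples = pd.DataFrame({
        "age": age[idx],
        "age_band": band[idx],
        "smoking": smoking[idx],
        "reported_sex": config.reported_sex,
        "case_status": [r[1] for r in rows],
        "matched_set_id": [r[2] for r in rows],
        "event_time": [etime[i] if np.isfinite(etime[i]) else np.nan
                       for i in idx],
        "subpop": truth.subpop[idx],
    }, index=geno.sample_ids[idx])
    samples.attrs["n_dropped_sets"] = dropped
    samples.attrs["n_converters"] = len(converters)
    return samples


def simulate_biomarkers(samples: pd.DataFrame, het_counts: pd.Series,
                        config: SimulationConfig,
                        rng: Optional[np.random.Generator] = None,
                        ) -> pd.DataFrame:
    """Append biomarker columns linear in heterozygosity.

    Each trait is ``gamma_per_2000 * het/2000 + age and smoking terms +
    Gaussian noise``; ``gamma`` defaults to 0 (no heterozygosity-trait
    relationship). ``biomarker_missing_fraction`` masks an exact-size
    random subset per trait, mimicking traits measured only in an initial
    subset of the case-control pairs.
    """
    rng = config.rng() if rng is None else rng
    out = samples.copy()
    het = het_counts.reindex(samples.index).to_numpy(dtype=float)
    n = len(out)
    n_miss = round(config.biomarker_missing_fraction * n)
    for name in config.biomarker_names:
        y = (config.biomarker_gamma_per_2000 * het / 2000.0
             + config.biomarker_age_coef * (out["age"].to_numpy() - 60.0)
             + config.biomarker_smoking_coef * out["smoking"].to_numpy())
        if config.biomarker_noise_sd > 0:
            y = y + rng.normal(0.0, config.biomarker_noise_sd, size=n)
        if n_miss > 0:
            y = y.astype(float)
            y[rng.choice(n, size=n_miss, replace=False)] = np.nan
        out[name] = y
    return out


def simulate_cohort(config: SimulationConfig,
                    with_biomarkers: bool = True,
                    keep_cohort_genotypes: bool = False) -> SimulatedCohort:
    """Run the full generator: frequencies -> genotypes -> annotation ->
    outcomes/matching -> biomarkers.

    The returned genotype matrix is restricted to the nested case-control
    sample (set ``keep_cohort_genotypes`` to retain the whole cohort).
    """
    rng = config.rng()
    truth = draw_truth(config, rng)
    geno = simulate_genotypes(truth.subpop_freqs, truth, config, rng)
    ann, genes = simulate_annotation(config, rng)
    het_all = pd.Series((geno.genotypes == 1).sum(axis=1),
                        index=geno.sample_ids, name="het_count")
    samples = assign_outcomes_and_match(geno, truth, config, rng,
                                        het_counts=het_all.to_numpy())
    if with_biomarkers:
        samples = simulate_biomarkers(samples, het_all, config, rng)
    sub = geno if keep_cohort_genotypes else \
        geno.subset_samples(samples.index)
    return SimulatedCohort(genotypes=sub, samples=samples, annotation=ann,
                           genes=genes, truth=truth,
                           cohort_het_counts=het_all, config=config)
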