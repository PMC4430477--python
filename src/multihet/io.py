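"""Readers and writers for the standard genotype and table formats.

PLINK bed/bim/fam and VCF are supported for genotypes; covariate and SNP
annotation tables are tab-separated text with a header. Genotype codes
count non-reference alleles, so a VCF ``0/1`` call maps to code 1 and the
bed A1 allele is taken to be the alternate allele. Readers round-trip the
writers exactly (codes, ids, order).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .containers import (ANNOTATION_COLUMNS, GenotypeMatrix, SchemaError,
                         validate_annotation, validate_samples)

logger = logging.getLogger(__name__)

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # SNP-major bed
# 2-bit bed field -> allele-count code (A1 = alternate allele)
_BED_DECODE = np.array([2, -1, 1, 0], dtype=np.int8)
# allele-count code (-1,0,1,2 -> index 0..3 after +1) -> 2-bit bed field
_BED_ENCODE = np.array([1, 3, 2, 0], dtype=np.uint8)


class ParseError(ValueError):
    pass


def _ext(prefix, ext: str) -> Path:
    return Path(str(prefix) + "." + ext)


# ---------------------------------------------------------------- PLINK

def write_plink(prefix, geno: GenotypeMatrix,
                annotation: Optional[pd.DataFrame] = None,
                samples: Optional[pd.DataFrame] = None) -> None:
    """Write ``prefix``.bed/.bim/.fam (SNP-major bed)."""
    prefix = Path(prefix)
    n, m = geno.n_samples, geno.n_snps
    codes = geno.genotypes.T  # SNP-major
    fields = _BED_ENCODE[codes.astype(np.int16) + 1]
    width = (n + 3) // 4
    padded = np.zeros((m, width * 4), dtype=np.uint8)
    padded[:, :n] = fields
    packed = (padded[:, 0::4] | (padded[:, 1::4] << 2) |
              (padded[:, 2::4] << 4) | (padded[:, 3::4] << 6))
    with open(_ext(prefix, "bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())

    if annotation is not None:
        ann = annotation.reindex(geno.snp_ids)
        chrom = ann["chrom"].astype(str)
        pos = ann["pos"].astype(int)
    else:
        chrom = pd.Series("1", index=geno.snp_ids)
        pos = pd.Series(np.arange(1, m + 1), index=geno.snp_ids)
    bim = pd.DataFrame({
        "chrom": chrom.to_numpy(), "snp_id": geno.snp_ids, "cm": 0,
        "pos": pos.to_numpy(), "a1": "B", "a2": "A",
    })
    bim.to_csv(_ext(prefix, "bim"), sep="\t", header=False,
               index=False)

    sex_code = pd.Series(0, index=geno.sample_ids)
    if samples is not None and "reported_sex" in samples.columns:
        sex_code = samples["reported_sex"].map(
            {"male": 1, "female": 2}).reindex(geno.sample_ids).fillna(0)
    fam = pd.DataFrame({
        "fid": geno.sample_ids, "iid": geno.sample_ids,
        "father": 0, "mother": 0,
        "sex": sex_code.astype(int).to_numpy(), "pheno": -9,
    })
    fam.to_csv(_ext(prefix, "fam"), sep="\t", header=False,
               index=False)


def read_plink(prefix) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Read ``prefix``.bed/.bim/.fam; returns the genotype matrix and an
    annotation skeleton (chrom/pos filled, flags defaulted)."""
    prefix = Path(prefix)
    try:
        bim = pd.read_csv(_ext(prefix, "bim"), sep=r"\s+",
                          header=None,
                          names=["chrom", "snp_id", "cm", "pos",
                                 "a1", "a2"],
                          dtype={"chrom": str})
        fam = pd.read_csv(_ext(prefix, "fam"), sep=r"\s+",
                          header=None,
                          names=["fid", "iid", "father", "mother",
                                 "sex", "pheno"])
    except Exception as exc:
        raise ParseError(f"cannot parse bim/fam for {prefix}: {exc}")
    n, m = len(fam), len(bim)
    raw = np.fromfile(_ext(prefix, "bed"), dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise ParseError(f"{prefix}.bed: bad magic bytes "
                         "(not a SNP-major bed file)")
    width = (n + 3) // 4
    body = raw[3:]
    if body.size != m * width:
        raise ParseError(f"{prefix}.bed: expected {m * width} data bytes, "
                         f"found {body.size}")
    body = body.reshape(m, width)
    fields = np.empty((m, width * 4), dtype=np.uint8)
    for shift in range(4):
        fields[:, shift::4] = (body >> (2 * shift)) & 0x3
    codes = _BED_DECODE[fields[:, :n]].T
    geno = GenotypeMatrix(codes, fam["iid"].astype(str), bim["snp_id"])
    ann = annotation_skeleton(bim["snp_id"], bim["chrom"], bim["pos"])
    return geno, ann


# ------------------------------------------------------------------ VCF

def write_vcf(path, geno: GenotypeMatrix,
              annotation: Optional[pd.DataFrame] = None) -> None:
    """Write a plain-text VCF 4.2 with GT-only biallelic records."""
    if annotation is not None:
        ann = annotation.reindex(geno.snp_ids)
        chrom = ann["chrom"].astype(str).to_numpy()
        pos = ann["pos"].astype(int).to_numpy()
    else:
        chrom = np.full(geno.n_snps, "1", dtype=object)
        pos = np.arange(1, geno.n_snps + 1)
    gt = np.array(["./.", "0/0", "0/1", "1/1"], dtype=object)
    codes = geno.genotypes.astype(np.int16) + 1
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,'
                 'Description="Genotype">\n')
        for c in dict.fromkeys(chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, geno.sample_ids)) + "\n")
        for j, sid in enumerate(geno.snp_ids):
            calls = "\t".join(gt[codes[:, j]])
            fh.write(f"{chrom[j]}\t{pos[j]}\t{sid}\tA\tG\t.\t.\t.\tGT\t"
                     f"{calls}\n")


def read_vcf(path, strict: bool = False
             ) -> tuple[GenotypeMatrix, pd.DataFrame, int]:
    """Read a (plain or bgzipped) VCF into allele-count codes.

    Non-biallelic records are dropped (counted in the returned integer)
    unless ``strict`` is set, in which case they raise. Half-calls are
    treated as missing, or rejected under ``strict``.
    """
    from cyvcf2 import VCF
    vcf = VCF(str(path), gts012=True)
    sample_ids = list(vcf.samples)
    codes, ids, chroms, poss = [], [], [], []
    dropped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            if strict:
                raise ParseError(
                    f"non-biallelic record at {var.CHROM}:{var.POS}")
            dropped += 1
            continue
        if strict:
            for g in var.genotypes:
                alleles = g[:-1]
                if (-1 in alleles) and any(a >= 0 for a in alleles):
                    raise ParseError(
                        f"half-call at {var.CHROM}:{var.POS}")
        # gts012: 0/1/2 = alt-allele count, 3 = unknown
        row = var.gt_types.astype(np.int8)
        row[row == 3] = -1
        codes.append(row)
        ids.append(var.ID if var.ID not in (None, ".")
                   else f"{var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
    if dropped:
        logger.info("read_vcf: dropped %d non-biallelic record(s)", dropped)
    if not codes:
        raise ParseError(f"no usable biallelic records in {path}")
    geno = GenotypeMatrix(np.stack(codes, axis=1), sample_ids, ids)
    ann = annotation_skeleton(pd.Index(ids, name="snp_id"), chroms, poss)
    return geno, ann, dropped


def read_genotypes(path, format: str = "plink", strict: bool = False
                   ) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Dispatch on ``format`` in {"plink", "vcf"}; ``path`` is the PLINK
    prefix or the VCF path."""
    if format == "plink":
        return read_plink(path)
    if format == "vcf":
        geno, ann, _ = read_vcf(path, strict=strict)
        return geno, ann
    raise ValueError(f"unknown genotype format {format!r}")


def write_genotypes(path, geno: GenotypeMatrix,
                    annotation: Optional[pd.DataFrame] = None,
                    samples: Optional[pd.DataFrame] = None,
                    format: str = "plink") -> None:
    if format == "plink":
        write_plink(path, geno, annotation, samples)
    elif format == "vcf":
        write_vcf(path, geno, annotation)
    else:
        raise ValueError(f"unknown genotype format {format!r}")


# ----------------------------------------------------------------- TSVs

def annotation_skeleton(snp_ids, chrom, pos) -> pd.DataFrame:
    """Annotation with positional columns filled and flags defaulted:
    autosomal unless the chromosome label is X/Y/MT, no gene assignment,
    nothing nonsynonymous, single unnamed platform."""
    chrom = pd.Series(list(map(str, chrom)), index=snp_ids, name="chrom")
    ann = pd.DataFrame({
        "chrom": chrom,
        "pos": pd.Series(list(pos), index=snp_ids).astype(int),
        "is_autosomal": ~chrom.str.upper().isin(["X", "Y", "MT", "M",
                                                 "23", "24", "25", "26"]),
        "gene_id": None,
        "is_nonsynonymous": False,
        "platforms": "",
    })
    ann.index.name = "snp_id"
    return ann


def write_annotation(path, annotation: pd.DataFrame) -> None:
    validate_annotation(annotation)
    annotation.to_csv(path, sep="\t", na_rep="NA",
                      index_label="snp_id")


def read_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str},
                     na_values=["NA"], keep_default_na=False)
    if "snp_id" not in df.columns:
        raise SchemaError("annotation file is missing column(s): "
                          "['snp_id']")
    df = df.set_index("snp_id")
    missing = [c for c in ("chrom", "pos") if c not in df.columns]
    if missing:
        raise SchemaError(f"annotation file is missing column(s): "
                          f"{missing}")
    if "is_autosomal" not in df.columns:
        df["is_autosomal"] = ~df["chrom"].str.upper().isin(
            ["X", "Y", "MT", "M"])
    if "gene_id" not in df.columns:
        df["gene_id"] = None
    df["gene_id"] = df["gene_id"].where(df["gene_id"].notna(), None)
    if "is_nonsynonymous" not in df.columns:
        df["is_nonsynonymous"] = False
    if "platforms" not in df.columns:
        df["platforms"] = ""
    df["is_autosomal"] = df["is_autosomal"].astype(bool)
    df["is_nonsynonymous"] = df["is_nonsynonymous"].astype(bool)
    df["platforms"] = df["platforms"].fillna("").astype(str)
    return validate_annotation(df[list(ANNOTATION_COLUMNS)
                                  + [c for c in df.columns
                                     if c not in ANNOTATION_COLUMNS]])


def write_covariates(path, samples: pd.DataFrame) -> None:
    validate_samples(samples)
    samples.to_csv(path, sep="\t", na_rep="NA",
                   index_label="sample_id")


def read_covariates(path) -> pd.DataFrame:
    """Read a sample covariate/outcome TSV.

    Mandatory columns: sample_id, age, smoking, reported_sex,
    case_status, matched_set_id. Unknown columns are preserved (treated
    as biomarkers downstream); missing values are empty fields or "NA".
    """
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    if "sample_id" not in df.columns:
        raise SchemaError("covariate file is missing column(s): "
                          "['sample_id']")
    df = df.set_index(df["sample_id"].astype(str)).drop(
        columns="sample_id")
    df.index.name = "sample_id"
    return validate_samples(df)


def write_gene_table(path, genes: pd.DataFrame) -> None:
    genes.to_csv(path, sep="\t", index=False)


def read_gene_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in ("gene_id", "chrom", "start", "end", "strand")
               if c not in df.columns]
    if missing:
        raise SchemaError(f"gene table is missing column(s): {missing}")
    return df


def read_bed_genes(path) -> pd.DataFrame:
    """Read a BED-like gene file (0-based half-open) and convert to the
    1-based inclusive convention used throughout."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "gene_id", "score",
                            "strand"],
                     dtype={"chrom": str})
    out = pd.DataFrame({
        "gene_id": df["gene_id"], "chrom": df["chrom"],
        "start": df["start"].astype(int) + 1,
        "end": df["end"].astype(int), "strand": df["strand"],
    })
    return out
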