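"""Readers and writers for genotype and clinical tables.

Genotype files are tab-delimited, one row per sample: either a plain
layout (first column the sample id, remaining columns SNP ids with values
0/1/2) or PLINK ``.raw`` additive coding, recognized by its six leading
metadata columns (FID IID PAT MAT SEX PHENOTYPE), of which IID becomes the
sample id and the rest are ignored. Clinical files carry columns
``sample_id``, ``time`` (non-negative decimal) and ``status`` (1 = event,
0 = censored); anything else is an error, never silently coerced.

On assembly, SNPs with any missing genotype and SNPs with a single
observed genotype (monomorphic) are excluded, and the exclusion counts are
logged so that SNPs in = excluded + analyzed always balances.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import DataError, GenotypeMatrix, SurvivalData

__all__ = ["Dataset", "read_genotypes", "read_clinical", "read_dataset",
           "write_genotypes", "write_clinical", "write_results",
           "write_risk_scores"]

logger = logging.getLogger("snpsurv")

_PLINK_META = ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE")


@dataclass
class Dataset:
    """Aligned genotype and clinical data plus the exclusion bookkeeping."""

    genotypes: GenotypeMatrix
    survival: SurvivalData
    excluded_missing: tuple
    excluded_monomorphic: tuple


def read_genotypes(path) -> pd.DataFrame:
    """Genotype table as a samples x SNPs DataFrame (NaN = missing).

    Accepts the plain TSV layout or PLINK .raw; validates every non-missing
    value is 0, 1 or 2.
    """
    df = pd.read_csv(path, sep=r"\s+" if _is_plink_raw(path) else "\t")
    if df.shape[1] < 2:
        raise DataError(f"{path}: expected a sample-id column plus SNP columns")
    if tuple(df.columns[:6]) == _PLINK_META:
        df = df.set_index("IID").drop(columns=list(_PLINK_META[:1] + _PLINK_META[2:]))
    else:
        df = df.set_index(df.columns[0])
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].tolist()
        raise DataError(f"{path}: duplicated sample ids {dupes}")
    values = df.apply(pd.to_numeric, errors="coerce")
    bad = values.isna() & df.notna()
    valid = values.isin((0, 1, 2)) | values.isna()
    bad |= ~valid
    if bad.any().any():
        i, j = np.argwhere(bad.values)[0]
        raise DataError(
            f"{path}: invalid genotype value {df.iloc[i, j]!r} for sample "
            f"{df.index[i]!r}, SNP {df.columns[j]!r} (expected 0, 1 or 2)")
    return values


def _is_plink_raw(path) -> bool:
    with open(path) as fh:
        header = fh.readline().split()
    return tuple(header[:6]) == _PLINK_META


def read_clinical(path) -> pd.DataFrame:
    """Clinical table indexed by sample id with ``time`` and ``status``."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    needed = {"sample_id", "time", "status"}
    if not needed.issubset(df.columns):
        raise DataError(f"{path}: clinical file must have columns {sorted(needed)}")
    df["sample_id"] = df["sample_id"].astype(str)
    if df["sample_id"].duplicated().any():
        raise DataError(f"{path}: duplicated sample ids in clinical file")
    time = pd.to_numeric(df["time"], errors="coerce")
    if time.isna().any() or (time < 0).any():
        bad = df.loc[time.isna() | (time < 0), "sample_id"].tolist()
        raise DataError(f"{path}: non-numeric or negative time for samples {bad}")
    status = pd.to_numeric(df["status"], errors="coerce")
    if not status.isin((0, 1)).all():
        bad = df.loc[~status.isin((0, 1)), "sample_id"].tolist()
        raise DataError(f"{path}: status must be 0 or 1; offending samples {bad}")
    out = pd.DataFrame({"time": time.values, "status": status.astype(int).values},
                       index=df["sample_id"].values)
    return out


def read_dataset(genotype_path, clinical_path) -> Dataset:
    """Read, validate, align and filter a genotype/clinical file pair.

    Sample order follows the genotype file; unmatched ids on either side
    are an error. SNPs with missing genotypes are dropped (the analyses
    require complete columns), as are monomorphic SNPs.
    """
    geno = read_genotypes(genotype_path)
    clin = read_clinical(clinical_path)
    g_ids, c_ids = set(geno.index), set(clin.index)
    if g_ids != c_ids:
        only_g = sorted(g_ids - c_ids)[:10]
        only_c = sorted(c_ids - g_ids)[:10]
        raise DataError(
            f"sample ids do not match: {len(g_ids - c_ids)} only in genotypes "
            f"(e.g. {only_g}), {len(c_ids - g_ids)} only in clinical "
            f"(e.g. {only_c})")
    clin = clin.loc[geno.index]

    has_missing = geno.isna().any(axis=0)
    excluded_missing = tuple(geno.columns[has_missing])
    kept = geno.loc[:, ~has_missing]
    monomorphic = kept.nunique(axis=0) <= 1
    excluded_mono = tuple(kept.columns[monomorphic])
    kept = kept.loc[:, ~monomorphic]
    logger.info(
        "read %d SNPs: %d excluded (missing genotypes), %d excluded "
        "(monomorphic), %d analyzed",
        geno.shape[1], len(excluded_missing), len(excluded_mono), kept.shape[1])
    if kept.shape[1] == 0:
        raise DataError("no SNPs left after excluding missing/monomorphic ones")
    genotypes = GenotypeMatrix(kept.values.astype(np.int8),
                               tuple(kept.index), tuple(kept.columns))
    survival = SurvivalData(clin["time"].values, clin["status"].values)
    return Dataset(genotypes=genotypes, survival=survival,
                   excluded_missing=excluded_missing,
                   excluded_monomorphic=excluded_mono)


def write_genotypes(genotypes: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(genotypes.values, index=list(genotypes.sample_ids),
                      columns=list(genotypes.snp_ids))
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def write_clinical(survival: SurvivalData, sample_ids, path) -> None:
    # %.17g keeps write -> read an exact identity on the times
    pd.DataFrame({"sample_id": list(sample_ids),
                  "time": survival.times,
                  "status": survival.events}).to_csv(
        path, sep="\t", index=False, float_format="%.17g")


def write_results(table: pd.DataFrame, path) -> None:
    """Per-SNP results TSV with 6-significant-digit numeric formatting."""
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_risk_scores(sample_ids, risk_scores, groups, path) -> None:
    pd.DataFrame({
        "sample_id": list(sample_ids),
        "risk_score": risk_scores,
        "group": np.where(groups, "high", "low"),
    }).to_csv(path, sep="\t", index=False, float_format="%.6g")
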