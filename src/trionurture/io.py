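"""Readers and writers for the pipeline's on-disk formats.

Dosages travel as PLINK ``.raw``-style TSV (FID, IID, then one
``<variant>_<counted allele>`` column per SNP) or as uncompressed VCF;
pedigrees as FAM-like TSV; phenotypes as a CSV of 18 rating-scale items plus
sex, birth year and auxiliary variables; summary statistics as TSV with
columns SNP, A1, A2, BETA, SE, P, FRQ.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .pgs import DosagePanel
from .simtrio import TrioCohort, items_from_phenotype

__all__ = [
    "write_dosages",
    "read_plink_raw",
    "read_vcf",
    "write_pedigree",
    "read_pedigree",
    "write_phenotype",
    "read_phenotype",
    "write_sumstats",
    "write_cohort",
]


def write_dosages(panel: DosagePanel, path) -> None:
    """Write a dosage panel as a PLINK .raw-style TSV."""
    cols = [f"{v}_{a}" for v, a in zip(panel.variant_id, panel.counted_allele)]
    df = pd.DataFrame(panel.matrix, columns=cols)
    df.insert(0, "IID", panel.ids)
    df.insert(0, "FID", panel.ids)
    df.to_csv(path, sep="\t", index=False)


_RAW_COL = re.compile(r"^(?P<vid>.+)_(?P<allele>[ACGT])$")


def read_plink_raw(path) -> DosagePanel:
    """Read a PLINK .raw-style dosage TSV into a DosagePanel."""
    df = pd.read_csv(path, sep="\t")
    meta = [c for c in ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE") if c in df.columns]
    snp_cols = [c for c in df.columns if c not in meta]
    vids, alleles = [], []
    for c in snp_cols:
        m = _RAW_COL.match(c)
        if not m:
            raise ValueError(f"column {c!r} is not of the form <variant>_<allele>")
        vids.append(m["vid"])
        alleles.append(m["allele"])
    ids = df["IID"].to_numpy(dtype=object) if "IID" in df.columns else np.arange(len(df))
    return DosagePanel(
        ids=ids,
        variant_id=np.array(vids, dtype=object),
        counted_allele=np.array(alleles, dtype=object),
        other_allele=np.array([""] * len(vids), dtype=object),
        matrix=df[snp_cols].to_numpy(dtype=np.int8),
    )


def read_vcf(path) -> DosagePanel:
    """Read GT fields from a VCF into a DosagePanel (ALT allele counted)."""
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(str(path))
    ids = np.array(vcf.samples, dtype=object)
    vids, alt, ref, rows = [], [], [], []
    for var in vcf:
        vids.append(var.ID or f"{var.CHROM}:{var.POS}")
        ref.append(var.REF)
        alt.append(var.ALT[0])
        rows.append(np.asarray(var.genotypes)[:, :2].sum(axis=1))
    return DosagePanel(
        ids=ids,
        variant_id=np.array(vids, dtype=object),
        counted_allele=np.array(alt, dtype=object),
        other_allele=np.array(ref, dtype=object),
        matrix=np.array(rows, dtype=np.int8).T,
    )


def write_pedigree(cohort: TrioCohort, path) -> None:
    """FAM-like trio pedigree: family, child, father, mother ids plus child sex."""
    pd.DataFrame(
        {
            "family_id": cohort.trio_id,
            "child_id": [f"{t}_c" for t in cohort.trio_id],
            "father_id": [f"{t}_f" for t in cohort.trio_id],
            "mother_id": [f"{t}_m" for t in cohort.trio_id],
            "sex": cohort.sex,
        }
    ).to_csv(path, sep="\t", index=False)


def read_pedigree(path) -> pd.DataFrame:
    ped = pd.read_csv(path, sep="\t")
    need = {"family_id", "child_id", "father_id", "mother_id"}
    if not need <= set(ped.columns):
        raise ValueError(f"pedigree missing columns: {sorted(need - set(ped.columns))}")
    return ped


def write_phenotype(cohort: TrioCohort, path, items_seed: int = 0) -> pd.DataFrame:
    """Write the child item table: 18 items, sex, birth year, auxiliaries.

    Items are generated from the latent phenotype; families with the outcome
    masked as missing get empty item cells (the attrition the imputation
    stage addresses).
    """
    items = items_from_phenotype(cohort.phenotype, seed=items_seed)
    if cohort.observed_mask is not None:
        items[~cohort.observed_mask, :] = np.nan
    df = pd.DataFrame(items, columns=[f"item{i:02d}" for i in range(1, 19)])
    df.insert(0, "trio_id", cohort.trio_id)
    df["sex"] = cohort.sex
    df["birth_year"] = cohort.birth_year
    if cohort.auxiliaries is not None:
        for k in range(cohort.auxiliaries.shape[1]):
            df[f"aux{k + 1}"] = cohort.auxiliaries[:, k]
    df.to_csv(path, index=False)
    return df


def read_phenotype(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "trio_id" not in df.columns:
        raise ValueError("phenotype file must have a trio_id column")
    return df


def write_sumstats(sumstats: pd.DataFrame, path) -> None:
    sumstats.to_csv(path, sep="\t", index=False)


def write_cohort(
    cohort: TrioCohort,
    outdir,
    sumstats: Optional[pd.DataFrame] = None,
    items_seed: int = 0,
) -> dict:
    """Write a simulated cohort in the standard layout; returns the file map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {}
    for role in ("mother", "father", "child"):
        p = outdir / f"dosages_{role}.tsv"
        write_dosages(DosagePanel.from_cohort(cohort, role), p)
        files[f"dosages_{role}"] = p
    files["pedigree"] = outdir / "pedigree.tsv"
    write_pedigree(cohort, files["pedigree"])
    files["phenotype"] = outdir / "phenotype.csv"
    write_phenotype(cohort, files["phenotype"], items_seed=items_seed)
    if sumstats is not None:
        files["sumstats"] = outdir / "sumstats.tsv"
        write_sumstats(sumstats, files["sumstats"])
    return files
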