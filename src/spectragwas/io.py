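"""Delimited-text readers and writers for phenotypes and genotypes.

Native formats are headered tab-separated tables: a phenotype table with
meta columns followed by one column per wavenumber (header is the cm^-1
value), and a dosage matrix (rows = cows) with a separate SNP map table.
A plain-text VCF can be imported as a convenience.
"""
from __future__ import annotations

import datetime as _dt
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .data import GenotypeData, SpectraDataset, ValidationError, WavenumberGrid
from .simulate import season_of_date

__all__ = [
    "read_phenotypes",
    "write_phenotypes",
    "read_genotypes",
    "write_genotypes",
    "read_genotypes_vcf",
    "apply_genotype_qc",
    "check_cow_overlap",
]

log = logging.getLogger(__name__)

_META_OPTIONAL = ("fat_pct", "protein_pct", "date")
MISSING_DOSAGE = "NA"


def _is_wavenumber(name: str) -> bool:
    try:
        float(name)
        return True
    except ValueError:
        return False


def read_phenotypes(path: str | Path) -> SpectraDataset:
    """Load a phenotype table; invalid rows are rejected with messages.

    Requires columns cow, herd, parity, dim and either season or date (the
    season is derived from the date by the April-September summer rule);
    all float-parseable headers are treated as wavenumber columns.
    """
    df = pd.read_csv(path, sep="\t", dtype={"cow": str, "herd": str})
    required = {"cow", "herd", "parity", "dim"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"phenotype table missing columns: {sorted(missing)}")
    if "season" not in df.columns and "date" not in df.columns:
        raise ValidationError("phenotype table needs a season or date column")
    wn_cols = [c for c in df.columns if _is_wavenumber(c)]
    if not wn_cols:
        raise ValidationError("no wavenumber columns found")
    wn_cols = sorted(wn_cols, key=float)

    rejected: list[str] = []
    keep = np.ones(len(df), dtype=bool)
    dim = pd.to_numeric(df["dim"], errors="coerce")
    bad_dim = dim.isna() | (dim < 1) | (dim > 400)
    for i in df.index[bad_dim]:
        rejected.append(f"row {i}: dim {df['dim'][i]!r} outside [1, 400]")
    keep &= ~bad_dim.to_numpy()

    values = df[wn_cols].apply(pd.to_numeric, errors="coerce").to_numpy()
    bad_val = np.isnan(values).any(axis=1)
    for i in np.nonzero(bad_val)[0]:
        rejected.append(f"row {df.index[i]}: non-numeric transmittance")
    keep &= ~bad_val

    if "season" not in df.columns:
        dates = pd.to_datetime(df["date"], errors="coerce")
        bad_date = dates.isna().to_numpy()
        for i in np.nonzero(bad_date)[0]:
            rejected.append(f"row {df.index[i]}: unparseable date")
        keep &= ~bad_date
        df = df.assign(season=[
            season_of_date(d.date()) if not pd.isna(d) else "winter"
            for d in dates])

    for msg in rejected:
        log.warning("rejected %s", msg)
    meta_cols = ["cow", "herd", "parity", "season", "dim"] + \
        [c for c in _META_OPTIONAL if c in df.columns]
    meta = df.loc[keep, meta_cols].reset_index(drop=True)
    meta["parity"] = meta["parity"].astype(int)
    meta["dim"] = dim[keep].astype(int).to_numpy()
    ds = SpectraDataset(
        meta=meta, values=values[keep],
        grid=WavenumberGrid(np.array([float(c) for c in wn_cols])))
    ds.rejected_rows = rejected
    return ds


def write_phenotypes(dataset: SpectraDataset, path: str | Path) -> None:
    df = dataset.meta.copy()
    for j, wn in enumerate(dataset.grid.values):
        df[repr(float(wn))] = dataset.values[:, j]
    df.to_csv(path, sep="\t", index=False)


def read_genotypes(matrix_path: str | Path, map_path: str | Path,
                   qc: bool = True) -> GenotypeData:
    """Load a dosage matrix plus SNP map and (by default) apply QC:
    drop SNPs with >40% missing calls or MAF < 0.01, autosomes only."""
    mat = pd.read_csv(matrix_path, sep="\t", dtype={"cow": str},
                      na_values=[MISSING_DOSAGE])
    if "cow" not in mat.columns:
        raise ValidationError("dosage matrix needs a 'cow' column")
    snp_map = pd.read_csv(map_path, sep="\t", dtype={"snp": str, "chrom": str})
    missing = {"snp", "chrom", "bp"} - set(snp_map.columns)
    if missing:
        raise ValidationError(f"SNP map missing columns: {sorted(missing)}")
    snp_cols = [c for c in mat.columns if c != "cow"]
    if snp_cols != list(snp_map["snp"]):
        raise ValidationError("dosage columns do not match the SNP map")
    geno = _assemble(mat["cow"].to_numpy(), snp_map,
                     mat[snp_cols].to_numpy(dtype=float))
    return apply_genotype_qc(geno)[0] if qc else geno


def write_genotypes(geno: GenotypeData, matrix_path: str | Path,
                    map_path: str | Path) -> None:
    mat = pd.DataFrame(geno.dosages, columns=geno.snp_map["snp"])
    mat.insert(0, "cow", geno.cow_ids)
    mat.to_csv(matrix_path, sep="\t", index=False, na_rep=MISSING_DOSAGE)
    geno.snp_map.to_csv(map_path, sep="\t", index=False)


def read_genotypes_vcf(path: str | Path, qc: bool = True) -> GenotypeData:
    """Import GT fields of a VCF as ALT-allele dosages."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    cows = np.array(vcf.samples)
    rows, chroms, bps, ids = [], [], [], []
    for i, variant in enumerate(vcf):
        gts = np.asarray(variant.gt_types, dtype=float)  # 0,1,3 = dosage; 2 = unknown
        dos = np.where(gts == 3, 2.0, gts)
        dos[gts == 2] = np.nan
        rows.append(dos)
        chroms.append(variant.CHROM)
        bps.append(variant.POS)
        ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
    snp_map = pd.DataFrame({"snp": ids, "chrom": chroms, "bp": bps})
    geno = _assemble(cows, snp_map, np.column_stack(rows) if rows
                     else np.empty((len(cows), 0)))
    return apply_genotype_qc(geno)[0] if qc else geno


def _numeric_chrom(chrom: pd.Series) -> pd.Series:
    return pd.to_numeric(
        chrom.astype(str).str.replace("^(chr|Chr|BTA)", "", regex=True),
        errors="coerce")


def _assemble(cows: np.ndarray, snp_map: pd.DataFrame,
              dosages: np.ndarray) -> GenotypeData:
    """Sort by (chrom, bp) and build the container; chromosome labels are
    normalised to integers where possible (non-numeric = sex/MT, kept as -1
    until QC)."""
    chrom_num = _numeric_chrom(snp_map["chrom"])
    labels = snp_map["chrom"].astype(str)
    negatives = {lab: -(i + 1) for i, lab in
                 enumerate(pd.unique(labels[chrom_num.isna()]))}
    chrom_int = np.where(chrom_num.isna(), labels.map(negatives),
                         chrom_num).astype(int)
    snp_map = snp_map.assign(chrom=chrom_int)
    order = np.lexsort((snp_map["bp"].to_numpy(), snp_map["chrom"].to_numpy()))
    return GenotypeData(
        cow_ids=cows,
        snp_map=snp_map.iloc[order].reset_index(drop=True),
        dosages=dosages[:, order])


def check_cow_overlap(dataset: SpectraDataset, geno: GenotypeData) -> None:
    """Raise if phenotyped cows are missing from the genotype matrix."""
    pheno_cows = set(dataset.meta["cow"])
    missing = sorted(pheno_cows - set(map(str, geno.cow_ids)))
    if missing:
        shown = ", ".join(missing[:10])
        more = f" (+{len(missing) - 10} more)" if len(missing) > 10 else ""
        raise ValidationError(
            f"{len(missing)} phenotyped cows lack genotypes: {shown}{more}")


def apply_genotype_qc(geno: GenotypeData, max_missing: float = 0.40,
                      min_maf: float = 0.01, autosomes_only: bool = True,
                      ) -> tuple[GenotypeData, dict[str, int]]:
    """Drop SNPs with too many missing calls, low MAF, or off autosomes."""
    miss = geno.missing_rate()
    maf = geno.maf()
    keep = (miss <= max_missing) & (maf >= min_maf)
    counts = {
        "missing": int((miss > max_missing).sum()),
        "maf": int(((miss <= max_missing) & (maf < min_maf)).sum()),
    }
    if autosomes_only:
        auto = geno.snp_map["chrom"].to_numpy() >= 1
        counts["non_autosomal"] = int((keep & ~auto).sum())
        keep &= auto
    log.info("genotype QC dropped %d SNPs (%s)", int((~keep).sum()), counts)
    return geno.subset_snps(keep), counts
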