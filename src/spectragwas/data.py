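"""Core data containers shared across pipeline stages."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: columns every phenotype record table must carry
META_COLUMNS = ("cow", "herd", "parity", "season", "dim")

SEASONS = ("summer", "winter")


class ValidationError(ValueError):
    """Raised when a container violates one of its invariants."""


@dataclass(frozen=True)
class WavenumberGrid:
    """Strictly monotone grid of wavenumbers in cm^-1."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 1:
            raise ValidationError("grid must be a non-empty 1-D array")
        diffs = np.diff(values)
        if not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise ValidationError("grid must be strictly monotone")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return len(self.values)

    @classmethod
    def uniform(cls, start: float, stop: float, n: int) -> "WavenumberGrid":
        return cls(np.linspace(start, stop, n))


@dataclass
class SpectraDataset:
    """Repeated milk records with per-wavenumber transmittance.

    ``meta`` holds one row per record (cow, herd, parity, season, dim and
    optionally ``fat_pct``/``protein_pct``); ``values`` is the aligned
    records x wavenumbers transmittance matrix.
    """

    meta: pd.DataFrame
    values: np.ndarray
    grid: WavenumberGrid
    rejected_rows: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise ValidationError(f"meta missing columns: {missing}")
        if self.values.shape != (len(self.meta), len(self.grid)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.meta)} records x {len(self.grid)} wavenumbers"
            )
        dim = self.meta["dim"].to_numpy()
        if np.any((dim < 1) | (dim > 400)):
            raise ValidationError("dim outside [1, 400]")
        bad = set(self.meta["season"]) - set(SEASONS)
        if bad:
            raise ValidationError(f"unknown season levels: {sorted(bad)}")

    @property
    def n_records(self) -> int:
        return len(self.meta)

    def subset_records(self, mask: np.ndarray) -> "SpectraDataset":
        return SpectraDataset(
            meta=self.meta.loc[mask].reset_index(drop=True),
            values=self.values[np.asarray(mask)],
            grid=self.grid,
        )


@dataclass
class GenotypeData:
    """Dosage matrix (cows x SNPs, 0/1/2 with NaN for missing) plus map."""

    cow_ids: np.ndarray
    snp_map: pd.DataFrame  # columns: snp, chrom, bp — sorted by (chrom, bp)
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.cow_ids = np.asarray(self.cow_ids)
        self.dosages = np.asarray(self.dosages, dtype=float)
        for col in ("snp", "chrom", "bp"):
            if col not in self.snp_map.columns:
                raise ValidationError(f"snp_map missing column {col!r}")
        if self.dosages.shape != (len(self.cow_ids), len(self.snp_map)):
            raise ValidationError("dosage matrix shape mismatch")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValidationError("dosages must be 0/1/2 or missing")
        srt = self.snp_map.sort_values(["chrom", "bp"], kind="stable")
        if not np.array_equal(srt.index.to_numpy(), np.arange(len(self.snp_map))):
            raise ValidationError("snp_map must be sorted by (chrom, bp)")
        by_chrom = self.snp_map.groupby("chrom")["bp"]
        if (by_chrom.apply(lambda s: (np.diff(s.to_numpy()) <= 0).any())).any():
            raise ValidationError("bp must be strictly increasing within chromosome")

    @property
    def n_cows(self) -> int:
        return len(self.cow_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_map)

    def allele_frequency(self) -> np.ndarray:
        """Per-SNP ALT allele frequency over non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_frequency()
        return np.minimum(p, 1.0 - p)

    def missing_rate(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    def centred_dosages(self) -> np.ndarray:
        """Mean-imputed, column-centred dosage matrix (dense)."""
        g = self.dosages.copy()
        col_mean = np.nanmean(g, axis=0)
        nan_r, nan_c = np.nonzero(np.isnan(g))
        g[nan_r, nan_c] = col_mean[nan_c]
        return g - g.mean(axis=0)

    def subset_snps(self, mask: np.ndarray) -> "GenotypeData":
        mask = np.asarray(mask)
        return GenotypeData(
            cow_ids=self.cow_ids,
            snp_map=self.snp_map.loc[mask].reset_index(drop=True),
            dosages=self.dosages[:, mask],
        )
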