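"""Synthetic genotypes and repeated-record spectra with known ground truth.

The generator plants QTL of configurable additive-variance fractions on a
linkage-equilibrium background, draws herd/permanent-environment/residual
components at configured variances, and builds block-correlated wavenumber
phenotypes so every downstream stage can be validated against truth.
"""
from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import GenotypeData, SpectraDataset, WavenumberGrid

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "SimulationConfigError",
    "simulate_genotypes",
    "simulate_spectra",
    "season_of_date",
]

#: sampling window for record dates (one milk-recording year)
DATE_START = _dt.date(2015, 10, 1)
DATE_STOP = _dt.date(2016, 9, 30)


class SimulationConfigError(ValueError):
    """Invalid simulation configuration."""


def season_of_date(date: _dt.date) -> str:
    """Season label for a record date: summer is April through September."""
    return "summer" if 4 <= date.month <= 9 else "winter"


@dataclass
class SimulationConfig:
    n_cows: int = 300
    n_herds: int = 10
    records_per_cow_range: tuple[int, int] = (1, 20)
    n_chromosomes: int = 3
    snps_per_chromosome: int = 200
    maf_range: tuple[float, float] = (0.05, 0.5)
    #: (chromosome 1-based, snp index 0-based within chromosome, variance fraction)
    planted_qtl: list[tuple[int, int, float]] = field(default_factory=list)
    #: (sigma2_A, sigma2_herd, sigma2_PE, sigma2_E)
    variance_components: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    #: (mean, parity-2 contrast, winter contrast, wilmink beta1, wilmink beta2)
    fixed_effects: tuple[float, float, float, float, float] = (
        50.0, 0.5, -0.3, 1.0, -2.0)
    #: (block start cm^-1, block end cm^-1, within-block residual correlation)
    wavenumber_blocks: list[tuple[float, float, float]] = field(default_factory=list)
    grid_start: float = 925.0
    grid_stop: float = 5008.0
    grid_points: int = 20
    missing_rate: float = 0.0
    parity2_fraction: float = 0.09
    seed: int = 0

    def validate(self) -> None:
        if self.n_cows < 2 or self.snps_per_chromosome < 2:
            raise SimulationConfigError("need at least 2 cows and 2 SNPs/chromosome")
        if self.n_herds < 1 or self.n_chromosomes < 1:
            raise SimulationConfigError("n_herds and n_chromosomes must be >= 1")
        lo, hi = self.records_per_cow_range
        if not (1 <= lo <= hi <= 20):
            raise SimulationConfigError("records_per_cow_range must lie in [1, 20]")
        mlo, mhi = self.maf_range
        if not (0.0 < mlo <= mhi <= 0.5):
            raise SimulationConfigError("maf_range must lie in (0, 0.5]")
        if any(v < 0 for v in self.variance_components):
            raise SimulationConfigError("variance components must be >= 0")
        fracs = [f for (_, _, f) in self.planted_qtl]
        if any(not 0.0 < f <= 1.0 for f in fracs):
            raise SimulationConfigError("planted fractions must be in (0, 1]")
        if sum(fracs) > 1.0 + 1e-12:
            raise SimulationConfigError("planted fractions sum above 1")
        for chrom, idx, _ in self.planted_qtl:
            if not (1 <= chrom <= self.n_chromosomes):
                raise SimulationConfigError(f"planted QTL on unknown chromosome {chrom}")
            if not (0 <= idx < self.snps_per_chromosome):
                raise SimulationConfigError(f"planted QTL index {idx} out of range")
        if not (0.0 <= self.missing_rate < 1.0):
            raise SimulationConfigError("missing_rate must be in [0, 1)")

    def heritability(self) -> float:
        a, h, pe, e = self.variance_components
        tot = a + h + pe + e
        return a / tot if tot > 0 else 0.0


@dataclass
class TruthRecord:
    """Ground truth exposed by the generator for downstream validation."""

    #: per-block true SNP effects, shape (n_blocks, n_snps)
    snp_effects: np.ndarray
    variance_components: tuple[float, float, float, float]
    #: per-wavenumber true heritability
    h2: np.ndarray
    #: planted intervals: (chromosome, bp_start, bp_end)
    qtl_intervals: list[tuple[int, int, int]]
    #: block id of each grid wavenumber
    block_of: np.ndarray
    #: realised per-block components: genetic (blocks x cows), herd effects,
    #: permanent environment (blocks x cows), residual (blocks x records)
    genetic_values: np.ndarray
    herd_effects: np.ndarray
    pe_values: np.ndarray
    residuals: np.ndarray


def simulate_genotypes(config: SimulationConfig) -> GenotypeData:
    """Draw Hardy-Weinberg dosages and a sorted multi-chromosome SNP map.

    Allele frequencies are drawn uniformly from ``maf_range`` per SNP; SNPs
    whose realised MAF falls below 0.01 are resampled so the matrix passes
    the pipeline's own MAF filter.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    p = config.n_chromosomes * config.snps_per_chromosome
    freqs = rng.uniform(*config.maf_range, size=p)
    dosages = rng.binomial(2, freqs, size=(config.n_cows, p)).astype(float)

    for _ in range(1000):
        af = dosages.mean(axis=0) / 2.0
        bad = np.minimum(af, 1 - af) < 0.01
        if not bad.any():
            break
        dosages[:, bad] = rng.binomial(2, freqs[bad], size=(config.n_cows, bad.sum()))
    else:  # pragma: no cover - pathological maf_range
        raise SimulationConfigError("could not realise MAF >= 0.01 for all SNPs")

    chroms = np.repeat(np.arange(1, config.n_chromosomes + 1),
                       config.snps_per_chromosome)
    gaps = rng.integers(1_000, 100_000,
                        size=(config.n_chromosomes, config.snps_per_chromosome))
    bp = np.cumsum(gaps, axis=1).ravel()
    snp_map = pd.DataFrame({
        "snp": [f"snp{c}_{i}" for c, i in
                zip(chroms, np.tile(np.arange(config.snps_per_chromosome),
                                    config.n_chromosomes))],
        "chrom": chroms,
        "bp": bp,
    })

    if config.missing_rate > 0:
        mask = rng.random(dosages.shape) < config.missing_rate
        dosages[mask] = np.nan

    cow_ids = np.array([f"cow{i:05d}" for i in range(config.n_cows)])
    geno = GenotypeData(cow_ids=cow_ids, snp_map=snp_map, dosages=dosages)
    geno.drawn_freqs = freqs  # exposed for sampling-error oracles
    return geno


def _block_assignment(grid: WavenumberGrid,
                      blocks: list[tuple[float, float, float]]) -> np.ndarray:
    """Map each grid point to a block id; unassigned points become singletons."""
    block_of = np.full(len(grid), -1, dtype=int)
    for b, (lo, hi, _rho) in enumerate(blocks):
        inside = (grid.values >= lo) & (grid.values <= hi)
        if (block_of[inside] != -1).any():
            raise SimulationConfigError("wavenumber blocks overlap")
        block_of[inside] = b
    nxt = len(blocks)
    for i in np.nonzero(block_of == -1)[0]:
        block_of[i] = nxt
        nxt += 1
    return block_of


def _snp_effects_for_block(rng: np.random.Generator, config: SimulationConfig,
                           var_g: np.ndarray, planted_cols: np.ndarray,
                           fractions: np.ndarray) -> np.ndarray:
    """Effects sized so planted SNPs carry their variance fractions and the
    i.i.d. background carries the rest of sigma2_A (in realised dosage variance)."""
    sigma2_a = config.variance_components[0]
    p = var_g.size
    effects = np.zeros(p)
    if sigma2_a == 0:
        return effects
    signs = rng.choice([-1.0, 1.0], size=planted_cols.size)
    effects[planted_cols] = signs * np.sqrt(
        fractions * sigma2_a / np.maximum(var_g[planted_cols], 1e-12))
    remaining = sigma2_a * (1.0 - fractions.sum())
    background = np.setdiff1d(np.arange(p), planted_cols)
    if remaining > 0 and background.size:
        raw = rng.standard_normal(background.size)
        scale = np.sqrt(remaining / np.sum(var_g[background] * raw ** 2))
        effects[background] = raw * scale
    return effects


def simulate_spectra(config: SimulationConfig,
                     genotypes: GenotypeData) -> tuple[SpectraDataset, TruthRecord]:
    """Build repeated records per the repeatability model with planted QTL.

    Each wavenumber block gets its own SNP-effect vector, herd effects,
    permanent-environment effects and residual stream; wavenumbers within a
    block share those signals plus a block-correlated residual, so the
    within-block phenotype correlation exceeds the configured value.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    sigma2_a, sigma2_h, sigma2_pe, sigma2_e = config.variance_components
    mean, parity2, winter, beta1, beta2 = config.fixed_effects

    n_cows = genotypes.n_cows
    herd = rng.integers(0, config.n_herds, size=n_cows)
    parity = 1 + (rng.random(n_cows) < config.parity2_fraction).astype(int)
    lo, hi = config.records_per_cow_range
    n_rec = rng.integers(lo, hi + 1, size=n_cows)
    n_records = int(n_rec.sum())
    cow_idx = np.repeat(np.arange(n_cows), n_rec)

    day_span = (DATE_STOP - DATE_START).days
    dates = [DATE_START + _dt.timedelta(days=int(d))
             for d in rng.integers(0, day_span + 1, size=n_records)]
    season = np.array([season_of_date(d) for d in dates])
    dim = rng.integers(1, 401, size=n_records)

    grid = WavenumberGrid.uniform(config.grid_start, config.grid_stop,
                                  config.grid_points)
    block_of = _block_assignment(grid, config.wavenumber_blocks)
    n_blocks = int(block_of.max()) + 1
    rho_of = np.zeros(n_blocks)
    for b, (_, _, rho) in enumerate(config.wavenumber_blocks):
        rho_of[b] = rho

    gc = genotypes.centred_dosages()
    var_g = gc.var(axis=0)
    planted_cols, fractions = [], []
    qtl_intervals = []
    for chrom, idx, frac in config.planted_qtl:
        col = (chrom - 1) * config.snps_per_chromosome + idx
        planted_cols.append(col)
        fractions.append(frac)
        bp = int(genotypes.snp_map["bp"].iloc[col])
        qtl_intervals.append((chrom, bp, bp))
    planted_cols = np.asarray(planted_cols, dtype=int)
    fractions = np.asarray(fractions, dtype=float)

    snp_effects = np.empty((n_blocks, genotypes.n_snps))
    genetic = np.empty((n_blocks, n_cows))
    herd_eff = rng.normal(0, np.sqrt(sigma2_h), size=(n_blocks, config.n_herds))
    pe = rng.normal(0, np.sqrt(sigma2_pe), size=(n_blocks, n_cows))
    resid = np.empty((n_blocks, n_records))

    dim_scaled = dim / 365.0
    fixed = (mean + parity2 * (parity[cow_idx] == 2) + winter * (season == "winter")
             + beta1 * dim_scaled + beta2 * np.exp(-0.05 * dim_scaled))

    values = np.empty((n_records, len(grid)))
    shared = rng.standard_normal((n_blocks, n_records))
    for b in range(n_blocks):
        snp_effects[b] = _snp_effects_for_block(rng, config, var_g,
                                                planted_cols, fractions)
        genetic[b] = gc @ snp_effects[b]
        resid[b] = np.sqrt(sigma2_e) * shared[b]
    for w in range(len(grid)):
        b = block_of[w]
        rho = rho_of[b]
        own = rng.standard_normal(n_records)
        e_w = np.sqrt(sigma2_e) * (np.sqrt(rho) * shared[b]
                                   + np.sqrt(1 - rho) * own)
        values[:, w] = (fixed + herd_eff[b, herd[cow_idx]]
                        + genetic[b, cow_idx] + pe[b, cow_idx] + e_w)

    meta = pd.DataFrame({
        "cow": genotypes.cow_ids[cow_idx],
        "herd": np.char.add("herd", herd[cow_idx].astype(str)),
        "parity": parity[cow_idx],
        "season": season,
        "dim": dim,
        "date": [d.isoformat() for d in dates],
    })
    dataset = SpectraDataset(meta=meta, values=values, grid=grid)
    truth = TruthRecord(
        snp_effects=snp_effects,
        variance_components=config.variance_components,
        h2=np.full(len(grid), config.heritability()),
        qtl_intervals=qtl_intervals,
        block_of=block_of,
        genetic_values=genetic,
        herd_effects=herd_eff,
        pe_values=pe,
        residuals=resid,
    )
    return dataset, truth
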