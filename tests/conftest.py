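import numpy as np
import pandas as pd
import pytest

from spectragwas.data import GenotypeData, SpectraDataset, WavenumberGrid
from spectragwas.simulate import (SimulationConfig, simulate_genotypes,
                                  simulate_spectra)


def make_dataset(n_records=40, n_wn=6, seed=0, **meta_overrides):
    """Small hand-rolled dataset with arbitrary transmittances."""
    rng = np.random.default_rng(seed)
    meta = pd.DataFrame({
        "cow": [f"c{i % 10}" for i in range(n_records)],
        "herd": [f"h{i % 3}" for i in range(n_records)],
        "parity": rng.choice([1, 2], size=n_records),
        "season": rng.choice(["summer", "winter"], size=n_records),
        "dim": rng.integers(1, 401, size=n_records),
    })
    for k, v in meta_overrides.items():
        meta[k] = v
    values = rng.normal(50, 3, size=(n_records, n_wn))
    grid = WavenumberGrid(np.linspace(1000, 2000, n_wn))
    return SpectraDataset(meta=meta, values=values, grid=grid)


def make_genotypes(n_cows=10, n_snps=8, seed=0, chrom=None):
    rng = np.random.default_rng(seed)
    dosages = rng.binomial(2, 0.4, size=(n_cows, n_snps)).astype(float)
    if chrom is None:
        chrom = np.ones(n_snps, dtype=int)
    snp_map = pd.DataFrame({
        "snp": [f"s{i}" for i in range(n_snps)],
        "chrom": chrom,
        "bp": np.arange(1, n_snps + 1) * 1000,
    })
    return GenotypeData(
        cow_ids=np.array([f"c{i}" for i in range(n_cows)]),
        snp_map=snp_map, dosages=dosages)


@pytest.fixture(scope="session")
def small_sim():
    """One shared small simulation for cheap structural tests."""
    cfg = SimulationConfig(
        n_cows=60, n_herds=4, records_per_cow_range=(1, 3),
        n_chromosomes=2, snps_per_chromosome=50,
        wavenumber_blocks=[(1000.0, 1400.0, 0.97)],
        grid_points=8, grid_start=925.0, grid_stop=3000.0, seed=42)
    geno = simulate_genotypes(cfg)
    dataset, truth = simulate_spectra(cfg, geno)
    return cfg, geno, dataset, truth
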