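"""Wavenumber reduction: water-region exclusion, record QC,
covariate-corrected correlations, block detection and representative pick."""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import SpectraDataset, ValidationError, WavenumberGrid

__all__ = [
    "CorrelationBlock",
    "SelectedWavenumber",
    "filter_water_regions",
    "apply_record_qc",
    "residualized_correlation",
    "detect_blocks",
    "select_representative",
]

log = logging.getLogger(__name__)

#: wavenumbers strictly above this interact with water (upper region)
WATER_UPPER_BOUND = 3008.0
#: closed interval of the second water-interacting region
WATER_MID_REGION = (1623.0, 1669.0)


@dataclass(frozen=True)
class CorrelationBlock:
    """Contiguous run of retained wavenumbers, all pairwise correlated
    above the block threshold. Indices refer to the retained grid."""

    block_id: int
    start: int
    end: int  # inclusive
    wavenumbers: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValidationError("block end before start")
        if len(self.wavenumbers) != self.end - self.start + 1:
            raise ValidationError("member count does not match index span")

    @property
    def indices(self) -> np.ndarray:
        return np.arange(self.start, self.end + 1)


@dataclass
class SelectedWavenumber:
    block_id: int
    index: int  # index on the retained grid
    wavenumber: float
    correlation_sum: float
    tied: bool = False
    heritability: float | None = None


def filter_water_regions(grid: WavenumberGrid | np.ndarray) -> np.ndarray:
    """Indices of grid points outside the two water-interacting regions.

    Drops wavenumbers strictly above 3008 cm^-1 and wavenumbers inside the
    closed interval [1623, 1669] cm^-1; order is preserved. An empty array
    yields an empty result.
    """
    wn = grid.values if isinstance(grid, WavenumberGrid) else np.asarray(grid)
    keep = (wn <= WATER_UPPER_BOUND) & ~(
        (wn >= WATER_MID_REGION[0]) & (wn <= WATER_MID_REGION[1]))
    return np.nonzero(keep)[0]


#: per-population QC rule names understood by apply_record_qc
_QC_FIELDS = {
    "fat_max": ("fat_pct", lambda v, t: v > t),
    "protein_min": ("protein_pct", lambda v, t: v < t),
    "protein_max": ("protein_pct", lambda v, t: v > t),
}

HOLSTEIN_QC = {"fat_max": 8.0, "protein_min": 2.5, "protein_max": 5.0}
JERSEY_QC = {"protein_max": 5.5}


def apply_record_qc(dataset: SpectraDataset,
                    rules: dict[str, float]) -> tuple[SpectraDataset, pd.DataFrame]:
    """Drop records violating any configured composition bound.

    Returns the filtered dataset and a removal log (record index, rule,
    offending value).
    """
    removed = []
    drop = np.zeros(dataset.n_records, dtype=bool)
    for rule, threshold in rules.items():
        if rule not in _QC_FIELDS:
            raise KeyError(f"unknown QC rule {rule!r}")
        column, violates = _QC_FIELDS[rule]
        if column not in dataset.meta.columns:
            raise KeyError(f"QC rule {rule!r} needs missing column {column!r}")
        vals = dataset.meta[column].to_numpy(dtype=float)
        bad = violates(vals, threshold) & ~np.isnan(vals)
        for i in np.nonzero(bad)[0]:
            removed.append({"record": int(i), "rule": rule, "value": vals[i]})
        drop |= bad
    filtered = dataset.subset_records(~drop)
    log.info("record QC removed %d of %d records", int(drop.sum()),
             dataset.n_records)
    return filtered, pd.DataFrame(removed, columns=["record", "rule", "value"])


def _correction_design(meta: pd.DataFrame) -> np.ndarray:
    """Fixed-effect design for residualisation: intercept, parity and season
    contrasts, herd contrasts, and the two lactation-stage terms."""
    n = len(meta)
    cols = [np.ones(n)]
    for name in ("parity", "season", "herd"):
        levels = pd.unique(meta[name])
        for lvl in levels[1:]:
            cols.append((meta[name] == lvl).to_numpy(dtype=float))
    dim_scaled = meta["dim"].to_numpy(dtype=float) / 365.0
    cols.append(dim_scaled)
    cols.append(np.exp(-0.05 * dim_scaled))
    return np.column_stack(cols)


def residualized_correlation(dataset: SpectraDataset,
                             retained: np.ndarray) -> np.ndarray:
    """Pearson correlation of transmittances after removing season, parity,
    lactation-stage and herd effects by least squares."""
    retained = np.asarray(retained)
    if dataset.n_records < 3:
        raise ValidationError("need at least 3 records")
    if retained.size < 2:
        raise ValidationError("need at least 2 retained wavenumbers")
    for name in ("parity", "season", "herd"):
        counts = dataset.meta[name].value_counts()
        if (counts < 1).any():  # defensive; value_counts never reports zeros
            raise ValidationError(f"covariate {name} has an empty level")
    x = _correction_design(dataset.meta)
    if dataset.n_records <= x.shape[1]:
        raise ValidationError("not enough records to fit the correction model")
    y = dataset.values[:, retained]
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    corr = np.corrcoef(resid, rowvar=False)
    np.fill_diagonal(corr, 1.0)
    return corr


def detect_blocks(corr: np.ndarray, threshold: float = 0.95,
                  wavenumbers: np.ndarray | None = None) -> list[CorrelationBlock]:
    """Greedy left-to-right partition into contiguous blocks in which every
    pairwise correlation exceeds ``threshold``; singletons allowed.

    Deterministic stand-in for the visual heatmap inspection step.
    """
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValidationError("correlation matrix must be square")
    if not np.allclose(corr, corr.T, atol=1e-8):
        raise ValidationError("correlation matrix must be symmetric")
    n = corr.shape[0]
    if wavenumbers is None:
        wavenumbers = np.arange(n, dtype=float)
    blocks: list[CorrelationBlock] = []
    start = 0
    for j in range(1, n):
        if np.all(corr[j, start:j] > threshold):
            continue
        blocks.append(CorrelationBlock(
            block_id=len(blocks) + 1, start=start, end=j - 1,
            wavenumbers=tuple(wavenumbers[start:j])))
        start = j
    blocks.append(CorrelationBlock(
        block_id=len(blocks) + 1, start=start, end=n - 1,
        wavenumbers=tuple(wavenumbers[start:n])))
    return blocks


def select_representative(block: CorrelationBlock,
                          corr: np.ndarray) -> SelectedWavenumber:
    """Member with the highest within-block correlation sum (diagonal
    included); ties break toward the lower index."""
    idx = block.indices
    sums = corr[np.ix_(idx, idx)].sum(axis=1)
    best = int(np.argmax(sums))  # argmax returns the first (lowest) on ties
    tied = bool(np.sum(np.isclose(sums, sums[best], rtol=0, atol=1e-12)) > 1)
    if tied:
        log.info("correlation-sum tie in block %d; keeping lower index",
                 block.block_id)
    return SelectedWavenumber(
        block_id=block.block_id,
        index=int(idx[best]),
        wavenumber=float(block.wavenumbers[best]),
        correlation_sum=float(sums[best]),
        tied=tied,
    )
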