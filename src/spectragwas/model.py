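"""Hierarchical repeatability model fitted by MCMC.

For one selected wavenumber the transmittance of record r of cow l is

    y_r = x_r' b + Herd_k(r) + CowA_l(r) + CowPE_l(r) + e_r
    CowA_l = sum_m g_lm a_m            (centred dosages)

with flat priors on the fixed effects b and on all variance components
(uniform on (0, bound]), and normal priors Herd ~ N(0, s2_H),
CowPE ~ N(0, s2_PE), a_m ~ N(0, s2_a). All full conditionals are standard,
so the chain is run as a Gibbs sampler (the zero-rejection special case of
Metropolis-Hastings).
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .data import GenotypeData, SpectraDataset, ValidationError

__all__ = [
    "ModelDesign",
    "McmcConfig",
    "PosteriorSamples",
    "HeritabilityEstimate",
    "build_design",
    "fit_mcmc",
    "heritability",
    "gate_heritable",
]

log = logging.getLogger(__name__)

FIXED_NAMES = ("intercept", "parity2", "winter", "dim", "wilmink")


@dataclass
class ModelDesign:
    """Assembled inputs for one wavenumber's model fit."""

    y: np.ndarray                 # (n_records,)
    x: np.ndarray                 # (n_records, k) fixed-effect design
    fixed_names: tuple[str, ...]
    herd_idx: np.ndarray | None   # (n_records,) or None to drop the herd term
    cow_idx: np.ndarray           # (n_records,) into rows of g
    g: np.ndarray                 # (n_cows, n_snps) centred dosages
    include_pe: bool = True
    n_dropped_cows: int = 0

    def __post_init__(self) -> None:
        n = self.y.shape[0]
        if self.x.shape[0] != n or self.cow_idx.shape[0] != n:
            raise ValidationError("design row counts disagree")
        if self.herd_idx is not None and self.herd_idx.shape[0] != n:
            raise ValidationError("herd index length mismatch")
        if self.cow_idx.min() < 0 or self.cow_idx.max() >= self.g.shape[0]:
            raise ValidationError("cow index out of bounds")
        col_means = np.abs(self.g.mean(axis=0))
        if self.g.size and col_means.max() > 1e-8:
            raise ValidationError("dosage columns must be mean-centred")

    @property
    def n_records(self) -> int:
        return self.y.shape[0]

    @property
    def n_cows(self) -> int:
        return self.g.shape[0]

    @property
    def n_snps(self) -> int:
        return self.g.shape[1]


@dataclass
class McmcConfig:
    """Chain settings. Defaults are a desk-scale tenth of the full-length
    70,000/30,000 run; set those explicitly for a full fit."""

    n_iterations: int = 7_000
    n_burn_in: int = 3_000
    thinning: int = 10
    seed: int = 0
    variance_bound_factor: float = 1e6
    #: optionally fix any of "herd", "pe", "snp", "residual" variances
    fixed_variances: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if not 0 <= self.n_burn_in < self.n_iterations:
            raise ValidationError("burn-in must be < iterations")
        if self.thinning < 1:
            raise ValidationError("thinning must be >= 1")

    @property
    def n_saved(self) -> int:
        return (self.n_iterations - self.n_burn_in) // self.thinning


@dataclass
class PosteriorSamples:
    fixed: np.ndarray          # (S, k)
    fixed_names: tuple[str, ...]
    herd: np.ndarray | None    # (S, n_herds)
    pe: np.ndarray | None      # (S, n_cows)
    snp: np.ndarray            # (S, n_snps)
    cow_a: np.ndarray          # (S, n_cows) per-draw genomic values
    var_herd: np.ndarray       # (S,)
    var_pe: np.ndarray
    var_snp: np.ndarray        # per-SNP effect variance
    var_e: np.ndarray
    var_a: np.ndarray          # across-cow variance of cow_a per draw
    bound_warning: bool = False

    @property
    def n_saved(self) -> int:
        return self.snp.shape[0]


@dataclass
class HeritabilityEstimate:
    wavenumber: float
    mean: float
    sd: float
    passed: bool
    n_skipped_draws: int = 0


def build_design(dataset: SpectraDataset, genotypes: GenotypeData,
                 wavenumber: float,
                 conventional_wilmink: bool = False) -> ModelDesign:
    """Assemble response and covariates for one retained wavenumber.

    The lactation-stage terms are DIM = dim/365 and exp(-0.05*DIM) as used
    in the source model; ``conventional_wilmink`` switches the exponential
    term to exp(-0.05*dim) on the raw day scale.
    """
    matches = np.isclose(dataset.grid.values, wavenumber)
    if not matches.any():
        raise ValidationError(f"wavenumber {wavenumber} not on the grid")
    col = int(np.nonzero(matches)[0][0])

    geno_pos = {c: i for i, c in enumerate(genotypes.cow_ids)}
    has_geno = dataset.meta["cow"].map(geno_pos).notna().to_numpy()
    n_dropped = int(dataset.meta.loc[~has_geno, "cow"].nunique())
    if n_dropped:
        log.info("dropping %d cows without genotypes", n_dropped)
    meta = dataset.meta.loc[has_geno].reset_index(drop=True)
    y = dataset.values[has_geno, col]

    cows, cow_idx = np.unique(meta["cow"].to_numpy(), return_inverse=True)
    g_rows = np.array([geno_pos[c] for c in cows], dtype=int)
    g_full = genotypes.centred_dosages()[g_rows]
    g = g_full - g_full.mean(axis=0)  # re-centre on the modelled cows

    n = len(meta)
    cols = [np.ones(n)]
    names = ["intercept"]
    if meta["parity"].nunique() > 1:
        cols.append((meta["parity"] == 2).to_numpy(dtype=float))
        names.append("parity2")
    else:
        warnings.warn("single parity level; parity term dropped", stacklevel=2)
    if meta["season"].nunique() > 1:
        cols.append((meta["season"] == "winter").to_numpy(dtype=float))
        names.append("winter")
    else:
        warnings.warn("single season level; season term dropped", stacklevel=2)
    dim_scaled = meta["dim"].to_numpy(dtype=float) / 365.0
    cols.append(dim_scaled)
    names.append("dim")
    if conventional_wilmink:
        cols.append(np.exp(-0.05 * meta["dim"].to_numpy(dtype=float)))
    else:
        cols.append(np.exp(-0.05 * dim_scaled))
    names.append("wilmink")

    _, herd_idx = np.unique(meta["herd"].to_numpy(), return_inverse=True)
    return ModelDesign(
        y=y, x=np.column_stack(cols), fixed_names=tuple(names),
        herd_idx=herd_idx.astype(np.int64), cow_idx=cow_idx.astype(np.int64),
        g=g, n_dropped_cows=n_dropped)


@njit(cache=False)
def _sweep_snps(gt, a, ebar, n_rec, wg2, s2_snp, s2_e, z):
    """One single-site Gibbs pass over SNP effects.

    ``ebar`` holds per-cow sums of record residuals excluding the genomic
    term's contribution being updated; updating a_m shifts every record of
    each cow, hence the n_rec weighting.
    """
    p, n_cows = gt.shape
    for m in range(p):
        rhs = 0.0
        for l in range(n_cows):
            rhs += gt[m, l] * ebar[l]
        rhs = (rhs + wg2[m] * a[m]) / s2_e
        prec = wg2[m] / s2_e + 1.0 / s2_snp
        a_new = rhs / prec + z[m] / np.sqrt(prec)
        d = a_new - a[m]
        if d != 0.0:
            for l in range(n_cows):
                ebar[l] -= n_rec[l] * gt[m, l] * d
        a[m] = a_new


def _draw_variance(rng: np.random.Generator, ssq: float, q: int,
                   bound: float) -> tuple[float, bool]:
    """Sample a variance from its flat-prior conditional, a scaled inverse
    chi-square with q-2 degrees of freedom, truncated at ``bound``."""
    df = q - 2 if q > 2 else q
    hit = False
    for _ in range(100):
        draw = ssq / rng.chisquare(df)
        if draw <= bound:
            return draw, hit
        hit = True
    return bound, True


def fit_mcmc(design: ModelDesign, config: McmcConfig) -> PosteriorSamples:
    """Gibbs-sample the posterior of all effects and variance components."""
    config.validate()
    y = design.y
    n, k = design.x.shape
    var_y = float(np.var(y))
    if var_y == 0:
        raise ValidationError("response has zero variance")
    bound = config.variance_bound_factor * var_y
    rng = np.random.default_rng(config.seed)

    cow_idx = design.cow_idx
    n_cows = design.n_cows
    n_rec = np.bincount(cow_idx, minlength=n_cows).astype(np.float64)
    g = design.g
    gt = np.ascontiguousarray(g.T)
    wg2 = (n_rec[None, :] * gt ** 2).sum(axis=1)  # sum_l n_l g_lm^2
    sum_varg = g.var(axis=0).sum()

    has_herd = design.herd_idx is not None
    if has_herd:
        herd_idx = design.herd_idx
        n_herds = int(herd_idx.max()) + 1
        herd_n = np.bincount(herd_idx, minlength=n_herds).astype(float)

    # deterministic start: least-squares fixed effects, zero random effects,
    # equal quarters of the phenotypic variance
    xtx = design.x.T @ design.x
    xtx_chol = np.linalg.cholesky(np.linalg.inv(xtx))
    b = np.linalg.lstsq(design.x, y, rcond=None)[0]
    herd = np.zeros(n_herds) if has_herd else None
    pe = np.zeros(n_cows)
    a = np.zeros(design.n_snps)
    cow_a = np.zeros(n_cows)
    fv = config.fixed_variances
    s2_h = fv.get("herd", var_y / 4.0)
    s2_pe = fv.get("pe", var_y / 4.0)
    s2_e = fv.get("residual", var_y / 4.0)
    s2_snp = fv.get("snp", (var_y / 4.0) / max(sum_varg, 1e-12))

    n_saved = config.n_saved
    out = PosteriorSamples(
        fixed=np.empty((n_saved, k)), fixed_names=design.fixed_names,
        herd=np.empty((n_saved, n_herds)) if has_herd else None,
        pe=np.empty((n_saved, n_cows)) if design.include_pe else None,
        snp=np.empty((n_saved, design.n_snps)),
        cow_a=np.empty((n_saved, n_cows)),
        var_herd=np.zeros(n_saved), var_pe=np.zeros(n_saved),
        var_snp=np.empty(n_saved), var_e=np.empty(n_saved),
        var_a=np.empty(n_saved))

    bound_hits = 0
    saved = 0
    for it in range(config.n_iterations):
        herd_rec = herd[herd_idx] if has_herd else 0.0
        # fixed effects: joint normal draw around the GLS mean
        r = y - herd_rec - cow_a[cow_idx] - pe[cow_idx]
        b_hat = np.linalg.solve(xtx, design.x.T @ r)
        b = b_hat + np.sqrt(s2_e) * (xtx_chol @ rng.standard_normal(k))
        xb = design.x @ b

        if has_herd:
            r = y - xb - cow_a[cow_idx] - pe[cow_idx]
            s = np.bincount(herd_idx, weights=r, minlength=n_herds)
            prec = herd_n / s2_e + 1.0 / s2_h
            herd = s / s2_e / prec + rng.standard_normal(n_herds) / np.sqrt(prec)
            herd_rec = herd[herd_idx]

        if design.include_pe:
            r = y - xb - herd_rec - cow_a[cow_idx]
            s = np.bincount(cow_idx, weights=r, minlength=n_cows)
            prec = n_rec / s2_e + 1.0 / s2_pe
            pe = s / s2_e / prec + rng.standard_normal(n_cows) / np.sqrt(prec)

        # SNP effects via the single-site sweep on per-cow residual sums;
        # a zero SNP variance pins all effects (and the genomic term) at 0
        if s2_snp > 0:
            r = y - xb - herd_rec - pe[cow_idx]
            ebar = (np.bincount(cow_idx, weights=r, minlength=n_cows)
                    - n_rec * cow_a)
            _sweep_snps(gt, a, ebar, n_rec, wg2, s2_snp, s2_e,
                        rng.standard_normal(design.n_snps))
            cow_a = g @ a

        resid = y - xb - herd_rec - cow_a[cow_idx] - pe[cow_idx]
        if has_herd and "herd" not in fv:
            s2_h, hit = _draw_variance(rng, float(herd @ herd), n_herds, bound)
            bound_hits += hit
        if design.include_pe and "pe" not in fv:
            s2_pe, hit = _draw_variance(rng, float(pe @ pe), n_cows, bound)
            bound_hits += hit
        if "snp" not in fv:
            s2_snp, hit = _draw_variance(rng, float(a @ a), design.n_snps, bound)
            bound_hits += hit
        if "residual" not in fv:
            s2_e, hit = _draw_variance(rng, float(resid @ resid), n, bound)
            bound_hits += hit

        post_burn = it - config.n_burn_in
        if post_burn >= 0 and post_burn % config.thinning == 0 and saved < n_saved:
            out.fixed[saved] = b
            if has_herd:
                out.herd[saved] = herd
            if design.include_pe:
                out.pe[saved] = pe
            out.snp[saved] = a
            out.cow_a[saved] = cow_a
            out.var_herd[saved] = s2_h if has_herd else 0.0
            out.var_pe[saved] = s2_pe if design.include_pe else 0.0
            out.var_snp[saved] = s2_snp
            out.var_e[saved] = s2_e
            out.var_a[saved] = np.var(cow_a, ddof=1) if n_cows > 1 else 0.0
            saved += 1

    n_var_updates = config.n_iterations * (2 + has_herd + design.include_pe)
    if bound_hits > 0.5 * n_var_updates:
        out.bound_warning = True
        warnings.warn("variance draws hit the prior bound in most updates",
                      stacklevel=2)
    return out


def heritability(samples: PosteriorSamples,
                 wavenumber: float = float("nan")) -> HeritabilityEstimate:
    """Posterior mean/SD of h2 = s2_A / (s2_Herd + s2_A + s2_PE + s2_E),
    with s2_A taken per draw as the across-cow variance of the genomic values."""
    if samples.n_saved < 1:
        raise ValidationError("need at least one saved draw")
    num = samples.var_a
    den = samples.var_herd + samples.var_a + samples.var_pe + samples.var_e
    ok = den > 0
    n_skipped = int((~ok).sum())
    if n_skipped:
        log.info("skipping %d draws with zero total variance", n_skipped)
    if not ok.any():
        raise ValidationError("all draws have zero total variance")
    h2 = num[ok] / den[ok]
    mean = float(h2.mean())
    sd = float(h2.std(ddof=1)) if h2.size > 1 else 0.0
    return HeritabilityEstimate(
        wavenumber=wavenumber, mean=mean, sd=sd,
        passed=bool(mean >= 0.05), n_skipped_draws=n_skipped)


def gate_heritable(estimates: list[HeritabilityEstimate],
                   threshold: float = 0.05) -> list[HeritabilityEstimate]:
    """Keep wavenumbers whose posterior mean h2 is at least ``threshold``."""
    return [e for e in estimates if e.mean >= threshold]
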