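"""Configuration and orchestration: simulate/load -> select -> fit ->
window -> report, independently per population, plus cross-population
QTL overlap."""
from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io, model, spectra, windows
from .data import GenotypeData, SpectraDataset, ValidationError
from .simulate import SimulationConfig, simulate_genotypes, simulate_spectra

__all__ = ["PopulationSpec", "PipelineConfig", "PipelineResult",
           "run_pipeline", "run_from_manifest"]

log = logging.getLogger(__name__)


@dataclass
class PopulationSpec:
    name: str
    phenotypes: str | None = None
    genotypes: str | None = None
    snp_map: str | None = None
    simulation: SimulationConfig | None = None
    qc_rules: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if self.simulation is None:
            for attr in ("phenotypes", "genotypes", "snp_map"):
                path = getattr(self, attr)
                if path is None:
                    raise ValidationError(
                        f"population {self.name}: {attr} path required "
                        "when no simulation block is given")
                if not Path(path).exists():
                    raise ValidationError(
                        f"population {self.name}: missing file {path}")


@dataclass
class PipelineConfig:
    populations: list[PopulationSpec]
    out_dir: str = "spectragwas_out"
    seed: int = 0
    block_threshold: float = 0.95
    h2_gate: float = 0.05
    qtl_threshold: float = 0.35
    group_size: int = 100
    group_offsets: tuple[int, ...] = (1, 21, 41, 61, 81)
    min_group_size: int = 80
    mcmc: model.McmcConfig = field(default_factory=model.McmcConfig)
    #: cap on fitted wavenumbers per population (smoke runs); None = all
    max_wavenumbers: int | None = None
    make_plots: bool = False
    log_level: str = "INFO"

    def validate(self) -> None:
        if not self.populations:
            raise ValidationError("at least one population required")
        for t in (self.block_threshold, self.qtl_threshold):
            if t <= 0:
                raise ValidationError("thresholds must be positive")
        self.mcmc.validate()
        for pop in self.populations:
            pop.validate()

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        pops = []
        for p in raw.pop("populations", []):
            p = dict(p)
            sim = p.pop("simulation", None)
            if sim is not None:
                sim = SimulationConfig(**{
                    k: tuple(v) if isinstance(v, list) and k != "planted_qtl"
                    else ([tuple(q) for q in v] if k == "planted_qtl" else v)
                    for k, v in sim.items()})
            pops.append(PopulationSpec(simulation=sim, **p))
        mcmc = raw.pop("mcmc", None)
        cfg = cls(populations=pops, **{
            k: tuple(v) if k == "group_offsets" else v for k, v in raw.items()})
        if mcmc is not None:
            cfg.mcmc = model.McmcConfig(**mcmc)
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return _as_plain(dataclasses.asdict(self))


def _as_plain(obj):
    if isinstance(obj, dict):
        return {k: _as_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


@dataclass
class PipelineResult:
    out_dir: Path
    manifest: dict
    #: per population: dict with selection, heritability, qtl calls, ...
    populations: dict[str, dict]
    overlap: pd.DataFrame | None = None


def _load_population(pop: PopulationSpec,
                     seed: int) -> tuple[SpectraDataset, GenotypeData]:
    if pop.simulation is not None:
        cfg = dataclasses.replace(pop.simulation)
        cfg.seed = seed
        geno = simulate_genotypes(cfg)
        dataset, _truth = simulate_spectra(cfg, geno)
        return dataset, geno
    dataset = io.read_phenotypes(pop.phenotypes)
    geno = io.read_genotypes(pop.genotypes, pop.snp_map)
    return dataset, geno


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def _select_wavenumbers(dataset: SpectraDataset, config: PipelineConfig,
                        qc_rules: dict[str, float]):
    dataset, qc_log = spectra.apply_record_qc(dataset, qc_rules)
    retained = spectra.filter_water_regions(dataset.grid)
    corr = spectra.residualized_correlation(dataset, retained)
    wns = dataset.grid.values[retained]
    blocks = spectra.detect_blocks(corr, config.block_threshold, wavenumbers=wns)
    picks = [spectra.select_representative(b, corr) for b in blocks]
    return dataset, qc_log, retained, corr, blocks, picks


def run_population(pop: PopulationSpec, config: PipelineConfig,
                   out_dir: Path, seed: int) -> dict:
    """All stages for one population; returns tables and call objects."""
    dataset, geno = _load_population(pop, seed)
    dataset, qc_log, retained, corr, blocks, picks = _select_wavenumbers(
        dataset, config, pop.qc_rules)
    _write(qc_log, out_dir / "record_qc.tsv")
    block_table = pd.DataFrame(
        [{"block": b.block_id, "start_wn": b.wavenumbers[0],
          "end_wn": b.wavenumbers[-1], "n": len(b.wavenumbers)}
         for b in blocks])
    _write(block_table, out_dir / "blocks.tsv")
    np.savetxt(out_dir / "correlation_matrix.tsv", corr, delimiter="\t")

    if config.max_wavenumbers is not None:
        picks = picks[:config.max_wavenumbers]

    groups = windows.make_snp_groups(
        geno.snp_map, config.group_size, config.group_offsets,
        config.min_group_size)

    estimates, fits = [], {}
    for i, pick in enumerate(picks):
        design = model.build_design(dataset, geno, pick.wavenumber)
        mcfg = dataclasses.replace(config.mcmc, seed=seed * 100_003 + i)
        samples = model.fit_mcmc(design, mcfg)
        est = model.heritability(samples, pick.wavenumber)
        pick.heritability = est.mean
        estimates.append(est)
        fits[pick.wavenumber] = samples

    selection = pd.DataFrame(
        [{"block": p.block_id, "wavenumber": p.wavenumber,
          "correlation_sum": p.correlation_sum, "h2": p.heritability}
         for p in picks])
    _write(selection, out_dir / "selection.tsv")
    h2_table = pd.DataFrame(
        [{"wavenumber": e.wavenumber, "h2_mean": e.mean, "h2_sd": e.sd,
          "passed": e.passed} for e in estimates])
    _write(h2_table, out_dir / "heritability.tsv")

    kept = model.gate_heritable(estimates, config.h2_gate)
    kept_wns = [e.wavenumber for e in kept]

    variances: dict[float, list[windows.GroupVariance]] = {}
    calls: dict[float, list[windows.QtlCall]] = {}
    gv_rows, qtl_rows, man_frames = [], [], []
    for wn in kept_wns:
        samples = fits[wn]
        gvs = [windows.group_variance(samples, geno, grp, wn) for grp in groups]
        variances[wn] = gvs
        calls[wn] = windows.call_qtl(gvs, config.qtl_threshold)
        gv_rows += [{
            "wavenumber": wn, "chrom": gv.group.chrom,
            "offset": gv.group.offset, "first": gv.group.first,
            "last": gv.group.last, "bp_lower": gv.group.bp_lower,
            "bp_upper": gv.group.bp_upper, "var_gebv": gv.var_gebv,
            "percent_var_a": gv.percent_var_a} for gv in gvs]
        qtl_rows += [{
            "wavenumber": wn, "chrom": q.chrom, "bp_lower": q.bp_lower,
            "bp_upper": q.bp_upper, "n_groups": len(q.members),
            "peak_percent": q.peak.percent_var_a,
            "peak_bp_lower": q.peak.group.bp_lower,
            "peak_bp_upper": q.peak.group.bp_upper} for q in calls[wn]]
        man_frames.append(windows.manhattan_table(gvs, geno.snp_map))

    _write(pd.DataFrame(gv_rows), out_dir / "group_variance.tsv")
    _write(pd.DataFrame(qtl_rows), out_dir / "qtl.tsv")
    manhattan = (pd.concat(man_frames, ignore_index=True) if man_frames
                 else pd.DataFrame(columns=["wavenumber", "chrom", "offset",
                                            "bp_mid", "percent_var_a"]))
    _write(manhattan, out_dir / "manhattan.tsv")

    regions = windows.peak_regions(calls, variances,
                                   threshold=config.qtl_threshold)
    region_table = pd.DataFrame(
        [{"chrom": r.chrom, "label": r.label, "bp_lower": r.bp_lower,
          "bp_upper": r.bp_upper, "top_wavenumber": r.top_wavenumber,
          "associated": ";".join(f"{wn}:{pct:.4f}" for wn, pct in r.associated)}
         for r in regions])
    _write(region_table, out_dir / "peak_regions.tsv")

    if config.make_plots:
        _plot_outputs(corr, manhattan, config.qtl_threshold, out_dir)

    return {"selection": selection, "heritability": h2_table,
            "qtl": pd.DataFrame(qtl_rows), "calls": calls,
            "variances": variances, "regions": regions,
            "manhattan": manhattan}


def _plot_outputs(corr: np.ndarray, manhattan: pd.DataFrame,
                  threshold: float, out_dir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(corr, vmin=-1, vmax=1, cmap="RdBu_r")
    fig.colorbar(im, ax=ax, label="correlation")
    ax.set_title("Residualised wavenumber correlation")
    fig.savefig(out_dir / "correlation_heatmap.png", dpi=120)
    plt.close(fig)

    if len(manhattan):
        fig, ax = plt.subplots(figsize=(8, 3))
        for chrom, chunk in manhattan.groupby("chrom"):
            ax.scatter(chunk["bp_mid"], chunk["percent_var_a"], s=6,
                       label=f"chr{chrom}")
        ax.axhline(threshold, color="red", lw=1)
        ax.set_xlabel("middle-SNP position (bp)")
        ax.set_ylabel("% additive genetic variance")
        fig.savefig(out_dir / "manhattan.png", dpi=120)
        plt.close(fig)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage per population and the cross-population overlap."""
    config.validate()
    out_root = Path(config.out_dir)
    out_root.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    log.info("thresholds: block>%s h2>=%s qtl>%s", config.block_threshold,
             config.h2_gate, config.qtl_threshold)

    manifest = {
        "tool": "spectragwas",
        "version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": {},
        "outputs": [],
    }
    results: dict[str, dict] = {}
    try:
        for i, pop in enumerate(config.populations):
            pop_dir = out_root / pop.name
            pop_dir.mkdir(exist_ok=True)
            results[pop.name] = run_population(
                pop, config, pop_dir, seed=config.seed + i)
            manifest["stages"][pop.name] = "ok"
        overlap = None
        if len(config.populations) >= 2:
            a, b = (results[p.name] for p in config.populations[:2])
            calls_a = [q for qs in a["calls"].values() for q in qs]
            calls_b = [q for qs in b["calls"].values() for q in qs]
            overlap = windows.overlap_qtl(calls_a, calls_b)
            _write(overlap, out_root / "overlap.tsv")
            manifest["stages"]["overlap"] = "ok"
    except Exception as exc:
        manifest["stages"]["error"] = f"{type(exc).__name__}: {exc}"
        with open(out_root / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        raise

    manifest["outputs"] = sorted(
        str(p.relative_to(out_root)) for p in out_root.rglob("*") if p.is_file())
    with open(out_root / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return PipelineResult(out_dir=out_root, manifest=manifest,
                          populations=results, overlap=overlap)


def run_from_manifest(path: str | Path) -> PipelineResult:
    """Re-run a pipeline from the config echoed in a manifest."""
    with open(path) as fh:
        manifest = json.load(fh)
    return run_pipeline(PipelineConfig.from_dict(manifest["config"]))
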