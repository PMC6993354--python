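"""Overlapping 100-SNP window variance partition and QTL calling.

Each chromosome is tiled five times with windows of 100 consecutive SNPs
starting at ordinals 1, 21, 41, 61 and 81; truncated windows shorter than
80 SNPs are dropped. Per window the across-cow variance of the windowed
genomic value is expressed as a percentage of the total additive genetic
variance; windows above 0.35% are merged into QTL by base-pair overlap.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import GenotypeData, ValidationError
from .model import PosteriorSamples

__all__ = [
    "SnpGroup",
    "GroupVariance",
    "QtlCall",
    "PeakRegion",
    "make_snp_groups",
    "group_variance",
    "call_qtl",
    "peak_regions",
    "overlap_qtl",
    "manhattan_table",
]

GROUP_SIZE = 100
GROUP_OFFSETS = (1, 21, 41, 61, 81)
MIN_GROUP_SIZE = 80
QTL_THRESHOLD = 0.35


@dataclass(frozen=True)
class SnpGroup:
    chrom: int
    offset: int
    first: int          # 1-based ordinal within chromosome, inclusive
    last: int
    bp_lower: int
    bp_upper: int
    #: column indices of member SNPs in the genome-wide dosage matrix
    columns: tuple[int, ...]

    def __post_init__(self) -> None:
        # the [80, 100] size rule is enforced where groups are built
        # (make_snp_groups); the container only checks consistency
        n = self.last - self.first + 1
        if n < 1:
            raise ValidationError("group must span at least one SNP")
        if len(self.columns) != n:
            raise ValidationError("member count does not match ordinal span")

    @property
    def n_snps(self) -> int:
        return self.last - self.first + 1

    @property
    def key(self) -> tuple[int, int, int]:
        return (self.chrom, self.first, self.last)


@dataclass
class GroupVariance:
    group: SnpGroup
    wavenumber: float
    #: draw-averaged across-cow variance of the windowed genomic value
    var_gebv: float
    #: var_gebv as a percentage of the total additive genetic variance
    percent_var_a: float


@dataclass
class QtlCall:
    chrom: int
    wavenumber: float
    members: list[GroupVariance]
    bp_lower: int
    bp_upper: int
    peak: GroupVariance = field(init=False)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError("QTL needs at least one member group")
        self.peak = max(self.members, key=lambda gv: gv.percent_var_a)


@dataclass
class PeakRegion:
    chrom: int
    label: str
    bp_lower: int
    bp_upper: int
    #: (wavenumber, percent_var_a at the peak group), sorted descending
    associated: list[tuple[float, float]]
    top_wavenumber: float


def make_snp_groups(snp_map: pd.DataFrame,
                    group_size: int = GROUP_SIZE,
                    offsets: tuple[int, ...] = GROUP_OFFSETS,
                    min_size: int = MIN_GROUP_SIZE) -> list[SnpGroup]:
    """Tile each chromosome with overlapping fixed-size SNP windows.

    ``snp_map`` must be sorted by (chrom, bp); a window covers ordinals
    [o + j*size, o + (j+1)*size - 1] truncated at the chromosome end, and
    truncated windows below ``min_size`` are dropped.
    """
    srt = snp_map.sort_values(["chrom", "bp"], kind="stable")
    if not np.array_equal(srt.index.to_numpy(), np.arange(len(snp_map))):
        raise ValidationError("snp_map must be sorted by (chrom, bp)")
    groups: list[SnpGroup] = []
    for chrom, chunk in snp_map.groupby("chrom", sort=True):
        n = len(chunk)
        bp = chunk["bp"].to_numpy()
        base = int(chunk.index[0])
        for offset in offsets:
            first = offset
            while first <= n:
                last = min(first + group_size - 1, n)
                if last - first + 1 >= min_size:
                    groups.append(SnpGroup(
                        chrom=int(chrom), offset=offset, first=first, last=last,
                        bp_lower=int(bp[first - 1]), bp_upper=int(bp[last - 1]),
                        columns=tuple(range(base + first - 1, base + last))))
                first += group_size
    return groups


def group_variance(samples: PosteriorSamples, genotypes: GenotypeData,
                   group: SnpGroup, wavenumber: float = float("nan"),
                   per_draw_ratio: bool = False) -> GroupVariance:
    """Percentage of total additive genetic variance carried by one window.

    Per saved draw the windowed genomic value of each cow is the centred
    dosage of the member SNPs times that draw's effects; its across-cow
    variance is averaged over draws and divided by the draw-averaged total
    genomic variance (or, with ``per_draw_ratio``, ratios are averaged).
    """
    cols = np.asarray(group.columns)
    if cols.max() >= samples.snp.shape[1]:
        raise ValidationError("group SNPs not present in the fitted design")
    g = genotypes.centred_dosages()[:, cols]
    gebv = samples.snp[:, cols] @ g.T          # (draws, cows)
    var_draws = gebv.var(axis=1, ddof=1)
    if per_draw_ratio:
        ok = samples.var_a > 0
        percent = float(np.mean(var_draws[ok] / samples.var_a[ok]) * 100.0) \
            if ok.any() else 0.0
    else:
        total = float(samples.var_a.mean())
        percent = float(var_draws.mean() / total * 100.0) if total > 0 else 0.0
    return GroupVariance(group=group, wavenumber=wavenumber,
                         var_gebv=float(var_draws.mean()),
                         percent_var_a=percent)


def call_qtl(variances: list[GroupVariance],
             threshold: float = QTL_THRESHOLD) -> list[QtlCall]:
    """Merge significant windows into QTL per chromosome.

    Windows with percent_var_a strictly above ``threshold`` are grouped into
    connected components by (transitive) base-pair interval overlap; each
    component becomes one QTL with the union interval and its peak window.
    """
    significant = [gv for gv in variances if gv.percent_var_a > threshold]
    calls: list[QtlCall] = []
    by_chrom: dict[int, list[GroupVariance]] = {}
    for gv in significant:
        by_chrom.setdefault(gv.group.chrom, []).append(gv)
    for chrom in sorted(by_chrom):
        members = sorted(by_chrom[chrom], key=lambda gv: (gv.group.bp_lower,
                                                          gv.group.bp_upper))
        cluster: list[GroupVariance] = []
        hi = 0
        for gv in members:
            if cluster and gv.group.bp_lower > hi:
                calls.append(_finish_call(chrom, cluster))
                cluster = []
            if not cluster:
                hi = gv.group.bp_upper
            cluster.append(gv)
            hi = max(hi, gv.group.bp_upper)
        if cluster:
            calls.append(_finish_call(chrom, cluster))
    return calls


def _finish_call(chrom: int, members: list[GroupVariance]) -> QtlCall:
    wn = members[0].wavenumber
    return QtlCall(
        chrom=chrom, wavenumber=wn, members=list(members),
        bp_lower=min(gv.group.bp_lower for gv in members),
        bp_upper=max(gv.group.bp_upper for gv in members))


def peak_regions(calls: dict[float, list[QtlCall]],
                 variances: dict[float, list[GroupVariance]],
                 bond_groups: dict[float, str] | None = None,
                 threshold: float = QTL_THRESHOLD) -> list[PeakRegion]:
    """One region per chromosome (per chemical-bond group): the highest peak
    window across wavenumbers, with every wavenumber whose share at that
    window exceeds the threshold.
    """
    if bond_groups is None:
        bond_groups = {wn: "all" for wn in calls}
    regions: list[PeakRegion] = []
    for bond in sorted(set(bond_groups.values())):
        wns = [wn for wn in calls if bond_groups.get(wn) == bond]
        peaks: dict[int, GroupVariance] = {}
        for wn in wns:
            for call in calls[wn]:
                pk = call.peak
                cur = peaks.get(call.chrom)
                if cur is None or pk.percent_var_a > cur.percent_var_a:
                    peaks[call.chrom] = pk
        for chrom in sorted(peaks):
            peak = peaks[chrom]
            assoc = []
            for wn in wns:
                for gv in variances.get(wn, []):
                    if gv.group.key == peak.group.key and \
                            gv.percent_var_a > threshold:
                        assoc.append((wn, gv.percent_var_a))
            assoc.sort(key=lambda t: -t[1])
            regions.append(PeakRegion(
                chrom=chrom, label=str(chrom),
                bp_lower=peak.group.bp_lower, bp_upper=peak.group.bp_upper,
                associated=assoc,
                top_wavenumber=assoc[0][0] if assoc else peak.wavenumber))
    return regions


def overlap_qtl(calls_a: list[QtlCall],
                calls_b: list[QtlCall]) -> pd.DataFrame:
    """Per-chromosome counts of QTL and of base-pair overlaps between the
    two call sets. ``n_pairs`` counts intersecting (a, b) interval pairs;
    ``n_a_overlapping``/``n_b_overlapping`` count QTL with at least one
    partner on the other side.
    """
    chroms = sorted({c.chrom for c in calls_a} | {c.chrom for c in calls_b})
    rows = []
    for chrom in chroms:
        a = [c for c in calls_a if c.chrom == chrom]
        b = [c for c in calls_b if c.chrom == chrom]
        pairs = [(i, j) for i, qa in enumerate(a) for j, qb in enumerate(b)
                 if qa.bp_lower <= qb.bp_upper and qb.bp_lower <= qa.bp_upper]
        rows.append({
            "chrom": chrom,
            "n_qtl_a": len(a),
            "n_qtl_b": len(b),
            "n_pairs": len(pairs),
            "n_a_overlapping": len({i for i, _ in pairs}),
            "n_b_overlapping": len({j for _, j in pairs}),
        })
    return pd.DataFrame(rows, columns=["chrom", "n_qtl_a", "n_qtl_b",
                                       "n_pairs", "n_a_overlapping",
                                       "n_b_overlapping"])


def manhattan_table(variances: list[GroupVariance],
                    snp_map: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready table: each window's share placed at its middle SNP.

    The middle SNP is ordinal ceil(n/2) within the window.
    """
    rows = []
    for gv in variances:
        grp = gv.group
        mid_ordinal = (grp.n_snps + 1) // 2   # 1-based ceil(n/2)
        mid_col = grp.columns[mid_ordinal - 1]
        rows.append({
            "wavenumber": gv.wavenumber,
            "chrom": grp.chrom,
            "offset": grp.offset,
            "bp_mid": int(snp_map["bp"].iloc[mid_col]),
            "percent_var_a": gv.percent_var_a,
        })
    return pd.DataFrame(rows, columns=["wavenumber", "chrom", "offset",
                                       "bp_mid", "percent_var_a"])
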