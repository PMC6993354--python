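import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spectragwas.data import ValidationError
from spectragwas.model import PosteriorSamples
from spectragwas.windows import (GroupVariance, QtlCall, SnpGroup, call_qtl,
                                 group_variance, make_snp_groups,
                                 manhattan_table, overlap_qtl, peak_regions)

from conftest import make_genotypes


def chrom_map(n_snps, chrom=1, start=0):
    return pd.DataFrame({
        "snp": [f"s{chrom}_{i}" for i in range(n_snps)],
        "chrom": chrom,
        "bp": start + np.arange(1, n_snps + 1) * 1000,
    })


def brute_force_groups(n_snps, size=100, offsets=(1, 21, 41, 61, 81),
                       min_size=80):
    """Independent enumeration of (first, last) ordinals per offset."""
    out = []
    for o in offsets:
        for first in range(o, n_snps + 1, size):
            last = min(first + size - 1, n_snps)
            if last - first + 1 >= min_size:
                out.append((o, first, last))
    return out


def samples_from_draws(snp_draws, g):
    """Wrap explicit SNP-effect draws as PosteriorSamples."""
    snp_draws = np.asarray(snp_draws, dtype=float)
    cow_a = snp_draws @ g.T
    s = snp_draws.shape[0]
    return PosteriorSamples(
        fixed=np.zeros((s, 1)), fixed_names=("intercept",), herd=None,
        pe=None, snp=snp_draws, cow_a=cow_a,
        var_herd=np.zeros(s), var_pe=np.zeros(s),
        var_snp=np.full(s, 1.0), var_e=np.full(s, 1.0),
        var_a=cow_a.var(axis=1, ddof=1))


def make_gv(chrom, bp_lower, bp_upper, percent, offset=1, first=1):
    n = 80
    group = SnpGroup(chrom=chrom, offset=offset, first=first,
                     last=first + n - 1, bp_lower=bp_lower, bp_upper=bp_upper,
                     columns=tuple(range(n)))
    return GroupVariance(group=group, wavenumber=1000.0, var_gebv=percent,
                         percent_var_a=percent)


class TestMakeSnpGroups:
    @pytest.mark.parametrize("n_snps,expected_total", [
        (79, 0), (100, 2), (250, 9), (1000, 47)])
    def test_against_brute_force(self, n_snps, expected_total):
        groups = make_snp_groups(chrom_map(n_snps))
        oracle = brute_force_groups(n_snps)
        assert len(oracle) == len(groups)
        assert sorted((g.offset, g.first, g.last) for g in groups) == \
            sorted(oracle)
        if expected_total:
            assert len(groups) == expected_total

    def test_hundred_snp_chromosome_detail(self):
        groups = make_snp_groups(chrom_map(100))
        spans = sorted((g.offset, g.first, g.last) for g in groups)
        assert spans == [(1, 1, 100), (21, 21, 100)]

    def test_bp_bounds_span_members(self):
        smap = chrom_map(250)
        for g in make_snp_groups(smap):
            assert g.bp_lower == smap["bp"].iloc[g.first - 1 + 0]
            assert g.bp_upper == smap["bp"].iloc[g.last - 1]

    def test_groups_never_identical(self):
        groups = make_snp_groups(chrom_map(1000))
        keys = [(g.chrom, g.first, g.last) for g in groups]
        assert len(keys) == len(set(keys))

    def test_multi_chromosome_columns_offset(self):
        smap = pd.concat([chrom_map(120, chrom=1), chrom_map(120, chrom=2)],
                         ignore_index=True)
        groups = make_snp_groups(smap)
        for g in groups:
            if g.chrom == 2:
                assert min(g.columns) >= 120

    def test_unsorted_map_raises(self):
        smap = chrom_map(100).iloc[::-1].reset_index(drop=True)
        with pytest.raises(ValidationError):
            make_snp_groups(smap)

    @given(st.integers(min_value=2, max_value=600))
    @settings(max_examples=40, deadline=None)
    def test_property_matches_oracle(self, n_snps):
        groups = make_snp_groups(chrom_map(n_snps))
        assert sorted((g.offset, g.first, g.last) for g in groups) == \
            sorted(brute_force_groups(n_snps))
        for g in groups:
            assert 80 <= g.n_snps <= 100


class TestGroupVariance:
    def test_zero_effects_give_zero(self):
        geno = make_genotypes(n_cows=10, n_snps=100, seed=1)
        g = geno.centred_dosages()
        draws = np.zeros((3, 100))
        draws[:, 90:] = 1.0  # variance lives outside the group
        samples = samples_from_draws(draws, g)
        group = SnpGroup(chrom=1, offset=1, first=1, last=90, bp_lower=1000,
                         bp_upper=90_000, columns=tuple(range(90)))
        gv = group_variance(samples, geno, group)
        assert gv.percent_var_a == 0.0

    def test_brute_force_arithmetic_oracle(self):
        # printed-in-fixture instance: 5 cows, 4 SNPs, 3 draws
        dosages = np.array([[0, 1, 2, 1],
                            [1, 1, 0, 2],
                            [2, 0, 1, 0],
                            [0, 2, 2, 1],
                            [1, 0, 1, 2]], dtype=float)
        draws = np.array([[0.5, -0.2, 0.1, 0.3],
                          [0.4, -0.1, 0.0, 0.2],
                          [0.6, -0.3, 0.2, 0.4]])
        geno = make_genotypes(n_cows=5, n_snps=4, seed=0)
        geno.dosages[:] = dosages
        gc = dosages - dosages.mean(axis=0)
        samples = samples_from_draws(draws, gc)
        group = SnpGroup(chrom=1, offset=1, first=1, last=2, bp_lower=1000,
                         bp_upper=2000, columns=(0, 1))
        # fully spelled-out evaluation
        num, den = [], []
        for s in range(3):
            gebv = [sum(gc[l, m] * draws[s, m] for m in (0, 1))
                    for l in range(5)]
            tot = [sum(gc[l, m] * draws[s, m] for m in range(4))
                   for l in range(5)]
            num.append(np.var(gebv, ddof=1))
            den.append(np.var(tot, ddof=1))
        expected = np.mean(num) / np.mean(den) * 100.0
        gv = group_variance(samples, geno, group, per_draw_ratio=False)
        assert gv.percent_var_a == pytest.approx(expected, abs=1e-12)
        # switchable per-draw-ratio variant against its own oracle
        gv2 = group_variance(samples, geno, group, per_draw_ratio=True)
        expected2 = np.mean(np.array(num) / np.array(den)) * 100.0
        assert gv2.percent_var_a == pytest.approx(expected2, abs=1e-12)

    def test_invariant_to_cow_relabelling(self):
        geno = make_genotypes(n_cows=12, n_snps=100, seed=2)
        draws = np.random.default_rng(0).normal(size=(4, 100))
        group = SnpGroup(chrom=1, offset=1, first=1, last=80, bp_lower=1000,
                         bp_upper=80_000, columns=tuple(range(80)))
        gv1 = group_variance(samples_from_draws(draws, geno.centred_dosages()),
                             geno, group)
        perm = np.random.default_rng(1).permutation(12)
        geno2 = make_genotypes(n_cows=12, n_snps=100, seed=2)
        geno2.dosages[:] = geno.dosages[perm]
        gv2 = group_variance(samples_from_draws(draws,
                                                geno2.centred_dosages()),
                             geno2, group)
        assert gv1.percent_var_a == pytest.approx(gv2.percent_var_a, rel=1e-12)

    def test_invariant_to_zero_effect_snps(self):
        geno = make_genotypes(n_cows=12, n_snps=100, seed=3)
        rng = np.random.default_rng(2)
        draws = rng.normal(size=(4, 100))
        draws[:, 80:] = 0.0
        group = SnpGroup(chrom=1, offset=1, first=1, last=80, bp_lower=1000,
                         bp_upper=80_000, columns=tuple(range(80)))
        g = geno.centred_dosages()
        full = group_variance(samples_from_draws(draws, g), geno, group)
        trimmed = group_variance(samples_from_draws(draws[:, :80], g[:, :80]),
                                 geno.subset_snps(np.arange(100) < 80), group)
        assert full.percent_var_a == pytest.approx(trimmed.percent_var_a,
                                                   rel=1e-12)

    def test_group_outside_design_raises(self):
        geno = make_genotypes(n_cows=10, n_snps=100, seed=1)
        samples = samples_from_draws(np.zeros((2, 90)),
                                     geno.centred_dosages()[:, :90])
        group = SnpGroup(chrom=1, offset=1, first=21, last=100, bp_lower=1,
                         bp_upper=2, columns=tuple(range(20, 100)))
        with pytest.raises(ValidationError):
            group_variance(samples, geno, group)


def brute_force_components(intervals):
    """Connected components of the interval-overlap graph, by enumeration."""
    n = len(intervals)
    adj = {i: set() for i in range(n)}
    for i, j in itertools.combinations(range(n), 2):
        (a1, b1), (a2, b2) = intervals[i], intervals[j]
        if a1 <= b2 and a2 <= b1:
            adj[i].add(j)
            adj[j].add(i)
    seen, comps = set(), []
    for i in range(n):
        if i in seen:
            continue
        stack, comp = [i], set()
        while stack:
            k = stack.pop()
            if k in comp:
                continue
            comp.add(k)
            stack.extend(adj[k] - comp)
        seen |= comp
        comps.append(sorted(comp))
    return comps


class TestCallQtl:
    def test_nothing_significant(self):
        gvs = [make_gv(1, 1000, 2000, 0.1), make_gv(1, 1500, 2500, 0.35)]
        assert call_qtl(gvs) == []  # 0.35 itself is not strictly above

    def test_transitive_merge(self):
        gvs = [make_gv(1, 100, 300, 0.5), make_gv(1, 250, 500, 0.6),
               make_gv(1, 450, 700, 0.7)]
        calls = call_qtl(gvs)
        assert len(calls) == 1
        q = calls[0]
        assert (q.bp_lower, q.bp_upper) == (100, 700)
        assert q.peak.percent_var_a == 0.7

    def test_two_clusters_against_component_oracle(self):
        spec = [(1, 100, 300, 0.4), (1, 200, 400, 0.9), (1, 350, 500, 0.5),
                (1, 900, 1100, 0.6), (1, 1050, 1200, 0.8),
                (2, 10, 20, 0.45), (2, 15, 30, 0.55)]
        gvs = [make_gv(*s) for s in spec]
        calls = call_qtl(gvs)
        for chrom in (1, 2):
            sub = [(lo, hi) for c, lo, hi, _ in spec if c == chrom]
            comps = brute_force_components(sub)
            got = [c for c in calls if c.chrom == chrom]
            assert len(got) == len(comps)
            for call, comp in zip(
                    sorted(got, key=lambda c: c.bp_lower),
                    sorted(comps, key=lambda c: min(sub[i][0] for i in c))):
                assert call.bp_lower == min(sub[i][0] for i in comp)
                assert call.bp_upper == max(sub[i][1] for i in comp)
                best = max((p for c, lo, hi, p in spec
                            if c == chrom and (lo, hi) in
                            [sub[i] for i in comp]))
                assert call.peak.percent_var_a == best

    def test_intervals_bounded_by_members(self):
        gvs = [make_gv(1, 100, 300, 0.5), make_gv(1, 250, 500, 0.6)]
        (q,) = call_qtl(gvs)
        los = [gv.group.bp_lower for gv in q.members]
        his = [gv.group.bp_upper for gv in q.members]
        assert q.bp_lower == min(los) and q.bp_upper == max(his)

    def test_strict_threshold(self):
        gvs = [make_gv(1, 100, 300, 0.351)]
        assert len(call_qtl(gvs)) == 1
        assert call_qtl([make_gv(1, 100, 300, 0.35)]) == []


class TestPeakRegions:
    def test_single_wavenumber_single_qtl(self):
        gv = make_gv(1, 100, 300, 0.5)
        (call,) = call_qtl([gv])
        regions = peak_regions({1000.0: [call]}, {1000.0: [gv]})
        (r,) = regions
        assert (r.chrom, r.bp_lower, r.bp_upper) == (1, 100, 300)
        assert r.top_wavenumber == 1000.0

    def test_two_wavenumbers_share_peak_group(self):
        gv_a = make_gv(1, 100, 300, 0.5)
        gv_b = make_gv(1, 100, 300, 0.4)
        gv_b.wavenumber = 2000.0
        calls = {1000.0: call_qtl([gv_a]), 2000.0: call_qtl([gv_b])}
        (r,) = peak_regions(calls, {1000.0: [gv_a], 2000.0: [gv_b]})
        assert r.associated == [(1000.0, 0.5), (2000.0, 0.4)]
        assert r.top_wavenumber == 1000.0

    def test_one_region_per_chromosome_argmax_oracle(self):
        rng = np.random.default_rng(7)
        variances = {}
        calls = {}
        for wn in (1000.0, 1500.0, 2000.0):
            gvs = []
            for chrom in (1, 2, 3):
                for start in (100, 5000, 9000):
                    gv = make_gv(chrom, start, start + 900,
                                 float(rng.uniform(0.2, 1.0)))
                    gv.wavenumber = wn
                    gvs.append(gv)
            variances[wn] = gvs
            calls[wn] = call_qtl(gvs)
        regions = peak_regions(calls, variances)
        assert [r.chrom for r in regions] == [1, 2, 3]
        for r in regions:
            best = max((gv for gvs in variances.values() for gv in gvs
                        if gv.group.chrom == r.chrom),
                       key=lambda gv: gv.percent_var_a)
            assert (r.bp_lower, r.bp_upper) == (best.group.bp_lower,
                                                best.group.bp_upper)

    def test_bond_groups_split_regions(self):
        gv_a = make_gv(1, 100, 300, 0.5)
        gv_b = make_gv(1, 500, 700, 0.4)
        gv_b.wavenumber = 2000.0
        calls = {1000.0: call_qtl([gv_a]), 2000.0: call_qtl([gv_b])}
        regions = peak_regions(calls, {1000.0: [gv_a], 2000.0: [gv_b]},
                               bond_groups={1000.0: "C-H", 2000.0: "C=O"})
        assert len(regions) == 2


class TestOverlap:
    def test_identical_sets_all_overlap(self):
        gvs = [make_gv(1, 100, 300, 0.5), make_gv(2, 100, 300, 0.6)]
        calls = call_qtl(gvs)
        table = overlap_qtl(calls, calls)
        assert (table["n_pairs"] >= 1).all()
        assert (table["n_a_overlapping"] == table["n_qtl_a"]).all()

    def test_disjoint_chromosomes(self):
        a = call_qtl([make_gv(1, 100, 300, 0.5)])
        b = call_qtl([make_gv(2, 100, 300, 0.5)])
        table = overlap_qtl(a, b)
        assert table["n_pairs"].sum() == 0

    def test_staggered_intervals_against_pair_scan(self):
        a_spec = [(1, 100, 500), (1, 900, 1200), (2, 50, 80)]
        b_spec = [(1, 450, 950), (1, 2000, 2100), (2, 10, 60), (2, 70, 90)]
        a = [QtlCall(chrom=c, wavenumber=1.0,
                     members=[make_gv(c, lo, hi, 0.5)], bp_lower=lo,
                     bp_upper=hi) for c, lo, hi in a_spec]
        b = [QtlCall(chrom=c, wavenumber=1.0,
                     members=[make_gv(c, lo, hi, 0.5)], bp_lower=lo,
                     bp_upper=hi) for c, lo, hi in b_spec]
        table = overlap_qtl(a, b).set_index("chrom")
        expected_pairs = {1: 0, 2: 0}
        for (ca, la, ha) in a_spec:
            for (cb, lb, hb) in b_spec:
                if ca == cb and la <= hb and lb <= ha:
                    expected_pairs[ca] += 1
        assert table.loc[1, "n_pairs"] == expected_pairs[1]
        assert table.loc[2, "n_pairs"] == expected_pairs[2]
        # symmetry
        rev = overlap_qtl(b, a).set_index("chrom")
        assert (rev["n_pairs"] == table["n_pairs"]).all()


class TestManhattan:
    def test_middle_snp_orientation(self):
        smap = chrom_map(100)
        groups = make_snp_groups(smap)
        gvs = [GroupVariance(group=g, wavenumber=1000.0, var_gebv=0.0,
                             percent_var_a=0.1) for g in groups]
        table = manhattan_table(gvs, smap)
        by = {(r.offset): r for r in table.itertuples()}
        # offset-1 group has 100 SNPs: middle ordinal ceil(100/2) = 50
        assert by[1].bp_mid == smap["bp"].iloc[49]
        # offset-21 group has 80 SNPs: middle ordinal 40 -> overall SNP 60
        assert by[21].bp_mid == smap["bp"].iloc[20 + 39]
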