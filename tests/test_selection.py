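"""Selection scan: Weir-Cockerham components, EHH/iHH, XP-EHH, quantile
selection, candidate intersection and gene annotation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from helpers import ehh_pair_oracle, make_gm, make_haps, two_group_popmap, wc_scalar_reference
from sweepscan import (
    ConfigError,
    EhhCurve,
    ParseError,
    ScanConfig,
    ValidationError,
    annotate_genes,
    build_candidates,
    ehh,
    fst_scan,
    ihh,
    top_quantile,
    wc_components,
    xpehh_scan,
)
from sweepscan.selection import population_ihh, read_bed_genes, read_gff3_genes


class TestWcComponents:
    def test_monomorphic_locus_undefined(self):
        res = wc_components(10, 1.0, 0.0, 10, 1.0, 0.0)
        assert res.a == 0 and res.b == 0 and res.c == 0
        assert not res.defined
        assert np.isnan(res.theta)

    def test_fixed_difference_theta_one(self):
        res = wc_components(10, 1.0, 0.0, 10, 0.0, 0.0)
        assert res.theta == pytest.approx(1.0)
        assert res.a == pytest.approx(0.5)
        assert res.b == pytest.approx(0.0, abs=1e-15)
        assert res.c == 0.0

    def test_vectorized_matches_scalar_reference(self):
        rng = np.random.default_rng(9)
        n1 = rng.integers(5, 60, 1000).astype(float)
        n2 = rng.integers(5, 60, 1000).astype(float)
        p1 = rng.uniform(0, 1, 1000)
        p2 = rng.uniform(0, 1, 1000)
        h1 = 2 * p1 * (1 - p1) * rng.uniform(0.5, 1.0, 1000)
        h2 = 2 * p2 * (1 - p2) * rng.uniform(0.5, 1.0, 1000)
        res = wc_components(n1, p1, h1, n2, p2, h2)
        for i in range(1000):
            a, b, c, theta = wc_scalar_reference(n1[i], p1[i], h1[i], n2[i], p2[i], h2[i])
            assert res.a[i] == pytest.approx(a, abs=1e-12)
            assert res.b[i] == pytest.approx(b, abs=1e-12)
            assert res.c[i] == pytest.approx(c, abs=1e-12)
            if res.defined[i]:
                assert res.theta[i] == pytest.approx(theta, abs=1e-12)

    @given(
        p1=st.floats(0.0, 1.0),
        p2=st.floats(0.0, 1.0),
        n1=st.integers(2, 100),
        n2=st.integers(2, 100),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_theta_never_exceeds_one(self, p1, p2, n1, n2):
        res = wc_components(n1, p1, 2 * p1 * (1 - p1), n2, p2, 2 * p2 * (1 - p2))
        if res.defined:
            assert res.theta <= 1.0 + 1e-12

    def test_small_sample_flagged_undefined(self):
        res = wc_components(1, 0.5, 0.5, 10, 0.2, 0.3)
        assert not res.defined


class TestFstScan:
    def test_cloned_groups_nonpositive_theta(self):
        rng = np.random.default_rng(10)
        block = rng.binomial(2, rng.uniform(0.2, 0.8, 50), size=(8, 50)).astype(np.int8)
        g = make_gm(np.vstack([block, block]))
        pm = two_group_popmap(g.samples, 8)
        scan = fst_scan(g, pm)
        assert (scan.theta[scan.fst_defined] <= 1e-12).all()

    def test_sweep_like_snp_has_high_theta(self):
        res = wc_components(40, 0.95, 2 * 0.95 * 0.05, 40, 0.10, 2 * 0.10 * 0.90)
        assert res.theta > 0.5

    def test_scan_matches_per_locus_calls(self, small_ds):
        from sweepscan.genotype_io import group_stats

        g, pm = small_ds.genotypes, small_ds.popmap
        scan = fst_scan(g, pm)
        n1, p1, h1 = group_stats(g, pm, "G1")
        n2, p2, h2 = group_stats(g, pm, "G2")
        rng = np.random.default_rng(0)
        for j in rng.choice(g.n_variants, 50, replace=False):
            single = wc_components(n1[j], p1[j], h1[j], n2[j], p2[j], h2[j])
            if single.defined:
                assert scan.theta[j] == pytest.approx(float(single.theta), abs=1e-12)
            else:
                assert not scan.fst_defined[j]

    def test_empty_group_is_error(self, small_ds):
        from sweepscan import PopulationMap

        pm = PopulationMap({s: ("B", "G1") for s in small_ds.genotypes.samples})
        with pytest.raises(ValidationError, match="empty"):
            fst_scan(small_ds.genotypes, pm)


class TestEhh:
    def test_identical_haplotypes_stay_at_one(self):
        h = make_haps(np.tile([1, 0, 1, 0, 1], (6, 1)))
        curve = ehh(h, 2, "right")
        assert all(e == 1.0 for _, e in curve.points)

    def test_all_distinct_after_core_is_zero(self):
        haps = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=np.uint8)
        h = make_haps(haps)
        curve = ehh(h, 0, "right")
        assert curve.points[1][1] == 0.0
        assert curve.reason == "cutoff"

    def test_two_identical_pairs_give_one_third(self):
        # 4 haplotypes forming two identical pairs -> (1+1)/C(4,2) = 1/3
        haps = np.array([[0, 0, 0], [0, 0, 0], [1, 1, 1], [1, 1, 0]], dtype=np.uint8)
        h = make_haps(haps, positions=[1000, 2000, 3000])
        curve = ehh(h, 0, "right")
        assert curve.points[1][1] == pytest.approx(2 / 6)  # classes {2,2}
        assert curve.points[1][1] == pytest.approx(
            ehh_pair_oracle(haps, 0, 1))

    def test_monotone_and_matches_pair_enumeration(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            n, m = int(rng.integers(4, 16)) * 2, int(rng.integers(5, 30))
            haps = rng.integers(0, 2, size=(n, m)).astype(np.uint8)
            h = make_haps(haps)
            core = int(rng.integers(0, m))
            for side, step in (("left", -1), ("right", 1)):
                curve = ehh(h, core, side, ScanConfig(ehh_cutoff=0.0001))
                vals = [e for _, e in curve.points]
                assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))
                for k, (_, e) in enumerate(curve.points[1:], start=1):
                    assert e == pytest.approx(
                        ehh_pair_oracle(haps, core, core + step * k), abs=1e-12)

    def test_gap_truncation(self):
        haps = np.tile([0, 1], (4, 1)).astype(np.uint8)
        h = make_haps(haps, positions=[1000, 500_000])
        curve = ehh(h, 0, "right", ScanConfig(max_gap_bp=200_000))
        assert curve.reason == "gap"
        assert len(curve.points) == 1

    def test_core_out_of_range_errors(self):
        h = make_haps(np.zeros((4, 3), dtype=np.uint8))
        with pytest.raises(ValidationError):
            ehh(h, 5, "right")


class TestIhh:
    def test_curve_at_cutoff_has_zero_area(self):
        cfg = ScanConfig(ehh_cutoff=0.05)
        left = EhhCurve(0, "left", [(0.0, 0.05), (1000.0, 0.05)], "chrom_end")
        right = EhhCurve(0, "right", [(0.0, 0.05), (1000.0, 0.05)], "chrom_end")
        area, defined = ihh(left, right, cfg)
        assert area == 0.0
        assert not defined

    def test_triangle_closed_form(self):
        # (0,1) to (1000, 0.05) with cutoff 0.05 -> 0.5 * 1000 * 0.95 = 475
        cfg = ScanConfig(ehh_cutoff=0.05)
        left = EhhCurve(0, "left", [(0.0, 1.0)], "cutoff")
        right = EhhCurve(0, "right", [(0.0, 1.0), (1000.0, 0.05)], "cutoff")
        area, _ = ihh(left, right, cfg)
        assert area == pytest.approx(475.0)

    def test_matches_fine_riemann_sum(self):
        rng = np.random.default_rng(13)
        cfg = ScanConfig(ehh_cutoff=0.05)
        for _ in range(5):
            dists = np.sort(rng.uniform(0, 50_000, 20))
            vals = np.sort(rng.uniform(0.0, 1.0, 20))[::-1]
            pts = [(0.0, 1.0)] + list(zip(dists, vals))
            curve = EhhCurve(0, "right", pts, "cutoff")
            flat = EhhCurve(0, "left", [(0.0, 1.0)], "cutoff")
            area, _ = ihh(flat, curve, cfg)
            # fine-grid Riemann sum over the piecewise-linear curve
            xs = np.array([p[0] for p in pts])
            ys = np.clip(np.array([p[1] for p in pts]) - cfg.ehh_cutoff, 0, None)
            grid = np.linspace(xs[0], xs[-1], 200_001)
            riemann = np.trapezoid(np.interp(grid, xs, ys), grid)
            assert area == pytest.approx(riemann, rel=1e-6)

    def test_mismatched_cores_error(self):
        with pytest.raises(ValidationError):
            ihh(EhhCurve(0, "left", [(0.0, 1.0)], "cutoff"),
                EhhCurve(1, "right", [(0.0, 1.0)], "cutoff"))


class TestXpehh:
    def test_fast_path_matches_per_core_curves(self, small_ds):
        h = small_ds.hap_g1.take_variants(range(150))
        cfg = ScanConfig()
        fast_ihh, fast_def = population_ihh(h, cfg)
        for core in range(0, 150, 7):
            left = ehh(h, core, "left", cfg)
            right = ehh(h, core, "right", cfg)
            area, defined = ihh(left, right, cfg)
            assert fast_ihh[core] == pytest.approx(area, abs=1e-6)
            assert fast_def[core] == defined

    def test_identical_populations_raw_zero(self, small_ds):
        h = small_ds.hap_g1
        xp = xpehh_scan(h, h)
        defined = xp.xpehh_defined.to_numpy()
        assert defined.any()
        assert np.allclose(xp.xpehh_raw[defined], 0.0)

    def test_swapping_populations_negates_raw(self, small_ds):
        a = xpehh_scan(small_ds.hap_g1, small_ds.hap_g2)
        b = xpehh_scan(small_ds.hap_g2, small_ds.hap_g1)
        d = (a.xpehh_defined & b.xpehh_defined).to_numpy()
        assert d.any()
        assert np.allclose(a.xpehh_raw[d], -b.xpehh_raw[d], atol=1e-10)

    def test_standardized_scores_unit_scale(self, small_ds):
        xp = xpehh_scan(small_ds.hap_g1, small_ds.hap_g2)
        std = xp.xpehh_std[xp.xpehh_defined].to_numpy()
        assert abs(std.mean()) < 1e-9
        assert abs(std.std() - 1.0) < 1e-9

    def test_mismatched_variants_error(self, small_ds):
        with pytest.raises(ValidationError, match="share variants"):
            xpehh_scan(small_ds.hap_g1.take_variants(range(10)),
                       small_ds.hap_g2.take_variants(range(1, 11)))


class TestTopQuantile:
    def test_printed_count_at_study_scale(self):
        rng = np.random.default_rng(1)
        values = rng.permutation(46_355) / 46_355.0  # distinct scores
        sel, thr = top_quantile(values, 0.01)
        assert len(sel) == 464
        assert thr == values[np.argsort(values)][-464]

    def test_five_percent_of_hundred(self):
        sel, _ = top_quantile(np.arange(100, dtype=float), 0.05)
        assert len(sel) == 5
        assert set(sel) == {95, 96, 97, 98, 99}

    def test_boundary_ties_all_included(self):
        values = np.array([9.0, 8.0, 8.0, 8.0, 5, 4, 3, 2, 1, 0])
        sel, thr = top_quantile(values, 0.2)  # ceil(2) = 2 but 3-way tie at 8
        assert len(sel) == 4
        assert thr == 8.0

    def test_undefined_values_ignored(self):
        values = np.array([np.nan, 3.0, 2.0, 1.0, np.nan])
        sel, _ = top_quantile(values, 0.4, defined=~np.isnan(values))
        assert list(sel) == [1, 2]

    def test_bad_fraction_rejected(self):
        with pytest.raises(ConfigError):
            top_quantile(np.arange(10.0), 0.6)


class TestBuildCandidates:
    def test_disjoint_tails_all_defined(self):
        cand = build_candidates([0, 1], [2, 3], np.ones(5, dtype=bool))
        assert len(cand.intersect) == 0 and len(cand.rescue) == 0

    def test_intersect_and_rescue(self):
        defined = np.ones(6, dtype=bool)
        defined[1] = False
        cand = build_candidates([1, 2, 3], [2, 3, 4], defined)
        assert list(cand.intersect) == [2, 3]
        assert list(cand.rescue) == [1]
        assert list(cand.union) == [1, 2, 3]

    def test_subset_gives_full_intersection(self):
        cand = build_candidates([2, 3], [1, 2, 3, 4], np.ones(6, dtype=bool))
        assert list(cand.intersect) == [2, 3]
        assert len(cand.rescue) == 0

    def test_union_is_disjoint_sum(self):
        rng = np.random.default_rng(14)
        defined = rng.random(50) > 0.2
        fst_sel = rng.choice(50, 10, replace=False)
        xp_sel = rng.choice(np.flatnonzero(defined), 10, replace=False)
        cand = build_candidates(fst_sel, xp_sel, defined)
        assert len(cand.union) == len(cand.intersect) + len(cand.rescue)


class TestAnnotateGenes:
    GENES = pd.DataFrame(
        {"chrom": ["1", "1"], "start": [500, 100_000], "end": [2000, 130_000],
         "strand": ["+", "-"], "symbol": ["GA", "GB"]}
    )

    def snps(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "pos", "vid"])

    def test_snp_inside_gene_reported(self):
        out = annotate_genes(self.snps([("1", 1000, "s1")]), self.GENES, 25_000)
        assert list(out.symbol) == ["GA"]

    def test_snp_beyond_flank_not_reported(self):
        out = annotate_genes(self.snps([("1", 160_001, "s1")]), self.GENES, 25_000)
        assert len(out) == 0  # 30 kb downstream of GB with a 25 kb flank

    def test_flank_boundary_inclusive(self):
        out = annotate_genes(self.snps([("1", 155_000, "s1")]), self.GENES, 25_000)
        assert list(out.symbol) == ["GB"]

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(15)
        genes = pd.DataFrame({
            "chrom": ["1"] * 10,
            "start": rng.integers(1, 900_000, 10),
            "strand": ["+"] * 10,
            "symbol": [f"G{i}" for i in range(10)],
        })
        genes["end"] = genes.start + rng.integers(1000, 50_000, 10)
        snps = self.snps([("1", int(p), f"s{i}")
                          for i, p in enumerate(rng.integers(1, 1_000_000, 5))])
        flank = 25_000
        out = annotate_genes(snps, genes, flank)
        expect = set()
        for _, gene in genes.iterrows():
            for _, snp in snps.iterrows():
                if gene.start - flank <= snp.pos <= gene.end + flank:
                    expect.add(gene.symbol)
        assert set(out.symbol) == expect

    def test_gff3_parse_error_names_line(self, tmp_path):
        p = tmp_path / "bad.gff3"
        p.write_text("##gff-version 3\n1\tsim\tgene\t100\t200\t.\t+\t.\n")
        with pytest.raises(ParseError, match=r":2:"):
            read_gff3_genes(p)

    def test_bed_coordinates_converted(self, tmp_path):
        p = tmp_path / "g.bed"
        p.write_text("1\t99\t200\tGX\t0\t+\n")
        out = read_bed_genes(p)
        assert out.start.iloc[0] == 100 and out.end.iloc[0] == 200
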