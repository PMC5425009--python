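"""Selection scan: Weir-Cockerham components against hand-evaluated values,
window enumeration, outlier threshold/merging and opposite-homozygote logic."""

import numpy as np
import pytest

from polymap import selscan, simdata
from polymap.gio import MISSING, VariantSite
from polymap.selscan import FstWindow

from conftest import make_matrix


def _window(chrom="1", start=0, end=100_000, n=20, fst=0.5, qualifies=True):
    return FstWindow(chrom=chrom, start=start, end=end, n_snps=n, fst=fst,
                     fst_raw=fst, qualifies=qualifies)


class TestWeirCockerham:
    def test_hand_evaluated_components(self):
        # group A (1 hom-ref, 1 het, 1 hom-alt): n=3, p=1/2, h_obs=1/3
        # group B (3 hom-ref):                   n=3, p=0,   h_obs=0
        # nbar=3, nc=3, pbar=1/4, s2=1/8, hbar=1/6 give a=b=c=1/12 exactly
        a, b, c, ratio = selscan.wc_fst_site((1, 1, 1), (3, 0, 0))
        assert a == pytest.approx(1 / 12, abs=1e-12)
        assert b == pytest.approx(1 / 12, abs=1e-12)
        assert c == pytest.approx(1 / 12, abs=1e-12)
        assert ratio == pytest.approx(1 / 3, abs=1e-12)

    def test_fixed_difference_gives_one(self):
        a, b, c, ratio = selscan.wc_fst_site((3, 0, 0), (0, 0, 3))
        assert ratio == pytest.approx(1.0, abs=1e-12)
        assert b == pytest.approx(0.0, abs=1e-12)
        assert c == 0.0

    def test_identical_counts_give_nonpositive_ratio(self):
        *_, ratio = selscan.wc_fst_site((1, 1, 1), (1, 1, 1))
        assert ratio <= 0.0

    def test_monomorphic_flagged_as_zero_components(self):
        a, b, c, ratio = selscan.wc_fst_site((3, 0, 0), (3, 0, 0))
        assert (a, b, c) == (0.0, 0.0, 0.0)
        assert np.isnan(ratio)

    def test_vectorized_matches_scalar(self, rng):
        ca = rng.integers(-1, 3, size=(3, 50)).astype(np.int8)
        cb = rng.integers(-1, 3, size=(3, 50)).astype(np.int8)
        ma, mb = make_matrix(ca), make_matrix(cb)
        a, b, c = selscan.wc_components(ma, mb)
        for j in range(50):
            counts_a = tuple(int(np.sum(ca[:, j] == v)) for v in (0, 1, 2))
            counts_b = tuple(int(np.sum(cb[:, j] == v)) for v in (0, 1, 2))
            if sum(counts_a) == 0 or sum(counts_b) == 0:
                assert np.isnan(a[j])
                continue
            sa, sb, sc, _ = selscan.wc_fst_site(counts_a, counts_b)
            assert a[j] == pytest.approx(sa, abs=1e-12, nan_ok=True)
            assert b[j] == pytest.approx(sb, abs=1e-12, nan_ok=True)
            assert c[j] == pytest.approx(sc, abs=1e-12, nan_ok=True)

    def test_hudson_estimator_for_fixed_difference(self):
        assert selscan.hudson_fst_site((3, 0, 0), (0, 0, 3)) == \
            pytest.approx(1.0)


class TestWindows:
    def test_window_start_enumeration_and_truncation(self):
        sites = [VariantSite("1", 50_000, "A", "G")]
        a = np.array([0.5])
        w = selscan.window_fst(sites, a, a * 0, a * 0, {"1": 150_000})
        # starts 0, 10k, ..., 140k; trailing windows truncated at 150 kb
        assert len(w) == 15
        assert w[0].start == 0 and w[-1].start == 140_000
        assert w[-1].end == 150_000
        assert w[5].end == 150_000  # start 50k would reach 150k exactly

    def test_all_fixed_differences_give_window_fst_one(self):
        n = 30
        sites = [VariantSite("1", 1000 * (i + 1), "A", "G") for i in range(n)]
        a = np.full(n, 0.5)
        zeros = np.zeros(n)
        w = selscan.window_fst(sites, a, zeros, zeros, {"1": 40_000},
                               window=40_000, step=40_000, min_snps=10)
        assert w[0].fst == 1.0 and w[0].qualifies

    def test_single_site_window_equals_per_site_ratio(self):
        a, b, c, ratio = selscan.wc_fst_site((1, 1, 1), (3, 0, 0))
        sites = [VariantSite("1", 500, "A", "G")]
        w = selscan.window_fst(sites, np.array([a]), np.array([b]),
                               np.array([c]), {"1": 1000}, window=1000,
                               step=1000, min_snps=1)
        assert w[0].fst_raw == pytest.approx(ratio, abs=1e-12)

    def test_empty_chromosome_windows_do_not_qualify(self):
        sites = [VariantSite("1", 10, "A", "G")]
        arr = np.array([0.2])
        w = selscan.window_fst(sites, arr, arr, arr,
                               {"1": 30_000, "7": 30_000})
        chr7 = [x for x in w if x.chrom == "7"]
        assert all(x.n_snps == 0 and not x.qualifies for x in chr7)

    def test_unknown_chromosome_rejected(self):
        sites = [VariantSite("5", 10, "A", "G")]
        arr = np.array([0.2])
        with pytest.raises(ValueError, match="without a length"):
            selscan.window_fst(sites, arr, arr, arr, {"1": 1000})

    def test_undefined_sites_excluded_from_counts(self):
        sites = [VariantSite("1", 100, "A", "G"), VariantSite("1", 200, "A", "G")]
        a = np.array([0.5, 0.0])
        bc = np.array([0.0, 0.0])
        w = selscan.window_fst(sites, a, bc, bc, {"1": 1000}, window=1000,
                               step=1000, min_snps=1)
        assert w[0].n_snps == 1  # the monomorphic (0,0,0) site contributes nothing
        assert w[0].fst == 1.0


class TestOutliers:
    def test_threshold_is_min_of_top_fraction(self):
        vals = [0.001 * i for i in range(1, 1001)]
        assert selscan.outlier_threshold(vals) == pytest.approx(1.0)

    def test_degenerate_equal_values_flagged(self):
        with pytest.warns(UserWarning, match="degenerate"):
            thr = selscan.outlier_threshold([0.4] * 2000)
        assert thr == 0.4

    def test_small_n_uses_single_top_window(self):
        assert selscan.outlier_threshold([0.1, 0.5, 0.3, 0.2, 0.4]) == 0.5

    def test_merge_overlapping_windows(self):
        w1 = _window(start=8_300_000, end=8_400_000)
        w2 = _window(start=8_350_000, end=8_450_000, fst=0.9)
        (r,) = selscan.merge_outliers([w1, w2])
        assert (r.start, r.end) == (8_300_000, 8_450_000)
        assert r.peak_fst == 0.9 and r.n_windows == 2

    def test_disjoint_chromosomes_stay_separate(self):
        rs = selscan.merge_outliers([_window(chrom="1"), _window(chrom="2")])
        assert len(rs) == 2

    def test_chain_of_step_adjacent_windows_merges_to_400kb(self):
        start0 = 8_260_000
        chain = [_window(start=start0 + 10_000 * i,
                         end=start0 + 10_000 * i + 100_000)
                 for i in range(31)]
        (r,) = selscan.merge_outliers(chain)
        assert r.end - r.start == 400_000
        assert r.n_windows == 31

    def test_top_region_prefers_peak_then_size(self):
        small = selscan.OutlierRegion("1", 0, 100, peak_fst=1.0, n_windows=1)
        big = selscan.OutlierRegion("2", 0, 500, peak_fst=1.0, n_windows=5)
        weak = selscan.OutlierRegion("3", 0, 900, peak_fst=0.8, n_windows=9)
        assert selscan.top_outlier_region([small, big, weak]) is big


class TestOppositeHomozygotes:
    def test_fixed_difference_qualifies(self):
        a = make_matrix([[0], [0], [0]])
        b = make_matrix([[2], [2], [2]])
        (hit,) = selscan.opposite_homozygotes(a, b)
        assert hit.allele_a == "A" and hit.allele_b == "G"

    def test_one_heterozygote_disqualifies(self):
        a = make_matrix([[0], [1], [0]])
        b = make_matrix([[2], [2], [2]])
        assert selscan.opposite_homozygotes(a, b) == []

    def test_missing_call_disqualifies_unless_relaxed(self):
        a = make_matrix([[0], [MISSING], [0]])
        b = make_matrix([[2], [2], [2]])
        assert selscan.opposite_homozygotes(a, b) == []
        assert len(selscan.opposite_homozygotes(a, b,
                                                require_complete=False)) == 1

    def test_matches_brute_force_enumeration(self, rng):
        ca = rng.integers(-1, 3, size=(3, 60)).astype(np.int8)
        cb = rng.integers(-1, 3, size=(3, 60)).astype(np.int8)
        ma, mb = make_matrix(ca), make_matrix(cb)
        hits = {h.site.pos for h in selscan.opposite_homozygotes(ma, mb)}
        expected = set()
        for j in range(60):
            va, vb = set(ca[:, j].tolist()), set(cb[:, j].tolist())
            if (va == {0} and vb == {2}) or (va == {2} and vb == {0}):
                expected.add(ma.sites[j].pos)
        assert hits == expected

    def test_sweep_makes_causal_chromosome_top_count(self, tiny_config):
        a, b = simdata.simulate_divergent_panels(tiny_config)
        hits = selscan.opposite_homozygotes(a, b)
        counts = selscan.opposite_homozygote_counts(hits, vtype="SNP")
        counts_all = selscan.opposite_homozygote_counts(hits)
        assert max(counts_all, key=counts_all.get) == tiny_config.causal_chrom
        assert counts.get("2", 0) <= counts_all.get("2", 0)


class TestChromDensity:
    def test_density_ranking(self):
        df = selscan.chrom_density({"1": 100, "2": 100},
                                   {"1": 20_000_000, "2": 10_000_000})
        assert list(df["chrom"]) == ["2", "1"]
        assert df["density_per_mb"].tolist() == [10.0, 5.0]

    def test_zero_counts_fill_in(self):
        df = selscan.chrom_density({}, {"1": 1_000_000})
        assert df["count"].tolist() == [0]
        assert df["density_per_mb"].tolist() == [0.0]

    def test_missing_length_rejected(self):
        with pytest.raises(ValueError, match="no length"):
            selscan.chrom_density({"5": 3}, {"1": 1_000_000})
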