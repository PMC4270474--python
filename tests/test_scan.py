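"""LOD scans, permutation thresholds, and peak calling."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kruskal

import doseqtl as dq
from doseqtl.errors import InvalidParameterError
from doseqtl.scan import expected_genotype_codes


def _two_group_matrix(g_column, marker_map=None):
    """Wrap one +/-1 column as a single-marker genotype matrix."""
    g = np.asarray(g_column, dtype=np.int8)[:, None]
    mm = marker_map or dq.MarkerMap(
        chromosome=np.array(["c1"], dtype=object),
        position_cM=np.array([0.0]),
        marker=np.array(["m1"], dtype=object),
    )
    strains = np.array([f"s{i}" for i in range(len(g))], dtype=object)
    return dq.GenotypeMatrix(codes=g, markers=mm, strains=strains)


class TestHkScan:
    def test_hand_computed_two_group_lod(self):
        # groups (+1 x4, -1 x4), y = (2,2,1,1, 1,1,0,0):
        # RSS0 = 4, RSS1 = 2, LOD = 4 * log10(2) = 1.20412
        gm = _two_group_matrix([1, 1, 1, 1, -1, -1, -1, -1])
        y = np.array([2.0, 2, 1, 1, 1, 1, 0, 0])
        res = dq.hk_lod_scan(gm, y)
        assert res.lod[0] == pytest.approx(4 * np.log10(2.0), abs=1e-12)

    def test_constant_phenotype_gives_zero_scan(self, small_panel):
        res = dq.hk_lod_scan(small_panel, np.ones(small_panel.n_strains))
        assert np.all(res.lod == 0) and res.constant_phenotype

    def test_affine_invariance(self, small_panel):
        rng = np.random.default_rng(1)
        y = rng.normal(size=small_panel.n_strains)
        a = dq.hk_lod_scan(small_panel, y)
        b = dq.hk_lod_scan(small_panel, 3.0 * y + 7.0)
        assert np.allclose(a.lod, b.lod, atol=1e-10)

    def test_matches_brute_force_regression_oracle(self):
        # per-marker least squares: LOD = -(n/2) log10(1 - R^2)
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = int(rng.integers(12, 50))
            m = int(rng.integers(2, 10))
            mm = dq.make_marker_map([10.0 * m], 10.0)
            gm = dq.simulate_genotypes(mm, n, seed=int(rng.integers(1e6)))
            y = rng.normal(size=n)
            res = dq.hk_lod_scan(gm, y)
            for j in range(gm.n_markers):
                g = gm.codes[:, j].astype(float)
                if np.ptp(g) == 0:
                    assert res.lod[j] == 0
                    continue
                X = np.column_stack([np.ones(n), g])
                beta, *_ = np.linalg.lstsq(X, y, rcond=None)
                rss1 = ((y - X @ beta) ** 2).sum()
                rss0 = ((y - y.mean()) ** 2).sum()
                assert res.lod[j] == pytest.approx(
                    (n / 2) * np.log10(rss0 / rss1), abs=1e-10
                )

    def test_perfect_fit_is_capped_and_flagged(self):
        gm = _two_group_matrix([1] * 6 + [-1] * 6)
        y = np.array([1.0] * 6 + [0.0] * 6)
        res = dq.hk_lod_scan(gm, y)
        assert res.lod[0] == 50.0 and res.capped[0]

    def test_monomorphic_marker_flagged_zero(self):
        gm = _two_group_matrix([1] * 12)
        res = dq.hk_lod_scan(gm, np.arange(12.0))
        assert res.lod[0] == 0 and res.monomorphic[0]

    def test_missing_genotypes_imputed_from_flanks(self):
        mm = dq.make_marker_map([20.0], 10.0)  # 3 markers at 0, 10, 20
        codes = np.array([[1.0, np.nan, 1.0], [-1.0, np.nan, 1.0], [np.nan, np.nan, np.nan]])
        imputed = expected_genotype_codes(codes, mm)
        r = dq.haldane_r(10.0)
        # same flanks: symmetric posterior; expectation from two-sided Markov
        same = (1 - r) ** 2 / ((1 - r) ** 2 + r**2)
        assert imputed[0, 1] == pytest.approx(2 * same - 1)
        assert imputed[1, 1] == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(imputed[2], 0.0)


class TestNpScan:
    def test_constant_phenotype_gives_zero_scan(self, small_panel):
        res = dq.np_lod_scan(small_panel, np.zeros(small_panel.n_strains))
        assert np.all(res.lod == 0) and res.constant_phenotype

    def test_complete_separation_matches_hand_computed_h(self):
        # ranks 1..10 vs 11..20: H = 12/(20*21)*(55^2/10 + 155^2/10) - 63
        gm = _two_group_matrix([-1] * 10 + [1] * 10)
        y = np.arange(1.0, 21.0)
        res = dq.np_lod_scan(gm, y)
        h = 12.0 / (20 * 21) * (55.0**2 / 10 + 155.0**2 / 10) - 3 * 21
        assert h == pytest.approx(14.285714285714286)
        assert res.lod[0] == pytest.approx(h / (2 * np.log(10)), abs=1e-12)

    def test_agrees_with_scipy_kruskal(self, small_panel):
        rng = np.random.default_rng(3)
        y = rng.normal(size=small_panel.n_strains)
        y[rng.random(len(y)) < 0.3] = 0.0  # force heavy ties
        res = dq.np_lod_scan(small_panel, y)
        for j in (0, 7, 23, 54):
            g = small_panel.codes[:, j]
            h = kruskal(y[g == 1], y[g == -1]).statistic
            assert res.lod[j] == pytest.approx(h / (2 * np.log(10)), rel=1e-10)

    def test_invariance_under_monotone_transform(self, small_panel):
        rng = np.random.default_rng(4)
        y = rng.normal(size=small_panel.n_strains)
        a = dq.np_lod_scan(small_panel, y)
        b = dq.np_lod_scan(small_panel, np.exp(2.0 * y))
        assert np.allclose(a.lod, b.lod, atol=1e-10)

    def test_zero_inflated_phenotype_scans(self, small_panel):
        rng = np.random.default_rng(5)
        y = np.clip(rng.normal(-0.3, 1.0, small_panel.n_strains), 0, None)
        assert (y == 0).mean() > 0.4
        res = dq.np_lod_scan(small_panel, y)
        assert np.all(res.lod >= 0)


class TestPermutationThreshold:
    def test_quantile_monotone_in_alpha(self, small_panel):
        rng = np.random.default_rng(6)
        y = rng.normal(size=small_panel.n_strains)
        lo = dq.permutation_threshold(
            small_panel, y, dq.ScanConfig(alpha=0.99, n_permutations=200, seed=1)
        )
        hi = dq.permutation_threshold(
            small_panel, y, dq.ScanConfig(alpha=0.01, n_permutations=200, seed=1)
        )
        assert lo <= hi

    def test_permutation_preserves_phenotype_multiset(self, small_panel):
        # the permuted maxima must come from rearrangements of y itself:
        # with a symmetric y multiset, negating y leaves the thresholds equal
        rng = np.random.default_rng(7)
        y = rng.normal(size=small_panel.n_strains)
        y_sym = np.concatenate([y[:100], -y[:100]])
        cfg = dq.ScanConfig(n_permutations=150, seed=2)
        a = dq.permutation_threshold(small_panel, y_sym, cfg)
        b = dq.permutation_threshold(small_panel, -y_sym, cfg)
        assert a == pytest.approx(b, abs=1e-10)

    def test_seeded_reproducibility(self, small_panel):
        rng = np.random.default_rng(8)
        y = rng.normal(size=small_panel.n_strains)
        cfg = dq.ScanConfig(n_permutations=120, seed=9)
        assert dq.permutation_threshold(small_panel, y, cfg) == dq.permutation_threshold(
            small_panel, y, cfg
        )

    def test_low_permutation_count_rejected(self):
        with pytest.raises(InvalidParameterError):
            dq.ScanConfig(n_permutations=50)


class TestPeakCalling:
    def _scan(self, lods, spacing=10.0):
        mm = dq.make_marker_map([spacing * (len(lods) - 1)], spacing)
        return dq.ScanResult(lod=np.asarray(lods, float), markers=mm, method="hk")

    def test_all_below_threshold_gives_no_peaks(self):
        assert dq.call_peaks(self._scan([0, 1, 2, 2.9, 1]), threshold=3.0) == []

    def test_single_peak_with_lod_drop_interval(self):
        # LOD (0,1,2,4,5,4,2,1): peak at marker 5 (40 cM), markers with
        # LOD >= 3.5 are 4..6 -> interval 30..50 cM
        peaks = dq.call_peaks(self._scan([0, 1, 2, 4, 5, 4, 2, 1]), threshold=3.0)
        assert len(peaks) == 1
        p = peaks[0]
        assert p.position_cM == 40.0 and p.lod == 5.0
        assert (p.ci_left_cM, p.ci_right_cM) == (30.0, 50.0)

    def test_peak_at_chromosome_start_truncates_interval(self):
        peaks = dq.call_peaks(self._scan([6, 5, 4, 2, 1]), threshold=3.0)
        assert len(peaks) == 1
        assert peaks[0].ci_left_cM == 0.0 and peaks[0].position_cM == 0.0

    def test_shallow_valley_merges_maxima(self):
        # valley 4.0 between maxima 5 and 4.8: 4.8 - 4.0 < 1.5 -> one peak
        peaks = dq.call_peaks(self._scan([0, 5, 4.0, 4.8, 0.5]), threshold=3.0)
        assert len(peaks) == 1 and peaks[0].lod == 5.0

    def test_deep_valley_keeps_maxima_distinct(self):
        # valley 3.0 between maxima 5 and 4.8: 4.8 - 3.0 >= 1.5 -> two peaks
        peaks = dq.call_peaks(self._scan([0, 5, 3.0, 4.8, 0.5]), threshold=3.0)
        assert len(peaks) == 2

    def test_effective_threshold_is_max_of_cutoff_and_permutation(self):
        scan = self._scan([0, 3.5, 0, 0, 0])
        assert len(dq.call_peaks(scan, threshold=0.0)) == 1  # cutoff 3 governs
        assert dq.call_peaks(scan, threshold=4.0) == []  # permutation governs

    def test_planted_qtl_recovered_inside_interval(self, small_panel):
        arch = dq.QTLArchitecture(
            additive=(dq.AdditiveQTL(16, {40.0: 0.6}),),  # chrom 2, 25 cM
            replicate_sd=0.5, baseline={40.0: 3.0},
        )
        hits = 0
        for seed in range(10):
            gm = dq.simulate_genotypes(small_panel.markers, 300, seed=100 + seed)
            y = dq.strain_genetic_values(gm, arch, 40.0) + np.random.default_rng(
                seed
            ).normal(0, 0.5, 300)
            peaks = dq.call_peaks(dq.hk_lod_scan(gm, y), threshold=3.0)
            chrom = str(gm.markers.chromosome[16])
            pos = float(gm.markers.position_cM[16])
            hits += any(p.contains(chrom, pos) for p in peaks)
        assert hits >= 9
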