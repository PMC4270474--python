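"""Synthetic cross generator: map construction, segregation, phenotype model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import doseqtl as dq
from doseqtl.errors import InvalidParameterError, ShapeMismatchError


class TestMarkerMap:
    def test_degenerate_chromosome_has_single_marker_at_zero(self):
        mm = dq.make_marker_map([0.0], spacing_cM=5.0)
        assert len(mm) == 1
        assert mm.position_cM[0] == 0.0

    def test_study_grid_has_51_markers_per_chromosome(self):
        # 0..100 cM in 2 cM steps is 51 grid points; 16 chromosomes -> 816
        mm = dq.make_marker_map([100.0] * 16, 2.0)
        assert len(mm) == 816
        first = mm.position_cM[mm.chromosome == mm.chromosomes()[0]]
        assert len(first) == 51

    def test_chromosome_end_is_always_a_marker(self):
        mm = dq.make_marker_map([5.0], spacing_cM=10.0)
        assert list(mm.position_cM) == [0.0, 5.0]

    @pytest.mark.parametrize("bad", [{"spacing_cM": 0.0}, {"spacing_cM": -1.0}])
    def test_non_positive_spacing_rejected(self, bad):
        with pytest.raises(InvalidParameterError):
            dq.make_marker_map([10.0], **bad)

    def test_negative_length_rejected(self):
        with pytest.raises(InvalidParameterError):
            dq.make_marker_map([-1.0], spacing_cM=1.0)

    @given(
        lengths=st.lists(st.floats(0, 300), min_size=1, max_size=8),
        spacing=st.floats(0.5, 50),
    )
    @settings(max_examples=50, deadline=None)
    def test_positions_monotone_and_ids_unique(self, lengths, spacing):
        mm = dq.make_marker_map(lengths, spacing)
        assert len(set(mm.marker)) == len(mm)
        for c in mm.chromosomes():
            pos = mm.position_cM[mm.chromosome == c]
            assert np.all(np.diff(pos) >= 0)
            assert pos[-1] == pytest.approx(
                lengths[mm.chromosomes().index(c)], abs=1e-9
            )


class TestGenotypeSimulation:
    def test_zero_distance_markers_always_cosegregate(self):
        mm = dq.MarkerMap(
            chromosome=np.array(["c1", "c1"], dtype=object),
            position_cM=np.array([10.0, 10.0]),
            marker=np.array(["a", "b"], dtype=object),
        )
        gm = dq.simulate_genotypes(mm, 500, seed=3)
        assert (gm.codes[:, 0] == gm.codes[:, 1]).all()

    def test_switch_rate_matches_haldane_at_10_cM(self):
        # r = (1 - e^{-0.2})/2 = 0.090634...
        mm = dq.make_marker_map([10.0], 10.0)
        gm = dq.simulate_genotypes(mm, 20_000, seed=4)
        switch = (gm.codes[:, 0] != gm.codes[:, 1]).mean()
        r = dq.haldane_r(10.0)
        assert r == pytest.approx(0.09063462, abs=1e-8)
        tol = 3 * np.sqrt(r * (1 - r) / 20_000)
        assert abs(switch - r) < tol

    def test_allele_frequency_is_mendelian(self):
        mm = dq.make_marker_map([20.0] * 2, 10.0)
        gm = dq.simulate_genotypes(mm, 10_000, seed=5)
        freq_plus = (gm.codes == 1).mean(axis=0)
        tol = 3 * 0.5 / np.sqrt(10_000)
        assert np.all(np.abs(freq_plus - 0.5) < tol)

    def test_linkage_decays_with_distance(self, small_panel):
        # empirical inter-marker correlation tracks 1 - 2r under Haldane
        gm = dq.simulate_genotypes(small_panel.markers, 5000, seed=6)
        sl = gm.markers.chromosome_slices()[gm.markers.chromosomes()[0]]
        block = gm.codes[:, sl].astype(float)
        pos = gm.markers.position_cM[sl]
        corr = np.corrcoef(block, rowvar=False)[0]
        expected = 1 - 2 * dq.haldane_r(pos - pos[0])
        assert np.all(np.abs(corr - expected) < 0.05)

    def test_seed_determinism(self, small_map):
        a = dq.simulate_genotypes(small_map, 50, seed=9)
        b = dq.simulate_genotypes(small_map, 50, seed=9)
        assert (a.codes == b.codes).all()

    def test_invalid_segregant_count_rejected(self, small_map):
        with pytest.raises(InvalidParameterError):
            dq.simulate_genotypes(small_map, 0, seed=1)


class TestPhenotypeSimulation:
    def test_noise_free_null_architecture_is_constant(self, small_panel):
        arch = dq.QTLArchitecture(baseline={40.0: 2.5})
        tab = dq.simulate_phenotypes(small_panel, arch, 40.0, 3, seed=1)
        assert np.allclose(tab["radius"], 2.5)

    def test_single_qtl_group_gap_is_twice_beta(self, small_panel):
        arch = dq.QTLArchitecture(
            additive=(dq.AdditiveQTL(0, {40.0: 1.0}),), baseline={40.0: 5.0}
        )
        tab = dq.simulate_phenotypes(small_panel, arch, 40.0, 1, seed=1)
        means = tab.groupby(
            small_panel.codes[:, 0][
                tab["strain"].map(
                    {s: i for i, s in enumerate(small_panel.strains)}
                ).to_numpy()
            ]
        )["radius"].mean()
        assert means[1] - means[-1] == pytest.approx(2.0)

    def test_noise_free_regression_recovers_beta_exactly(self, small_panel):
        arch = dq.QTLArchitecture(
            additive=(
                dq.AdditiveQTL(2, {40.0: 0.7}),
                dq.AdditiveQTL(30, {40.0: -0.3}),
            ),
            baseline={40.0: 4.0},
        )
        y = dq.strain_genetic_values(small_panel, arch, 40.0)
        X = small_panel.codes[:, [2, 30]].astype(float)
        coef, *_ = np.linalg.lstsq(
            np.column_stack([np.ones(len(y)), X]), y, rcond=None
        )
        assert coef[1] == pytest.approx(0.7, abs=1e-12)
        assert coef[2] == pytest.approx(-0.3, abs=1e-12)

    def test_strain_mean_variance_matches_architecture(self):
        # independent +/-1 loci: Var = sum(beta^2) + sum(gamma^2) + sigma_s^2
        mm = dq.make_marker_map([1.0] * 6, 2.0)  # 6 unlinked single-marker chroms
        gm = dq.simulate_genotypes(mm, 40_000, seed=7)
        arch = dq.QTLArchitecture(
            additive=(dq.AdditiveQTL(0, {40.0: 0.8}), dq.AdditiveQTL(2, {40.0: 0.5})),
            epistatic=(dq.EpistaticPair(4, 6, {40.0: 0.4}),),
            strain_sd=0.3,
            baseline={40.0: 50.0},  # far from the clamp at 0
        )
        tab = dq.simulate_phenotypes(gm, arch, 40.0, 1, seed=8)
        expected = 0.8**2 + 0.5**2 + 0.4**2 + 0.3**2
        assert tab["radius"].var() == pytest.approx(expected, rel=0.05)

    def test_radii_clamped_at_zero(self, small_panel):
        arch = dq.QTLArchitecture(baseline={200.0: 0.1}, replicate_sd=1.0)
        tab = dq.simulate_phenotypes(small_panel, arch, 200.0, 4, seed=2)
        assert (tab["radius"] >= 0).all()
        assert (tab["radius"] == 0).any()

    def test_seed_determinism_and_unique_keys(self, small_panel, study_architecture=None):
        arch = dq.QTLArchitecture(baseline={40.0: 3.0}, replicate_sd=0.2)
        a = dq.simulate_phenotypes(small_panel, arch, 40.0, 4, seed=5)
        b = dq.simulate_phenotypes(small_panel, arch, 40.0, 4, seed=5)
        assert a.equals(b)
        assert not a.duplicated(["strain", "dose_uM", "replicate", "layout"]).any()

    def test_architecture_index_validation(self, small_panel):
        arch = dq.QTLArchitecture(additive=(dq.AdditiveQTL(999, {40.0: 1.0}),))
        with pytest.raises(ShapeMismatchError):
            dq.simulate_phenotypes(small_panel, arch, 40.0, 1, seed=1)


class TestParentPanel:
    def test_sign_convention_by_parent_grows_better(self):
        arch = dq.QTLArchitecture(
            additive=(dq.AdditiveQTL(0, {40.0: 1.0}),), baseline={40.0: 5.0}
        )
        tab = dq.simulate_parent_panel(arch, 40.0, 4, seed=1)
        means = tab.groupby("strain")["radius"].mean()
        assert means["BY"] > means["RM"]

    def test_opposing_loci_leave_parents_equal_but_segregants_spread(self):
        arch = dq.QTLArchitecture(
            additive=(dq.AdditiveQTL(0, {40.0: 1.0}), dq.AdditiveQTL(1, {40.0: -1.0})),
            baseline={40.0: 5.0},
        )
        tab = dq.simulate_parent_panel(arch, 40.0, 2, seed=1, n_markers=2)
        means = tab.groupby("strain")["radius"].mean()
        assert means["BY"] == pytest.approx(means["RM"])
        # segregant genotypes (+1,-1) and (-1,+1) reach 5 +/- 2
        vals = [
            dq.strain_genetic_values(np.array([[+1, -1]]), arch, 40.0)[0],
            dq.strain_genetic_values(np.array([[-1, +1]]), arch, 40.0)[0],
        ]
        assert sorted(vals) == [3.0, 7.0]

    def test_parent_replicate_count(self):
        arch = dq.QTLArchitecture(baseline={40.0: 5.0}, replicate_sd=0.1)
        tab = dq.simulate_parent_panel(arch, 40.0, 48, seed=1)
        assert (tab.groupby("strain").size() == 48).all()
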