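"""Effect sizes, additive variance models, and the epistasis scan."""

import numpy as np
import pandas as pd
import pytest

import doseqtl as dq
from doseqtl.errors import CollinearityError, DegenerateLocusError


class TestEffectSize:
    def test_balanced_groups_effect_is_half_the_mean_gap(self):
        g = np.array([1.0] * 5 + [-1.0] * 5)
        y = np.array([1.0] * 5 + [0.0] * 5)
        est = dq.locus_effect_size(y, g)
        assert est.effect == pytest.approx(0.5, abs=1e-12)

    def test_constant_phenotype_has_zero_effect(self):
        g = np.array([1.0, -1, 1, -1, 1, -1])
        est = dq.locus_effect_size(np.ones(6), g)
        assert est.effect == 0.0

    def test_unbalanced_groups_match_normal_equation_oracle(self):
        rng = np.random.default_rng(12)
        g = np.array([1.0] * 6 + [-1.0] * 4)
        y = rng.normal(size=10)
        est = dq.locus_effect_size(y, g)
        # 2x2 normal equations solved directly
        A = np.array([[10.0, g.sum()], [g.sum(), (g**2).sum()]])
        b = np.array([y.sum(), g @ y])
        slope = np.linalg.solve(A, b)[1]
        assert est.effect == pytest.approx(slope, abs=1e-12)
        # SE cross-check against the closed-form regression formula
        resid = y - y.mean() - est.effect * (g - g.mean())
        sxx = ((g - g.mean()) ** 2).sum()
        assert est.se == pytest.approx(np.sqrt(resid @ resid / 8 / sxx), abs=1e-12)

    def test_monomorphic_locus_rejected(self):
        with pytest.raises(DegenerateLocusError):
            dq.locus_effect_size(np.arange(6.0), np.ones(6))

    def test_sign_convention_by_beneficial_allele_positive(self, small_panel):
        arch = dq.QTLArchitecture(
            additive=(dq.AdditiveQTL(4, {40.0: 0.4}),), baseline={40.0: 3.0}
        )
        y = dq.strain_genetic_values(small_panel, arch, 40.0)
        est = dq.locus_effect_size(y, small_panel.column(4))
        assert est.effect == pytest.approx(0.4, abs=1e-12)


class TestAdditiveModel:
    def test_single_locus_r2_is_squared_correlation(self, small_panel):
        rng = np.random.default_rng(13)
        g = small_panel.column(10)
        y = 0.5 * g + rng.normal(0, 1, len(g))
        fit = dq.additive_model(y, pd.DataFrame({"L1": g}))
        assert fit.r_squared == pytest.approx(np.corrcoef(y, g)[0, 1] ** 2, abs=1e-12)

    def test_adding_a_locus_never_decreases_r2(self, small_panel):
        rng = np.random.default_rng(14)
        y = rng.normal(size=small_panel.n_strains)
        one = dq.additive_model(y, pd.DataFrame({"a": small_panel.column(0)}))
        two = dq.additive_model(
            y, pd.DataFrame({"a": small_panel.column(0), "b": small_panel.column(30)})
        )
        assert two.r_squared >= one.r_squared - 1e-12

    def test_three_planted_loci_r2_matches_variance_algebra(self):
        # beta = (1, 0.5, 0.25), sigma_e = 1: R^2 = 1.3125 / 2.3125
        mm = dq.make_marker_map([1.0] * 3, 2.0)
        gm = dq.simulate_genotypes(mm, 1008, seed=15)
        arch = dq.QTLArchitecture(
            additive=tuple(
                dq.AdditiveQTL(j, {40.0: b}) for j, b in zip((0, 2, 4), (1.0, 0.5, 0.25))
            ),
            baseline={40.0: 0.0},
        )
        rng = np.random.default_rng(16)
        y = dq.strain_genetic_values(gm, arch, 40.0) + rng.normal(0, 1, 1008)
        fit = dq.additive_model(
            y, pd.DataFrame({f"L{j}": gm.column(j) for j in (0, 2, 4)})
        )
        assert fit.r_squared == pytest.approx(1.3125 / 2.3125, abs=0.05)
        # drop-one R^2 losses reflect each locus's share
        drop = fit.drop_one.set_index("locus")["delta_r2"]
        assert drop["L0"] > drop["L2"] > drop["L4"] > 0

    def test_perfectly_linked_loci_raise_collinearity(self, small_panel):
        g = small_panel.column(0)
        with pytest.raises(CollinearityError) as exc:
            dq.additive_model(
                np.arange(small_panel.n_strains, dtype=float),
                pd.DataFrame({"a": g, "b": g}),
            )
        assert {"a", "b"} <= set(exc.value.columns)


class TestInteractionScan:
    def test_nine_loci_give_36_pairs(self, study_panel):
        rng = np.random.default_rng(17)
        idx = [10, 70, 130, 190, 250, 310, 370, 430, 490]
        design = pd.DataFrame({f"L{j}": study_panel.column(j) for j in idx})
        y = rng.normal(size=study_panel.n_strains)
        res = dq.interaction_scan(y, design)
        assert res.n_pairs == 36
        assert len(res.pairs) == 36

    def test_purely_additive_noise_free_has_no_significant_pairs(self, small_panel):
        arch = dq.QTLArchitecture(
            additive=(dq.AdditiveQTL(0, {40.0: 1.0}), dq.AdditiveQTL(22, {40.0: 0.5})),
            baseline={40.0: 5.0},
        )
        y = dq.strain_genetic_values(small_panel, arch, 40.0)
        design = pd.DataFrame({"a": small_panel.column(0), "b": small_panel.column(22)})
        res = dq.interaction_scan(y, design)
        assert res.n_significant == 0
        assert res.delta_var == 0.0

    def test_planted_pair_detected_with_power(self):
        # gamma = 0.5, sigma_e = 1, n = 1008: expected t ~ 16, always found
        mm = dq.make_marker_map([1.0] * 3, 2.0)
        hits = 0
        for seed in range(10):
            gm = dq.simulate_genotypes(mm, 1008, seed=200 + seed)
            arch = dq.QTLArchitecture(
                additive=(dq.AdditiveQTL(0, {40.0: 0.5}), dq.AdditiveQTL(2, {40.0: 0.3})),
                epistatic=(dq.EpistaticPair(0, 2, {40.0: 0.5}),),
                baseline={40.0: 0.0},
            )
            rng = np.random.default_rng(300 + seed)
            y = dq.strain_genetic_values(gm, arch, 40.0) + rng.normal(0, 1, 1008)
            design = pd.DataFrame({"a": gm.column(0), "b": gm.column(2)})
            res = dq.interaction_scan(y, design, corrected_alpha=0.005)
            row = res.pairs.iloc[0]
            hits += bool(row["significant"]) and res.delta_var > 0
        assert hits >= 9

    def test_delta_var_never_negative_and_nested_r2(self, small_panel):
        rng = np.random.default_rng(18)
        y = rng.normal(size=small_panel.n_strains)
        design = pd.DataFrame(
            {f"L{j}": small_panel.column(j) for j in (0, 11, 22, 33)}
        )
        res = dq.interaction_scan(y, design, corrected_alpha=0.5)
        assert res.delta_var >= 0
        assert res.r2_with_interactions >= res.r2_additive

    def test_type_i_familywise_control_on_additive_simulations(self, small_panel):
        # no epistasis: any corrected-significant pair at 0.05 is an error
        false_hits = 0
        runs = 40
        for seed in range(runs):
            rng = np.random.default_rng(400 + seed)
            g1, g2, g3 = (small_panel.column(j) for j in (0, 22, 44))
            y = 0.5 * g1 + 0.3 * g2 + rng.normal(0, 1, small_panel.n_strains)
            res = dq.interaction_scan(
                y, pd.DataFrame({"a": g1, "b": g2, "c": g3}), corrected_alpha=0.05
            )
            false_hits += res.n_significant > 0
        assert false_hits / runs <= 0.10
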