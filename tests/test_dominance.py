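import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wingcpm import (
    ColourPattern,
    correlate_h_distance,
    dominance_coefficient,
    dominance_heatmap,
    permutation_test_mean_difference,
    trait_T,
)
from wingcpm.dominance import (
    DominanceModel,
    PairObservations,
    colour_expression_probability,
    colour_hierarchy_map,
    full_dominance_conformity,
    hierarchy_conformity,
)
from wingcpm.io import CLASSES

B, O, Y = (CLASSES.index(c) for c in ("black", "orange", "yellow"))


def _grids_for_trait(informative_frac=0.4, n=10):
    """modal_a / modal_b differing on the first ``informative_frac`` of a
    1 x n wing strip."""
    k = int(informative_frac * n)
    ma = np.full((1, n), B, np.int16)
    mb = np.full((1, n), B, np.int16)
    mb[0, :k] = Y
    return ma, mb, k


class TestTraitT:
    def test_individual_equal_to_modal_a(self):
        ma, mb, k = _grids_for_trait(0.4)
        t, neither = trait_T(ma, ma, mb)
        assert t == pytest.approx(0.4)
        assert neither == 0.0

    def test_individual_equal_to_modal_b(self):
        ma, mb, _ = _grids_for_trait(0.4)
        assert trait_T(mb, ma, mb)[0] == 0.0

    def test_half_and_half_on_informative_pixels(self):
        ma, mb, k = _grids_for_trait(0.4, n=10)
        ind = mb.copy()
        ind[0, : k // 2] = ma[0, : k // 2]
        assert trait_T(ind, ma, mb)[0] == pytest.approx(0.2)

    def test_neither_fraction_reported(self):
        ma, mb, k = _grids_for_trait(0.4, n=10)
        ind = ma.copy()
        ind[0, :2] = O  # matches neither modal there
        t, neither = trait_T(ind, ma, mb)
        assert neither == pytest.approx(0.2)

    def test_empty_surface_raises(self):
        z = np.zeros((2, 2), np.int16)
        with pytest.raises(ValueError, match="empty wing surface"):
            trait_T(z, z, z)


class TestDominanceCoefficient:
    def test_complete_dominance(self):
        r = dominance_coefficient([0.8], [0.8], [0.2], pair=("a", "b"))
        assert r.h_raw == pytest.approx(1.0)
        assert r.h == pytest.approx(1.0)
        assert r.dominant_allele == "a"

    def test_midpoint_is_codominance(self):
        r = dominance_coefficient([0.8], [0.5], [0.2])
        assert r.h_raw == pytest.approx(0.5)
        assert r.h == pytest.approx(0.5)

    def test_normalization_flips_direction(self):
        r = dominance_coefficient([0.8], [0.35], [0.2], pair=("a", "b"))
        assert r.h_raw == pytest.approx(0.25)
        assert r.h == pytest.approx(0.75)
        assert r.dominant_allele == "b"

    def test_uninformative_pair_raises(self):
        with pytest.raises(ValueError, match="uninformative"):
            dominance_coefficient([0.5], [0.5], [0.5])

    def test_out_of_range_h_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            r = dominance_coefficient([0.8], [0.95], [0.2])
        assert r.h == 1.0 and r.clipped

    @settings(max_examples=200, deadline=None)
    @given(st.tuples(st.floats(0, 1), st.floats(0, 1), st.floats(0, 1)))
    def test_normalized_h_always_in_half_one(self, triple):
        t_aa, t_ab, t_bb = triple
        if abs(t_aa - t_bb) < 1e-6:
            return
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = dominance_coefficient([t_aa], [t_ab], [t_bb])
        assert 0.5 <= r.h <= 1.0


class TestHeatmap:
    def test_pixel_category_proportions(self):
        md = np.full((1, 1), B, np.int16)
        mr = np.full((1, 1), Y, np.int16)
        hets = [np.full((1, 1), B, np.int16)] * 7 + \
               [np.full((1, 1), O, np.int16)] * 1 + \
               [np.full((1, 1), Y, np.int16)] * 2
        hm = dominance_heatmap(hets, md, mr)
        np.testing.assert_allclose(hm.props[:, 0, 0], [0.7, 0.2, 0.0, 0.1])

    def test_matching_both_where_modals_agree(self):
        md = np.full((1, 1), B, np.int16)
        hm = dominance_heatmap([md, md], md, md.copy())
        np.testing.assert_allclose(hm.props[:, 0, 0], [0, 0, 1, 0])

    def test_proportions_sum_to_one_on_synthetic_run(self, small_dataset):
        ds = small_dataset
        hets = [ds.truths[r.specimen_id].grid for r in ds.records
                if r.genotype == ("arc", "tar")]
        ma = ds.config.alleles["arc"].rasterize(96)
        mb = ds.config.alleles["tar"].rasterize(96)
        hm = dominance_heatmap(hets, ma, mb)
        sums = hm.props.sum(axis=0)[hm.valid]
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)
        img = hm.render()
        assert img.shape == (96, 96, 3)


def _pair_obs(het_grids, ma, mb, pair=("a", "b"), pair_class="NA"):
    return PairObservations(pair=pair, het_patterns=list(het_grids),
                            modal_a=ma, modal_b=mb, pair_class=pair_class)


class TestHierarchyStats:
    def test_hierarchy_map_pure_dominant_colour(self):
        ma = np.full((1, 4), O, np.int16)
        mb = np.full((1, 4), Y, np.int16)
        hets = [ma.copy()] * 3  # orange expressed everywhere
        chm = colour_hierarchy_map([_pair_obs(hets, ma, mb)], ("orange", "yellow"))
        assert chm.summary["orange"] == 1.0
        assert chm.summary["yellow"] == 0.0
        sums = chm.props.sum(axis=0)[chm.n_obs > 0]
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_hierarchy_map_empty_for_absent_colour_pair(self):
        ma = np.full((1, 4), O, np.int16)
        mb = np.full((1, 4), Y, np.int16)
        with pytest.warns(UserWarning, match="empty"):
            chm = colour_hierarchy_map([_pair_obs([ma], ma, mb)], ("black", "yellow"))
        assert chm.empty

    def test_conformity_one_for_hierarchy_generated(self):
        ma = np.full((1, 6), B, np.int16)
        mb = np.full((1, 6), Y, np.int16)
        hets = [np.full((1, 6), B, np.int16)] * 4  # black wins everywhere
        assert hierarchy_conformity([_pair_obs(hets, ma, mb)]) == 1.0

    def test_conformity_estimates_bernoulli_rate(self, rng):
        """Hets conforming with per-pixel probability 0.79 estimate 0.79."""
        n = 200
        ma = np.full((1, n), B, np.int16)
        mb = np.full((1, n), Y, np.int16)
        hets = []
        for _ in range(60):
            h = np.where(rng.random((1, n)) < 0.79, B, Y).astype(np.int16)
            hets.append(h)
        est = hierarchy_conformity([_pair_obs(hets, ma, mb)])
        assert est == pytest.approx(0.79, abs=0.02)

    def test_full_dominance_conformity_direction_symmetry(self):
        ma = np.full((1, 5), B, np.int16)
        mb = np.full((1, 5), Y, np.int16)
        frac, allele = full_dominance_conformity([mb.copy()] * 3, ma, mb, ("a", "b"))
        assert frac == 1.0 and allele == "b"
        frac, allele = full_dominance_conformity([ma.copy()] * 3, ma, mb, ("a", "b"))
        assert frac == 1.0 and allele == "a"

    def test_colour_expression_probability_matches_construction(self, rng):
        """A mechanism emitting orange at rate q on black/yellow disagreement
        pixels yields P(orange) = q."""
        n, q = 400, 0.21
        ma = np.full((1, n), B, np.int16)
        mb = np.full((1, n), Y, np.int16)
        hets = []
        for _ in range(50):
            h = np.where(rng.random((1, n)) < q, O, B).astype(np.int16)
            hets.append(h)
        probs = colour_expression_probability([_pair_obs(hets, ma, mb)],
                                              ("black", "yellow"))
        assert probs["orange"] == pytest.approx(q, abs=0.02)
        assert probs["black"] == pytest.approx(1 - q, abs=0.02)


class TestPermutation:
    def test_identical_groups_give_p_one(self):
        obs, p = permutation_test_mean_difference([1, 1, 1, 1], ["a", "a", "b", "b"])
        assert obs == 0.0 and p == 1.0

    def test_three_vs_three_matches_enumeration(self):
        values = [1.0, 1.0, 1.0, 0.0, 0.0, 0.0]
        labels = ["x"] * 3 + ["y"] * 3
        obs, p = permutation_test_mean_difference(values, labels, n_perm=999)
        # exhaustive oracle over all C(6,3) assignments
        vals = np.array(values)
        hits = 0
        combos = list(itertools.combinations(range(6), 3))
        for idx in combos:
            sel = np.zeros(6, bool)
            sel[list(idx)] = True
            if abs(vals[sel].mean() - vals[~sel].mean()) >= abs(obs) - 1e-12:
                hits += 1
        assert p == pytest.approx(hits / len(combos))
        assert p == pytest.approx(2 / 20)

    @pytest.mark.parametrize("n1,n2", [(4, 4), (3, 5), (2, 6)])
    def test_random_values_match_enumeration(self, rng, n1, n2):
        values = rng.standard_normal(n1 + n2)
        labels = ["a"] * n1 + ["b"] * n2
        obs, p = permutation_test_mean_difference(values, labels)
        vals = np.asarray(values)
        combos = list(itertools.combinations(range(n1 + n2), n1))
        hits = sum(
            abs(vals[list(i)].mean() - np.delete(vals, list(i)).mean())
            >= abs(obs) - 1e-12
            for i in combos
        )
        assert p == pytest.approx(hits / len(combos))

    def test_sampled_mode_is_seed_deterministic(self, rng):
        values = rng.standard_normal(40)
        labels = ["a"] * 20 + ["b"] * 20
        r1 = permutation_test_mean_difference(values, labels, seed=3, exact=False)
        r2 = permutation_test_mean_difference(values, labels, seed=3, exact=False)
        assert r1 == r2

    def test_needs_two_groups(self):
        with pytest.raises(ValueError):
            permutation_test_mean_difference([1, 2], ["a", "a"])


class TestCorrelation:
    def test_affine_relation_gives_r_one(self):
        d = [1.0, 2.0, 3.0, 4.0]
        h = [0.5 + 0.1 * x for x in d]
        r, p = correlate_h_distance(h, d, n_perm=199, seed=0)
        assert r == pytest.approx(1.0)
        assert p < 0.1

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError, match="variance"):
            correlate_h_distance([0.7, 0.7, 0.7], [1, 2, 3])

    def test_shuffled_h_is_null(self, rng):
        d = np.arange(10.0)
        h = rng.permutation(d)
        r, p = correlate_h_distance(h, d, n_perm=199, seed=1)
        assert p > 0.01 or abs(r) > 0.6  # no false certainty on shuffled data


class TestDominanceModel:
    def test_fit_recovers_programmed_direction(self, small_dataset):
        ds = small_dataset
        pats = [ColourPattern(grid=ds.truths[r.specimen_id].grid, space="model")
                for r in ds.records]
        model = DominanceModel(pats, [r.genotype for r in ds.records])
        fit = model.fit()
        assert len(fit.results) == 1
        res = fit[("tar", "arc")]
        # on noise-free truths, h equals the mechanism's programmed dominance
        prog = ds.truth_bundle["programmed_dominance"]["arc/tar"]
        assert res.h == pytest.approx(prog["h"], abs=1e-9)
        assert res.dominant_allele == prog["dominant_allele"]
        assert "Dominance analysis" in fit.summary()
        assert set(fit.table.columns) >= {"pair", "h", "h_raw", "dominant"}

    def test_bootstrap_reports_uncertainty(self, small_dataset, rng):
        ds = small_dataset
        from wingcpm import categorize, extract_outline

        pats = []
        for r in ds.records:
            img = ds.images[r.specimen_id]
            pat, _ = categorize(img, extract_outline(img))
            pats.append(ColourPattern(grid=pat.grid, space="model"))
        fit = DominanceModel(pats, [r.genotype for r in ds.records]).fit(
            n_boot=50, seed=2)
        res = fit.results[0]
        assert np.isfinite(res.h_se)
        assert res.h_ci[0] <= res.h_ci[1]
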