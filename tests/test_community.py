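import numpy as np
import pytest
from scipy import stats

from fragdiv.community import (
    Beta4Params,
    CommunityConfig,
    Landscape,
    Metacommunity,
    assign_individuals,
    assignment_probs,
    draw_area_responses,
    draw_patch_areas,
    simulate_community,
    simulate_metacommunity,
)


class TestBeta4Params:
    def test_rejects_bad_shapes(self):
        with pytest.raises(ValueError):
            Beta4Params(alpha=0, beta=4, min=25, max=20000)
        with pytest.raises(ValueError):
            Beta4Params(alpha=1, beta=4, min=25, max=25)


class TestDrawPatchAreas:
    def test_two_patches_are_the_endpoints(self, rng):
        areas = draw_patch_areas(2, rng=rng)
        assert areas.tolist() == [25.0, 20000.0]

    def test_default_bounds_and_endpoints(self, rng):
        areas = draw_patch_areas(25, rng=rng)
        assert areas.size == 25
        assert areas.min() == 25.0
        assert areas.max() == 20000.0
        assert np.all(np.diff(areas) >= 0)
        assert np.all((areas >= 25.0) & (areas <= 20000.0))

    def test_rejects_single_patch(self, rng):
        with pytest.raises(ValueError):
            draw_patch_areas(1, rng=rng)

    def test_free_draw_mean_matches_analytic(self, rng):
        # analytic oracle: E[Beta(1,4)] = 1/5, so free areas average
        # 25 + 19975/5 = 4020
        expected = 25 + (20000 - 25) * stats.beta.mean(1, 4)
        areas = draw_patch_areas(20_002, rng=rng)
        free = np.sort(areas)[1:-1]  # endpoints are pre-assigned
        se = (20000 - 25) * stats.beta.std(1, 4) / np.sqrt(free.size)
        assert abs(free.mean() - expected) < 4 * se


class TestSimulateMetacommunity:
    def test_minimum_abundance_after_inflation(self, rng):
        meta = simulate_metacommunity(200, 100_000.0, rng=rng)
        assert meta.abundances.min() >= 500

    def test_conservation(self, rng):
        meta = simulate_metacommunity(200, 100_000.4, rng=rng)
        assert meta.total_individuals == 500 * round(100_000.4)

    def test_abundances_are_multiples_of_inflation(self, rng):
        meta = simulate_metacommunity(50, 3000.0, rng=rng)
        assert np.all(meta.abundances % 500 == 0)

    def test_degenerate_sad_equal_split(self, rng):
        meta = simulate_metacommunity(4, 8.0, sad_sdlog=0.0, rng=rng)
        assert meta.abundances.tolist() == [1000, 1000, 1000, 1000]

    def test_too_small_area_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_metacommunity(10, 5.0, rng=rng)


class TestDrawAreaResponses:
    def _meta(self, rng, n=200):
        return simulate_metacommunity(n, 100_000.0, rng=rng)

    def test_negated_count(self, rng):
        resp = draw_area_responses(self._meta(rng), alpha_max=8.0, rng=rng)
        assert (resp.beta_area < 0).sum() == 25  # round(200 / 8)
        assert resp.sign_flipped.size == 25

    def test_bounded_support(self, rng):
        resp = draw_area_responses(self._meta(rng), alpha_max=12.0, rng=rng)
        assert np.all(np.abs(resp.beta_area) <= 5.0)
        assert np.all((resp.alpha_i >= 0.1) & (resp.alpha_i <= 12.0))

    def test_alpha_decreases_with_abundance(self, rng):
        meta = self._meta(rng)
        resp = draw_area_responses(meta, alpha_max=8.0, rng=rng)
        distinct = np.unique(meta.abundances).size == meta.n_species
        rho, _ = stats.spearmanr(meta.abundances, resp.alpha_i)
        if distinct:
            assert rho == pytest.approx(-1.0)
        else:
            assert rho < -0.99

    @pytest.mark.parametrize("ramp", ["inverse", "rank"])
    def test_extreme_species_pin_the_range(self, rng, ramp):
        meta = Metacommunity(abundances=np.array([500, 5_000, 1_000_000]))
        resp = draw_area_responses(meta, alpha_max=6.0, ramp=ramp, rng=rng)
        assert resp.alpha_i[0] == pytest.approx(6.0)  # rarest
        assert resp.alpha_i[2] == pytest.approx(0.1)  # most abundant

    def test_beta_draw_mean_matches_analytic(self):
        # Monte-Carlo oracle: E[5 * Beta(a, 5)] = 5a / (a + 5) per species.
        # Equal spacing over ranks makes alpha_i deterministic.
        meta = Metacommunity(abundances=np.arange(1, 201) * 500)
        draws = []
        alpha_ref = None
        for seed in range(300):
            resp = draw_area_responses(
                meta, alpha_max=9.9, neg_fraction=0.0, ramp="rank",
                rng=np.random.default_rng(seed),
            )
            alpha_ref = resp.alpha_i
            draws.append(resp.beta_area)
        draws = np.stack(draws)
        expected = 5 * alpha_ref / (alpha_ref + 5)
        sd = 5 * np.sqrt(
            stats.beta.var(alpha_ref, 5)
        )
        se = sd / np.sqrt(draws.shape[0])
        assert np.all(np.abs(draws.mean(axis=0) - expected) < 5 * se)

    def test_alpha_max_validation(self, rng):
        with pytest.raises(ValueError):
            draw_area_responses(self._meta(rng), alpha_max=0.05, rng=rng)


class TestAssignmentProbs:
    def test_zero_beta_uniform(self):
        phi = assignment_probs(np.array([10.0, 40.0, 90.0]), 0.0)
        assert phi == pytest.approx([1 / 3] * 3)

    def test_positive_beta(self):
        phi = assignment_probs(np.array([10.0, 100.0]), 1.0)
        assert phi == pytest.approx([1 / 11, 10 / 11])

    def test_negative_beta(self):
        phi = assignment_probs(np.array([10.0, 100.0]), -1.0)
        assert phi == pytest.approx([10 / 11, 1 / 11])

    def test_sums_to_one_at_extremes(self):
        areas = np.array([25.0, 200.0, 20000.0])
        for beta in (-5.0, 5.0):
            assert assignment_probs(areas, beta).sum() == pytest.approx(1.0)

    def test_rejects_nonpositive_area(self):
        with pytest.raises(ValueError):
            assignment_probs(np.array([0.0, 10.0]), 1.0)


class TestAssignIndividuals:
    def test_conservation_exact(self, small_community):
        c = small_community
        np.testing.assert_array_equal(
            c.abundance.sum(axis=0), c.metacommunity.abundances
        )

    def test_capacity_overshoot_bounded(self, small_community):
        c = small_community
        caps = c.landscape.capacities
        totals = c.abundance.sum(axis=1)
        assert np.all(totals <= caps + c.config.group_size)

    def test_single_patch_gets_everything(self, rng):
        land = Landscape(patch_areas=np.array([40.0]))
        meta = simulate_metacommunity(5, 40.0, rng=rng)
        resp = draw_area_responses(meta, alpha_max=4.0, rng=rng)
        N = assign_individuals(meta, land, resp, rng=rng)
        np.testing.assert_array_equal(N[0], meta.abundances)

    def test_deterministic_given_seed(self):
        a = simulate_community(CommunityConfig(n_patches=5, n_species=20,
                                               area_params=Beta4Params(1, 4, 25, 300)), 3)
        b = simulate_community(CommunityConfig(n_patches=5, n_species=20,
                                               area_params=Beta4Params(1, 4, 25, 300)), 3)
        np.testing.assert_array_equal(a.abundance, b.abundance)

    def test_rejects_overfull_landscape(self, rng):
        land = Landscape(patch_areas=np.array([25.0]))
        meta = Metacommunity(abundances=np.array([50_000]))
        resp = draw_area_responses(
            Metacommunity(abundances=np.array([50_000])), alpha_max=4.0, rng=rng
        )
        with pytest.raises(ValueError):
            assign_individuals(meta, land, resp, rng=rng)


class TestFullPipeline:
    def test_default_landscape_contracts(self, default_community):
        c = default_community
        assert c.landscape.n_patches == 25
        assert c.metacommunity.n_species == 200
        assert c.landscape.patch_areas.min() == 25.0
        assert c.landscape.patch_areas.max() == 20000.0
        assert c.metacommunity.abundances.min() >= 500
        np.testing.assert_array_equal(
            c.abundance.sum(axis=0), c.metacommunity.abundances
        )


class TestSarRealism:
    """Distribution-level properties of true species-area slopes."""

    @staticmethod
    def _z(seed, alpha_max, ramp):
        from fragdiv.trends import fit_sar, richness_from_matrix

        cfg = CommunityConfig(alpha_max=alpha_max, response_ramp=ramp)
        c = simulate_community(cfg, seed)
        return fit_sar(
            richness_from_matrix(c.abundance), c.landscape.patch_areas
        ).z_value

    def test_rank_ramp_z_increases_with_alpha_max(self):
        # paired seeds: the rank ramp strengthens mid-abundance responses,
        # steepening the SAR as alpha_max grows
        z4 = [self._z(500 + s, 4.0, "rank") for s in range(12)]
        z12 = [self._z(500 + s, 12.0, "rank") for s in range(12)]
        assert np.mean(z12) > np.mean(z4)

    def test_default_z_mostly_within_published_band(self):
        zs = [
            self._z(700 + s, am, "inverse")
            for am in (4.0, 8.0, 12.0)
            for s in range(10)
        ]
        inside = np.mean([(0.137 <= z <= 0.345) for z in zs])
        assert inside > 0.5
        assert 0.137 <= np.mean(zs) <= 0.345


def test_assignment_kernel_python_numba_parity(monkeypatch, rng):
    """The accelerated and reference assignment paths are bit-identical
    (the per-group uniforms are drawn outside the kernel)."""
    from fragdiv import community as cm

    cfg = CommunityConfig(
        n_patches=6, n_species=15,
        area_params=Beta4Params(alpha=1, beta=4, min=25, max=400),
    )
    fast = simulate_community(cfg, 21)
    monkeypatch.setattr(cm, "_assign_groups", cm._assign_groups_py)
    slow = simulate_community(cfg, 21)
    np.testing.assert_array_equal(fast.abundance, slow.abundance)
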