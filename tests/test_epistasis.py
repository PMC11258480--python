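import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epistax.epistasis import (
    EpistasisAnalysis,
    EpistasisInput,
    bootstrap_epistasis,
    classify_interaction,
    fit_epistasis_slope,
    select_features,
    simulate_model_distributions,
)
from epistax.simulate import InteractionModel, simulate_effects
from tests.conftest import make_contrast


def grid_search_slope(x, delta, lo=-5.0, hi=5.0, step=1e-4):
    """Independent oracle: dense scan of the orthogonal objective.

    Returns None when the optimum sits on the grid boundary (the true slope
    lies outside the scanned range, so the scan is not a valid oracle there).
    """
    grid = np.arange(lo, hi + step / 2, step)
    resid = delta[None, :] - grid[:, None] * x[None, :]
    obj = (resid**2).sum(axis=1) / (1.0 + grid**2)
    best = int(np.argmin(obj))
    if best in (0, len(grid) - 1):
        return None
    return grid[best]


def effects_input(name, n=500, noise_sd=0.05, seed=1, effect_sd=1.0):
    model = InteractionModel.preset(name, noise_sd=noise_sd)
    eff = simulate_effects(model, n, effect_sd, seed=seed)
    return EpistasisInput(eff.feature_ids, eff.beta_a, eff.beta_b, eff.beta_ab)


class TestSlope:
    def test_points_on_axis_give_zero(self):
        assert fit_epistasis_slope(np.array([1.0, 2.0, -3.0]), np.zeros(3)) == 0.0

    def test_repressive_collinear_gives_minus_one(self):
        x = np.array([1.0, -2.0, 0.5])
        assert fit_epistasis_slope(x, -x) == pytest.approx(-1.0)

    def test_two_point_closed_form(self):
        s = fit_epistasis_slope(np.array([1.0, 2.0]), np.array([1.0, 0.0]))
        assert s == pytest.approx(np.sqrt(5) - 2, abs=1e-12)

    def test_closed_form_agrees_with_grid_oracle(self):
        rng = np.random.default_rng(123)
        checked = 0
        while checked < 100:
            n = rng.integers(2, 11)
            x = rng.normal(0, 1, n)
            delta = rng.normal(0, 1, n)
            oracle = grid_search_slope(x, delta)
            if oracle is None:  # optimum outside the scan range
                continue
            assert fit_epistasis_slope(x, delta) == pytest.approx(oracle, abs=1e-3)
            checked += 1

    def test_scale_invariance(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 50)
        delta = rng.normal(0, 1, 50)
        s = fit_epistasis_slope(x, delta)
        assert fit_epistasis_slope(3.7 * x, 3.7 * delta) == pytest.approx(s, rel=1e-9)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.integers(0, 2**31 - 1),
        st.floats(0.1, 100.0),
    )
    def test_scale_invariance_property(self, seed, scale):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, 20)
        delta = rng.normal(0, 1, 20)
        s = fit_epistasis_slope(x, delta)
        assert fit_epistasis_slope(scale * x, scale * delta) == pytest.approx(
            s, rel=1e-6, abs=1e-9
        )

    def test_all_zero_x_rejected(self):
        with pytest.raises(ValueError):
            fit_epistasis_slope(np.zeros(5), np.ones(5))


class TestSelection:
    def test_triple_intersection_hand_filter(self):
        ids = [f"f{i}" for i in range(6)]
        qa = [0.01, 0.05, 0.5, 0.02, 0.09, 0.2]
        qb = [0.02, 0.05, 0.01, 0.3, 0.08, 0.01]
        qab = [0.03, 0.5, 0.01, 0.04, 0.07, 0.05]
        res = [make_contrast(ids, q=np.array(q)) for q in (qa, qb, qab)]
        with pytest.warns(UserWarning):
            inp = select_features(*res, q_threshold=0.1)
        # manual: f0 passes all; f1 fails ab; f2 fails a; f3 fails b; f4 passes; f5 fails a
        assert inp.feature_ids == ["f0", "f4"]

    def test_all_significant_keeps_order(self):
        ids = [f"f{i}" for i in range(20)]
        res = [make_contrast(ids, q=np.zeros(20)) for _ in range(3)]
        inp = select_features(*res)
        assert inp.feature_ids == ids

    def test_none_selected_raises(self):
        ids = ["a", "b"]
        res = [make_contrast(ids, q=np.array([0.5, 0.9])) for _ in range(3)]
        with pytest.raises(ValueError):
            select_features(*res)

    def test_symmetry_in_a_and_b(self):
        inp = effects_input("branched", seed=3)
        swapped = EpistasisInput(inp.feature_ids, inp.beta_b, inp.beta_a, inp.beta_ab)
        np.testing.assert_allclose(inp.x, swapped.x)
        np.testing.assert_allclose(inp.delta, swapped.delta)
        assert fit_epistasis_slope(inp) == fit_epistasis_slope(swapped)


class TestBootstrap:
    def test_noise_free_additive_ci_degenerate(self):
        inp = effects_input("additive", n=100, noise_sd=0.0)
        res = bootstrap_epistasis(inp, n_boot=200, seed=0)
        assert res.s_hat == 0.0
        assert res.ci == (0.0, 0.0)
        assert np.all(res.boot == 0.0)

    @pytest.mark.parametrize("name,target", [
        ("additive", 0.0), ("unbranched", -0.5), ("repressive", -1.0),
    ])
    def test_regime_recovery_with_noise(self, name, target):
        inp = effects_input(name, n=500, noise_sd=0.05, seed=1)
        res = bootstrap_epistasis(inp, n_boot=1000, seed=1)
        assert res.boot_mean == pytest.approx(target, abs=0.05)

    def test_branched_lands_strictly_inside_regime(self):
        inp = effects_input("branched", n=500, noise_sd=0.05, seed=1)
        res = bootstrap_epistasis(inp, n_boot=1000, seed=1)
        assert -0.5 < res.boot_mean < 0.0

    def test_seeded_determinism(self):
        inp = effects_input("branched", seed=2)
        a = bootstrap_epistasis(inp, n_boot=300, seed=7)
        b = bootstrap_epistasis(inp, n_boot=300, seed=7)
        np.testing.assert_array_equal(a.boot, b.boot)

    def test_small_n_boot_rejected(self):
        inp = effects_input("additive")
        with pytest.raises(ValueError):
            bootstrap_epistasis(inp, n_boot=50)


class TestModelDistributions:
    def test_additive_distribution_concentrates_at_zero(self):
        inp = effects_input("branched", n=300, seed=4)
        dists = simulate_model_distributions(inp, n_boot=1000, seed=4)
        assert abs(np.mean(dists["additive"])) < 0.02

    def test_repressive_distribution_concentrates_at_minus_one(self):
        inp = effects_input("branched", n=300, seed=4)
        dists = simulate_model_distributions(inp, n_boot=500, seed=4)
        assert np.mean(dists["repressive"]) == pytest.approx(-1.0, abs=0.02)

    def test_masking_on_coincident_betas_gives_minus_half(self):
        """When beta_a = beta_b the masked double mutant sits at s = -1/2."""
        inp = effects_input("unbranched", n=400, noise_sd=0.0, seed=5)
        dists = simulate_model_distributions(inp, n_boot=500, seed=5)
        assert np.mean(dists["b_masks_a"]) == pytest.approx(-0.5, abs=0.05)
        assert np.mean(dists["a_masks_b"]) == pytest.approx(-0.5, abs=0.05)

    def test_coincident_betas_make_unbranched_and_masking_degenerate(self):
        inp = effects_input("unbranched", n=400, noise_sd=0.0, seed=6)
        res = bootstrap_epistasis(inp, n_boot=500, seed=6)
        res = classify_interaction(res, simulate_model_distributions(inp, 500, seed=6))
        scores = dict(res.model_ranking)
        trio = [scores["unbranched"], scores["a_masks_b"], scores["b_masks_a"]]
        assert max(trio) - min(trio) < 0.05


class TestClassification:
    @pytest.mark.parametrize("name", ["additive", "repressive"])
    def test_generating_model_ranked_first(self, name):
        inp = effects_input(name, n=300, noise_sd=0.0, seed=8)
        res = bootstrap_epistasis(inp, n_boot=300, seed=8)
        res = classify_interaction(res, simulate_model_distributions(inp, 300, seed=8))
        assert res.model_ranking[0][0] == name

    def test_repressive_overlap_fraction_high(self):
        inp = effects_input("repressive", n=300, noise_sd=0.05, seed=9)
        res = bootstrap_epistasis(inp, n_boot=300, seed=9)
        res = classify_interaction(res, simulate_model_distributions(inp, 300, seed=9))
        assert res.model_overlap["repressive"] > 0.9

    def test_ranking_covers_all_six_models(self):
        inp = effects_input("additive", n=100, seed=10)
        res = bootstrap_epistasis(inp, n_boot=200, seed=10)
        res = classify_interaction(res, simulate_model_distributions(inp, 200, seed=10))
        assert sorted(m for m, _ in res.model_ranking) == sorted(
            ["additive", "branched", "unbranched", "repressive", "a_masks_b", "b_masks_a"]
        )

    def test_empty_model_dists_rejected(self):
        inp = effects_input("additive", n=100, seed=10)
        res = bootstrap_epistasis(inp, n_boot=200, seed=10)
        with pytest.raises(ValueError):
            classify_interaction(res, {})


class TestEstimator:
    def test_sklearn_contract(self):
        est = EpistasisAnalysis(n_boot=200, seed=3)
        params = est.get_params()
        assert params["n_boot"] == 200
        est.set_params(n_boot=300)
        assert est.n_boot == 300

    def test_fit_from_beta_array(self):
        inp = effects_input("repressive", n=200, noise_sd=0.05, seed=11)
        X = np.column_stack([inp.beta_a, inp.beta_b, inp.beta_ab])
        est = EpistasisAnalysis(n_boot=300, seed=11).fit(X)
        assert est.best_model_ == "repressive"
        assert est.ci_[0] <= est.boot_mean_ <= est.ci_[1]

    def test_fit_from_contrast_triple(self):
        inp = effects_input("unbranched", n=200, noise_sd=0.05, seed=12)
        res = [
            make_contrast(inp.feature_ids, beta=b, q=np.zeros(inp.n_features))
            for b in (inp.beta_a, inp.beta_b, inp.beta_ab)
        ]
        est = EpistasisAnalysis(n_boot=300, seed=12).fit(tuple(res))
        assert est.boot_mean_ == pytest.approx(-0.5, abs=0.05)
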