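import numpy as np
import pandas as pd
import pytest

from epistax.integrate import (
    ClassicalMDS,
    ExpressionPanel,
    RUVCorrector,
    correlation_panel,
    empirical_controls,
    mds_embed,
    overlap_counts,
    regularized_log,
    remove_unwanted_variation,
)
from epistax.diffexpr import test_contrast
from epistax.simulate import InteractionModel, simulate_counts, simulate_effects
from tests.conftest import make_contrast


class TestEmpiricalControls:
    def test_all_null_contrast_keeps_everything(self):
        ids = list("abcde")
        res = make_contrast(ids, p=np.full(5, 0.5))
        assert empirical_controls([res]) == set(ids)

    def test_threshold_is_strict(self):
        ids = ["x", "y"]
        res = make_contrast(ids, p=np.array([0.05, 0.2]))
        assert empirical_controls([res], p_threshold=0.1) == {"y"}

    def test_intersection_of_two_contrasts_hand_filter(self):
        ids = list("abcde")
        r1 = make_contrast(ids, p=np.array([0.5, 0.05, 0.3, 0.9, 0.02]))
        r2 = make_contrast(ids, p=np.array([0.2, 0.6, 0.05, 0.5, 0.8]))
        assert empirical_controls([r1, r2]) == {"a", "d"}

    def test_empty_control_set_raises(self):
        res = make_contrast(["a"], p=np.array([0.01]))
        with pytest.raises(ValueError, match="loosen"):
            empirical_controls([res])


def batch_panel(seed=5, batch_sd=0.5):
    model = InteractionModel("additive", noise_sd=0.0)
    eff = simulate_effects(model, 600, 1.0, frac_nonnull=0.3, seed=seed)
    cm = simulate_counts(eff, n_reps=4, depth_mean=200.0, bcv=0.1,
                         batch_sd=batch_sd, seed=seed + 1)
    return cm


class TestRUV:
    def test_k_zero_is_identity_after_normalization(self):
        cm = batch_panel()
        panel = remove_unwanted_variation(cm, controls=set(), k=0)
        expected = regularized_log(cm)
        pd.testing.assert_frame_equal(panel.values, expected)

    def test_shapes_preserved(self):
        cm = batch_panel()
        panel = remove_unwanted_variation(cm, set(cm.feature_ids[:100]), k=1)
        assert panel.values.shape == cm.counts.shape
        assert panel.k_removed == 1

    def test_planted_batch_factor_removed(self):
        cm = batch_panel()
        batch = (cm.sample_meta["batch"] == "b1").astype(float).to_numpy()
        contrasts = [
            test_contrast(cm, cm.samples_for("WT"), cm.samples_for(g))
            for g in ("A", "B", "AB")
        ]
        controls = empirical_controls(contrasts)
        before = regularized_log(cm)
        after = remove_unwanted_variation(cm, controls, k=1).values
        ctrl = [f for f in before.index if f in controls]

        def med_abs_corr(df):
            return np.median([abs(np.corrcoef(df.loc[f], batch)[0, 1]) for f in ctrl])

        b, a = med_abs_corr(before), med_abs_corr(after)
        assert a < 0.5 * b

    def test_zero_variance_controls_fall_back_to_identity(self):
        x = np.random.default_rng(0).normal(size=(6, 20))
        x[:, :5] = 3.14  # constant control features
        corr = RUVCorrector(k=2, control_idx=list(range(5))).fit(x)
        np.testing.assert_array_equal(corr.factors_, 0.0)
        np.testing.assert_array_equal(corr.transform(x), x)

    def test_k_exceeding_rank_rejected(self):
        x = np.random.default_rng(0).normal(size=(4, 10))
        with pytest.raises(ValueError):
            RUVCorrector(k=5, control_idx=[0, 1, 2]).fit(x)

    def test_k_positive_requires_controls(self):
        cm = batch_panel()
        with pytest.raises(ValueError):
            remove_unwanted_variation(cm, controls=set(), k=1)


class TestClassicalMDS:
    def test_duplicated_samples_coincide(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(5, 30))
        x[4] = x[0]
        emb = ClassicalMDS(2).fit_transform(x)
        assert np.linalg.norm(emb[4] - emb[0]) < 1e-9

    def test_pythagorean_triangle_distances_exact(self):
        d = np.array([[0.0, 3, 4], [3, 0, 5], [4, 5, 0]])
        emb = ClassicalMDS(2).fit_transform(d, dissimilarity="precomputed")
        from scipy.spatial.distance import pdist

        np.testing.assert_allclose(np.sort(pdist(emb)), [3, 4, 5], atol=1e-6)

    def test_embedding_centered_at_origin(self):
        x = np.random.default_rng(2).normal(size=(8, 40))
        emb = ClassicalMDS(3).fit_transform(x)
        np.testing.assert_allclose(emb.mean(axis=0), 0.0, atol=1e-9)

    def test_agrees_with_skbio_pcoa(self):
        skbio = pytest.importorskip("skbio")
        from scipy.spatial.distance import pdist, squareform

        x = np.random.default_rng(3).normal(size=(7, 25))
        d = squareform(pdist(x))
        ours = ClassicalMDS(2).fit_transform(d, dissimilarity="precomputed")
        ref = skbio.stats.ordination.pcoa(d, number_of_dimensions=2).samples.to_numpy()
        for k in range(2):  # eigenvectors defined up to sign
            assert min(
                np.abs(ours[:, k] - ref[:, k]).max(),
                np.abs(ours[:, k] + ref[:, k]).max(),
            ) < 1e-6

    def test_too_many_dims_rejected(self):
        with pytest.raises(ValueError):
            ClassicalMDS(3).fit(np.zeros((3, 5)))


class TestMDSEmbed:
    def _panel(self, n_features=50):
        rng = np.random.default_rng(4)
        values = pd.DataFrame(
            rng.normal(size=(n_features, 6)),
            index=[f"g{i}" for i in range(n_features)],
            columns=[f"s{i}" for i in range(6)],
        )
        return ExpressionPanel(values=values)

    def test_feature_order_invariance(self):
        panel = self._panel()
        coords1 = mds_embed(panel, n_top=30)
        shuffled = ExpressionPanel(values=panel.values.sample(frac=1, random_state=0))
        coords2 = mds_embed(shuffled, n_top=30)
        d1 = np.linalg.norm(coords1.to_numpy()[:, None] - coords1.to_numpy()[None], axis=-1)
        d2 = np.linalg.norm(coords2.to_numpy()[:, None] - coords2.to_numpy()[None], axis=-1)
        np.testing.assert_allclose(d1, d2, atol=1e-8)

    def test_fewer_features_than_requested_uses_all(self):
        coords = mds_embed(self._panel(20), n_top=500)
        assert coords.shape == (6, 2)


class TestCorrelationPanel:
    def test_self_and_negation(self):
        rng = np.random.default_rng(6)
        v = rng.normal(size=30)
        cm = correlation_panel({"a": v, "b": v.copy(), "c": -v})
        assert cm.r.loc["a", "b"] == pytest.approx(1.0)
        assert cm.r.loc["a", "c"] == pytest.approx(-1.0)
        assert cm.r.values.diagonal() == pytest.approx(1.0)

    def test_hand_computed_pearson(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([2.0, 1.0, 4.0, 3.0])
        r_hand = np.cov(a, b, ddof=1)[0, 1] / (a.std(ddof=1) * b.std(ddof=1))
        cm = correlation_panel({"a": a, "b": b})
        assert cm.r.loc["a", "b"] == pytest.approx(r_hand)

    def test_symmetric_and_order_is_permutation(self):
        rng = np.random.default_rng(7)
        prof = {k: rng.normal(size=40) for k in "abcd"}
        cm = correlation_panel(prof)
        np.testing.assert_allclose(cm.r.values, cm.r.values.T)
        assert sorted(cm.order) == sorted(cm.labels)

    def test_zero_variance_profile_named(self):
        with pytest.raises(ValueError, match="flat"):
            correlation_panel({"ok": np.array([1.0, 2.0, 3.0]), "flat": np.ones(3)})


class TestOverlapCounts:
    def test_disjoint_sets(self):
        table = overlap_counts({"A": {"a"}, "B": {"b"}})
        counts = dict(zip(table["combination"], table["count"]))
        assert counts == {"A": 1, "B": 1, "A&B": 0}

    def test_identical_sets_fill_full_intersection(self):
        s = set("abcdefg")
        table = overlap_counts({"A": s, "B": set(s)})
        counts = dict(zip(table["combination"], table["count"]))
        assert counts["A&B"] == 7
        assert counts["A"] == counts["B"] == 0

    def test_three_sets_match_brute_force(self):
        sets = {"A": {1, 2, 3, 4}, "B": {3, 4, 5}, "C": {4, 5, 6, 7}}
        table = overlap_counts(sets)
        counts = dict(zip(table["combination"], table["count"]))
        union = set().union(*sets.values())
        for combo, n in counts.items():
            members = combo.split("&")
            expected = sum(
                1 for f in union
                if all(f in sets[m] for m in members)
                and not any(f in sets[m] for m in sets if m not in members)
            )
            assert n == expected
        assert sum(counts.values()) == len(union)

    def test_single_set_rejected(self):
        with pytest.raises(ValueError):
            overlap_counts({"A": {1}})
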