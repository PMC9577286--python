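import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import groundlex as gl
from groundlex.evaluation import evaluate_variant, friedman_statistic, per_word_threshold_curves
from groundlex.predictor import NetworkConfig


def brute_dunn(points, labels):
    inter = np.inf
    diam = 0.0
    n = len(labels)
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.linalg.norm(points[i] - points[j]))
            if labels[i] == labels[j]:
                diam = max(diam, d)
            else:
                inter = min(inter, d)
    return np.inf if diam == 0 else inter / diam


class TestDunn:
    def test_two_tight_far_clusters(self):
        pts = np.array([[0.0, 0], [0, 1], [10, 0], [10, 1]])
        labels = np.array([0, 0, 1, 1])
        assert gl.dunn_index(pts, labels) == pytest.approx(10.0)

    def test_singletons_give_inf(self):
        pts = np.array([[0.0, 0], [5, 0], [9, 0]])
        assert gl.dunn_index(pts, np.array([0, 1, 2])) == np.inf

    def test_single_cluster_errors(self):
        with pytest.raises(ValueError):
            gl.dunn_index(np.zeros((3, 2)), np.array([1, 1, 1]))

    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(4, 15))
            pts = rng.standard_normal((n, int(rng.integers(1, 5))))
            labels = rng.integers(0, 3, size=n)
            if len(set(labels.tolist())) < 2:
                continue
            assert gl.dunn_index(pts, labels) == pytest.approx(brute_dunn(pts, labels), abs=1e-10)


class TestClusterWords:
    def test_recovers_separated_blobs(self):
        rng = np.random.default_rng(1)
        vecs = {}
        for i in range(15):
            vecs[f"a{i}"] = np.array([0.0, 0.0]) + 0.05 * rng.standard_normal(2)
            vecs[f"b{i}"] = np.array([50.0, 0.0]) + 0.05 * rng.standard_normal(2)
        space = gl.EmbeddingSpace("textual", vecs)
        (cs,) = gl.cluster_words(space, n_clusters=2, restarts=5, n_sets=1, seed=0)
        groups = {}
        for w, c in cs.assignment.items():
            groups.setdefault(c, set()).add(w[0])
        assert sorted(g.pop() for g in groups.values() if len(g) == 1) == ["a", "b"]

    def test_every_word_assigned_once(self, tiny_world):
        sets = gl.cluster_words(
            tiny_world.textual, lexicon=tiny_world.lexicon,
            n_clusters=5, restarts=3, n_sets=2, seed=0,
        )
        for cs in sets:
            assert set(cs.assignment) == set(tiny_world.lexicon.words)
            assert cs.dunn >= 0

    def test_selected_set_has_max_dunn_of_restarts(self, tiny_world):
        # rerun the restarts by hand with the same sub-seeds
        from scipy.spatial.distance import pdist, squareform
        from sklearn.cluster import KMeans

        words = list(tiny_world.lexicon)
        X = tiny_world.textual.matrix(words)
        D = squareform(pdist(X))
        (best,) = gl.cluster_words(
            tiny_world.textual, lexicon=tiny_world.lexicon,
            n_clusters=5, restarts=4, n_sets=1, seed=11,
        )
        (set_ss,) = np.random.SeedSequence(11).spawn(1)
        dunns = []
        for r_ss in set_ss.spawn(4):
            sub = int(r_ss.generate_state(1)[0] % (2**31))
            km = KMeans(n_clusters=5, n_init=1, max_iter=300, tol=1e-6, random_state=sub).fit(X)
            dunns.append(gl.dunn_index(X, km.labels_, precomputed=D))
        assert best.dunn == pytest.approx(max(dunns))

    def test_too_few_words_errors(self):
        space = gl.EmbeddingSpace("textual", {f"w{i}": np.ones(2) * i for i in range(3)})
        with pytest.raises(ValueError):
            gl.cluster_words(space, n_clusters=3, restarts=1, n_sets=1, seed=0)


class TestScorePredictions:
    def test_perfect_linear(self):
        r, rho, mse = gl.score_predictions(np.array([1.0, 2, 3]), np.array([2.0, 4, 6]))
        assert r == pytest.approx(1.0) and rho == pytest.approx(1.0)

    def test_perfect_negative(self):
        r, _, _ = gl.score_predictions(np.array([1.0, 2, 3]), np.array([6.0, 4, 2]))
        assert r == pytest.approx(-1.0)

    def test_hand_computed_case(self):
        r, _, mse = gl.score_predictions(np.array([1.0, 2, 4]), np.array([1.0, 3, 3]))
        assert r == pytest.approx(24 / np.sqrt(1008))
        assert mse == pytest.approx(2 / 3)

    def test_zero_variance_sentinel(self):
        r, rho, mse = gl.score_predictions(np.array([1.0, 1, 1]), np.array([1.0, 2, 3]))
        assert np.isnan(r) and np.isnan(rho) and mse == pytest.approx(5 / 3)

    def test_matches_brute_force_definitions(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            n = int(rng.integers(3, 20))
            a, b = rng.standard_normal(n), rng.standard_normal(n)
            r, rho, mse = gl.score_predictions(a, b)
            # Pearson from the definition
            ac, bc = a - a.mean(), b - b.mean()
            r_def = float(np.sum(ac * bc) / np.sqrt(np.sum(ac**2) * np.sum(bc**2)))
            assert r == pytest.approx(r_def, abs=1e-10)
            # Spearman = Pearson on average ranks
            ra, rb = stats.rankdata(a), stats.rankdata(b)
            rac, rbc = ra - ra.mean(), rb - rb.mean()
            rho_def = float(np.sum(rac * rbc) / np.sqrt(np.sum(rac**2) * np.sum(rbc**2)))
            assert rho == pytest.approx(rho_def, abs=1e-10)
            assert mse == pytest.approx(float(np.mean((a - b) ** 2)), abs=1e-12)

    def test_short_vectors_rejected(self):
        with pytest.raises(ValueError):
            gl.score_predictions(np.array([1.0, 2]), np.array([1.0, 2]))


class TestFriedman:
    def test_three_by_three_closed_form(self):
        # one model ranked best everywhere, no ties -> chi2 = 6, df = 2
        mat = pd.DataFrame({"A": [3.0, 3.1, 2.9], "B": [2.0, 2.2, 1.9], "C": [1.0, 1.2, 0.8]})
        chi2, df, p = friedman_statistic(mat)
        assert chi2 == pytest.approx(6.0) and df == 2

    def test_identical_columns_degenerate(self):
        mat = pd.DataFrame({"A": [1.0, 2.0], "B": [1.0, 2.0], "C": [1.0, 2.0]})
        chi2, df, p = friedman_statistic(mat)
        assert chi2 == 0.0 and p == 1.0

    def test_closed_form_on_random_no_ties_matrices(self):
        """12/(nk(k+1)) * sum R^2 - 3n(k+1) on random 5x4 matrices."""
        rng = np.random.default_rng(3)
        for _ in range(100):
            X = rng.standard_normal((5, 4))
            chi2, df, _ = friedman_statistic(X)
            ranks = stats.rankdata(X, axis=1)
            R = ranks.sum(axis=0)
            expected = 12.0 / (5 * 4 * 5) * np.sum(R**2) - 3 * 5 * 5
            assert chi2 == pytest.approx(expected, abs=1e-10)
            assert df == 3

    def test_agrees_with_scipy(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            X = rng.standard_normal((8, 3))
            chi2, _, p = friedman_statistic(X)
            s_chi2, s_p = stats.friedmanchisquare(X[:, 0], X[:, 1], X[:, 2])
            assert chi2 == pytest.approx(float(s_chi2), abs=1e-10)
            assert p == pytest.approx(float(s_p), abs=1e-10)


class TestCompareModels:
    def test_dominant_model_pair_significant(self):
        rng = np.random.default_rng(5)
        b = rng.standard_normal(20)
        mat = pd.DataFrame({"A": b + rng.uniform(0.5, 1.0, 20), "B": b})
        res = gl.compare_models(mat)
        assert res.pairwise["significant"].all()
        assert res.df == 1

    def test_identical_models_nothing_significant(self):
        vals = np.linspace(0, 1, 12)
        mat = pd.DataFrame({"A": vals, "B": vals, "C": vals})
        res = gl.compare_models(mat)
        assert res.friedman_chi2 == 0.0 and res.p_value == 1.0
        assert not res.pairwise["significant"].any()

    def test_all_pairs_reported(self):
        rng = np.random.default_rng(6)
        mat = pd.DataFrame(rng.standard_normal((10, 4)), columns=list("ABCD"))
        res = gl.compare_models(mat)
        assert len(res.pairwise) == 6  # 4 choose 2

    def test_ryan_procedure_extreme_pair(self):
        rng = np.random.default_rng(7)
        b = rng.standard_normal(25)
        mat = pd.DataFrame({"A": b + 2.0 + 0.1 * rng.standard_normal(25), "B": b + 1.0 + 0.1 * rng.standard_normal(25), "C": b})
        res = gl.compare_models(mat, procedure="ryan")
        sig = dict(zip(zip(res.pairwise["model_a"], res.pairwise["model_b"]), res.pairwise["significant"]))
        assert sig[("A", "C")]

    def test_missing_cells_rejected(self):
        mat = pd.DataFrame({"A": [1.0, np.nan], "B": [1.0, 2.0]})
        with pytest.raises(ValueError):
            gl.compare_models(mat)


@pytest.fixture(scope="module")
def cv(tiny_pipeline, tiny_net_cfg, tiny_world):
    world, visual, partition, grounded = tiny_pipeline
    sets = gl.cluster_words(
        world.textual, lexicon=world.lexicon, n_clusters=5, restarts=3, n_sets=1, seed=0
    )
    res = gl.loco_cv(
        gl.ModelSpec("indirect_grounding"), world.lexicon, world.textual, visual,
        grounded, partition, world.norms, sets[0], tiny_net_cfg, runs=3, seed=0,
    )
    return res, sets[0], world


class TestLocoCV:
    def test_each_word_predicted_exactly_once(self, cv):
        res, cs, world = cv
        assert sorted(res.predictions) == sorted(world.lexicon.words)
        assert len(res.scores) == len(world.lexicon)

    def test_training_never_contains_own_cluster(self, cv):
        res, cs, world = cv
        for c, train_words in res.fold_train_words.items():
            held_out = set(cs.members(c))
            assert held_out.isdisjoint(train_words)
            assert set(train_words) | held_out == set(world.lexicon.words)

    def test_retained_run_is_best(self, cv):
        res, _, _ = cv
        assert len(res.run_mean_r) == 3
        assert res.run_mean_r[res.retained_run] == max(res.run_mean_r)

    def test_deterministic_given_seed(self, tiny_pipeline, tiny_net_cfg, tiny_world):
        world, visual, partition, grounded = tiny_pipeline
        sets = gl.cluster_words(
            world.textual, lexicon=world.lexicon, n_clusters=5, restarts=2, n_sets=1, seed=1
        )
        kw = dict(runs=2, seed=42)
        a = gl.loco_cv(gl.ModelSpec("textual"), world.lexicon, world.textual, visual,
                       grounded, partition, world.norms, sets[0], tiny_net_cfg, **kw)
        b = gl.loco_cv(gl.ModelSpec("textual"), world.lexicon, world.textual, visual,
                       grounded, partition, world.norms, sets[0], tiny_net_cfg, **kw)
        pd.testing.assert_frame_equal(a.scores, b.scores)

    def test_textual_variant_on_noiseless_linear_world(self):
        """When norms are a linear map of the textual vectors, the textual
        variant's retained run reaches mean r > 0.95."""
        rng = np.random.default_rng(8)
        n, d, d_out = 90, 8, 6
        words = [f"w{i}" for i in range(n)]
        X = rng.standard_normal((n, d))
        A = rng.standard_normal((d, d_out))
        Y = X @ A
        textual = gl.EmbeddingSpace("textual", dict(zip(words, X)))
        visual = gl.EmbeddingSpace("visual", {w: np.zeros(2) for w in words})
        norms = gl.ConceptNorms([f"a{j}" for j in range(d_out)], dict(zip(words, Y)))
        lex = gl.Lexicon(words)
        ratings = gl.ConcretenessTable({w: 4.0 for w in words})
        partition = gl.partition_vocabulary(lex, ratings, 3.0)
        grounded = gl.build_grounded_space(lex, textual, visual, partition, gl.NeighborConfig(10, 3))
        sets = gl.cluster_words(textual, lexicon=lex, n_clusters=5, restarts=3, n_sets=1, seed=0)
        cfg = NetworkConfig(d_text_in=d, d_vis_in=2, d_text_hidden=24, d_vis_hidden=4,
                            d_out=d_out, epochs=200, learning_rate=0.01, batch_size=8)
        res = gl.loco_cv(gl.ModelSpec("textual"), lex, textual, visual, grounded,
                         partition, norms, sets[0], cfg, runs=3, seed=0)
        assert res.mean_score() > 0.95


class TestAggregate:
    def _mk(self, rs, words=("u", "v")):
        scores = pd.DataFrame(
            {"pearson": rs, "spearman": rs, "mse": [0.1] * len(words)}, index=list(words)
        )
        preds = {w: np.full(3, r) for w, r in zip(words, rs)}
        return gl.CVResult(variant="textual", predictions=preds, scores=scores)

    def test_identical_sets_idempotent(self):
        a = self._mk([0.2, 0.4])
        agg = gl.aggregate_cluster_sets([a, self._mk([0.2, 0.4])])
        pd.testing.assert_frame_equal(agg.scores, a.scores)

    def test_mean_of_two_sets(self):
        agg = gl.aggregate_cluster_sets([self._mk([0.2, 0.2]), self._mk([0.4, 0.4])])
        assert agg.scores["pearson"].tolist() == pytest.approx([0.3, 0.3])

    def test_random_sets_match_summation_oracle(self):
        rng = np.random.default_rng(9)
        results = [self._mk(rng.uniform(-1, 1, 2).tolist()) for _ in range(10)]
        agg = gl.aggregate_cluster_sets(results)
        for w in ("u", "v"):
            expected = sum(r.scores.loc[w, "pearson"] for r in results) / 10
            assert agg.scores.loc[w, "pearson"] == pytest.approx(expected, abs=1e-12)

    def test_mismatched_variants_or_lexica_rejected(self):
        a = self._mk([0.1, 0.2])
        b = self._mk([0.1, 0.2], words=("u", "w"))
        with pytest.raises(ValueError):
            gl.aggregate_cluster_sets([a, b])


class TestDiffAnalysis:
    def _results(self, r_i, r_b, words):
        def mk(rs, variant):
            scores = pd.DataFrame(
                {"pearson": rs, "spearman": rs, "mse": [0.0] * len(words)}, index=list(words)
            )
            return gl.CVResult(variant=variant, predictions={}, scores=scores)

        return {"indirect_grounding": mk(r_i, "indirect_grounding"), "hybrid": mk(r_b, "hybrid")}

    def test_interval_means_match_hand_average(self):
        words = ["w1", "w2", "w3", "w4", "w5", "w6"]
        ratings = gl.ConcretenessTable(dict(zip(words, [1.2, 1.6, 2.4, 2.6, 3.5, 4.5])))
        r_i = [0.5, 0.6, 0.7, 0.8, 0.9, 1.0]
        r_b = [0.4, 0.4, 0.4, 0.4, 0.4, 0.4]
        out = gl.diff_analysis(
            self._results(r_i, r_b, words), ratings, interval_width=2.0, rating_range=(1.0, 5.0)
        )
        ivs = out["intervals"]
        assert len(ivs) == 2
        lo = ivs[ivs["lower"] == 1.0].iloc[0]
        assert lo["n_words"] == 4
        assert lo["mean_diff_r"] == pytest.approx(np.mean([0.1, 0.2, 0.3, 0.4]))
        hi = ivs[ivs["lower"] == 3.0].iloc[0]
        assert hi["mean_diff_r"] == pytest.approx(np.mean([0.5, 0.6]))

    def test_identical_models_zero_diff_and_nan_correlation(self):
        words = ["a", "b", "c", "d"]
        ratings = gl.ConcretenessTable(dict(zip(words, [1.5, 2.5, 3.5, 4.5])))
        rs = [0.3, 0.5, 0.6, 0.7]
        out = gl.diff_analysis(self._results(rs, rs, words), ratings)
        assert (out["per_word"]["diff_r"] == 0).all()
        assert np.isnan(out["concreteness_correlation"])

    def test_category_filter_min_words(self):
        words = [f"w{i}" for i in range(7)]
        ratings = gl.ConcretenessTable({w: 2.0 for w in words})
        cats = gl.CategoryMap({w: ("big" if i < 4 else "small") for i, w in enumerate(words)})
        out = gl.diff_analysis(
            self._results([0.5] * 7, [0.2] * 7, words), ratings, category_map=cats, min_words=4
        )
        assert out["categories"]["category"].tolist() == ["big"]
        assert out["categories"].iloc[0]["mean_diff_r"] == pytest.approx(0.3)

    def test_diff_correlates_with_concreteness_when_built_in(self):
        rng = np.random.default_rng(10)
        words = [f"w{i}" for i in range(30)]
        c = rng.uniform(1, 5, 30)
        ratings = gl.ConcretenessTable(dict(zip(words, c)))
        r_b = np.zeros(30)
        r_i = 0.1 * c  # diff increases with concreteness
        out = gl.diff_analysis(self._results(r_i.tolist(), r_b.tolist(), words), ratings)
        assert out["concreteness_correlation"] == pytest.approx(1.0)


class TestThresholdSweep:
    def test_single_theta_consistent_with_direct_call(self, tiny_pipeline, tiny_net_cfg, tiny_world):
        world, visual, partition, grounded = tiny_pipeline
        sets = gl.cluster_words(
            world.textual, lexicon=world.lexicon, n_clusters=5, restarts=2, n_sets=1, seed=0
        )
        ncfg = gl.NetworkConfig(
            d_text_in=world.config.d_text, d_vis_in=world.config.d_vis,
            d_text_hidden=8, d_vis_hidden=8, d_out=world.config.d_out, epochs=4,
        )
        table = gl.threshold_sweep(
            [3.0], world.lexicon, world.textual, visual, world.ratings, world.norms,
            sets, ["textual"], ncfg, gl.NeighborConfig(20, 4), runs=1, seed=5,
        )
        assert len(table) == 1
        direct = evaluate_variant(
            gl.ModelSpec("textual"), world.lexicon, world.textual, visual, grounded,
            partition, world.norms, sets, ncfg, runs=1, seed=5,
        )
        assert table.iloc[0]["r_all_textual"] == pytest.approx(direct.mean_score())

    def test_empty_grid_rejected(self, tiny_world):
        with pytest.raises(ValueError):
            gl.threshold_sweep([], tiny_world.lexicon, None, None, None, None, [], [], None)


def test_per_word_threshold_curves_shape():
    scores = pd.DataFrame({"pearson": [0.1, 0.2], "spearman": [0, 0], "mse": [0, 0]}, index=["a", "b"])
    res = gl.CVResult(variant="indirect_grounding", predictions={}, scores=scores)
    curves = per_word_threshold_curves({1.5: {"indirect_grounding": res}, 2.0: {"indirect_grounding": res}}, ["a", "b"])
    assert curves.shape == (2, 3)
    assert curves["theta_c"].tolist() == [1.5, 2.0]
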