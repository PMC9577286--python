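"""Evaluation machinery: Dunn-selected k-means cluster sets,
leave-one-cluster-out cross-validation, per-word scoring, nonparametric
model comparison, threshold sweeps and diff(r) analyses.

Leave-one-cluster-out cross-validation replaces random folds with
semantic clusters: for each cluster the predictor is trained on every
word outside it and tested on the held-out cluster, so test words cannot
profit from close neighbors in the training set.  Cluster sets come from
k-means on the textual vectors, the best of many restarts by Dunn index,
and the whole procedure is repeated to produce several independent
cluster sets whose per-word scores are averaged.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans

from .grounding import (
    GroundedSpace,
    ModelSpec,
    NeighborConfig,
    VocabularyPartition,
    build_grounded_space,
    model_inputs,
    partition_vocabulary,
)
from .lexdata import ConcretenessTable, ConceptNorms, EmbeddingSpace, Lexicon
from .predictor import NetworkConfig, TrainingSet, init_network, predict_vector, train_network

__all__ = [
    "ClusterSet",
    "CVResult",
    "ComparisonResult",
    "dunn_index",
    "cluster_words",
    "loco_cv",
    "score_predictions",
    "compare_models",
    "friedman_statistic",
    "threshold_sweep",
    "diff_analysis",
    "per_word_threshold_curves",
    "aggregate_cluster_sets",
]


@dataclass
class ClusterSet:
    """One k-means partition of the lexicon, with its Dunn index."""

    assignment: dict[str, int]
    dunn: float
    seed: int
    restart_index: int = 0

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignment.values()))

    def cluster_ids(self) -> list[int]:
        return sorted(set(self.assignment.values()))

    def members(self, cluster_id: int) -> list[str]:
        return [w for w, c in self.assignment.items() if c == cluster_id]


@dataclass
class CVResult:
    """Per-word predictions and scores of one model variant.

    ``scores`` is indexed by word with columns ``pearson``, ``spearman``,
    ``mse``.  ``run_mean_r`` traces the mean correlation of each of the
    repeated runs; the retained run maximizes it.
    """

    variant: str
    predictions: dict[str, np.ndarray]
    scores: pd.DataFrame
    cluster_set_seed: int | None = None
    retained_run: int = 0
    run_mean_r: list[float] = field(default_factory=list)
    fold_train_words: dict[int, list[str]] | None = None

    def words(self) -> list[str]:
        return list(self.scores.index)

    def mean_score(self, metric: str = "pearson", subset: set[str] | frozenset[str] | None = None) -> float:
        s = self.scores[metric]
        if subset is not None:
            s = s.loc[[w for w in s.index if w in subset]]
        return float(np.nanmean(s.to_numpy())) if len(s) else float("nan")


@dataclass
class ComparisonResult:
    """Friedman omnibus plus familywise-controlled pairwise decisions."""

    friedman_chi2: float
    df: int
    p_value: float
    n_words: int
    pairwise: pd.DataFrame  # columns: model_a, model_b, p_raw, significant, procedure

    def significant_pairs(self) -> list[tuple[str, str]]:
        sig = self.pairwise[self.pairwise["significant"]]
        return [(a, b) for a, b in zip(sig["model_a"], sig["model_b"])]


# ---------------------------------------------------------------------------
# Clustering


def dunn_index(points: np.ndarray, labels: np.ndarray, precomputed: np.ndarray | None = None) -> float:
    """Ratio of minimum between-cluster distance to maximum cluster diameter.

    Distances are Euclidean over all point pairs.  All-singleton clusters
    have zero diameter and return ``inf`` (a degenerate but valid
    clustering that ranks above any finite value); a single cluster is an
    error.
    """
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("Dunn index needs at least two clusters")
    D = squareform(pdist(np.asarray(points, dtype=np.float64))) if precomputed is None else precomputed
    same = labels[:, None] == labels[None, :]
    n = len(labels)
    off_diag = ~np.eye(n, dtype=bool)
    inter = D[~same].min()
    intra_mask = same & off_diag
    max_diam = D[intra_mask].max() if intra_mask.any() else 0.0
    if max_diam == 0.0:
        return float("inf")
    return float(inter / max_diam)


def cluster_words(
    textual: EmbeddingSpace,
    lexicon: Lexicon | None = None,
    n_clusters: int = 20,
    restarts: int = 100,
    n_sets: int = 10,
    seed: int = 0,
) -> list[ClusterSet]:
    """Build ``n_sets`` cluster sets; each is the max-Dunn pick of ``restarts`` k-means runs.

    k-means uses Euclidean distance on the raw textual vectors (max 300
    iterations, centroid-shift tolerance 1e-6, one initialization per
    restart so that Dunn — not inertia — does the model selection).
    First restart wins Dunn ties, for determinism.
    """
    words = list(lexicon) if lexicon is not None else list(textual.words())
    if len(words) <= n_clusters:
        raise ValueError(f"need more than {n_clusters} words, got {len(words)}")
    X = textual.matrix(words)
    D = squareform(pdist(X))
    root = np.random.SeedSequence(seed)
    sets: list[ClusterSet] = []
    for set_ss in root.spawn(n_sets):
        best: ClusterSet | None = None
        for r_idx, r_ss in enumerate(set_ss.spawn(restarts)):
            sub_seed = int(r_ss.generate_state(1)[0] % (2**31))
            km = KMeans(
                n_clusters=n_clusters, n_init=1, max_iter=300, tol=1e-6, random_state=sub_seed
            ).fit(X)
            labels = km.labels_
            dunn = dunn_index(X, labels, precomputed=D)
            if best is None or dunn > best.dunn:
                best = ClusterSet(
                    assignment={w: int(c) + 1 for w, c in zip(words, labels)},
                    dunn=float(dunn),
                    seed=sub_seed,
                    restart_index=r_idx,
                )
        assert best is not None
        sets.append(best)
    return sets


# ---------------------------------------------------------------------------
# Scoring


def score_predictions(y_hat: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """(Pearson r, Spearman rho, MSE) between a predicted and a target vector.

    Spearman uses average ranks for ties.  A zero-variance vector leaves
    the correlations undefined; NaN is returned as the sentinel (MSE is
    always defined).
    """
    y_hat = np.asarray(y_hat, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if y_hat.shape != y.shape or y_hat.ndim != 1 or y_hat.shape[0] < 3:
        raise ValueError("score_predictions needs two equal-length vectors of length >= 3")
    mse = float(np.mean((y_hat - y) ** 2))
    if np.std(y_hat) == 0.0 or np.std(y) == 0.0:
        return float("nan"), float("nan"), mse
    r = float(stats.pearsonr(y_hat, y).statistic)
    rho = float(stats.spearmanr(y_hat, y).statistic)
    return r, rho, mse


# ---------------------------------------------------------------------------
# Leave-one-cluster-out cross-validation


def _fold_seed(seed: int, run_idx: int, cluster_id: int) -> int:
    # variant-independent: identical inputs must yield identical results
    return int(np.random.SeedSequence([seed, run_idx, cluster_id]).generate_state(1)[0] % (2**31))


def loco_cv(
    spec: ModelSpec,
    lexicon: Lexicon,
    textual: EmbeddingSpace,
    visual: EmbeddingSpace,
    grounded: GroundedSpace,
    partition: VocabularyPartition,
    norms: ConceptNorms,
    cluster_set: ClusterSet,
    net_cfg: NetworkConfig,
    runs: int = 3,
    seed: int = 0,
) -> CVResult:
    """Leave-one-cluster-out CV for one variant on one cluster set.

    For each cluster, the network is trained from scratch on all other
    clusters' words and predicts the held-out words, so every word is
    predicted exactly once.  The whole pass is repeated ``runs`` times
    with fresh seeds and the run with the highest mean Pearson r across
    all words is retained.  Fold seeds depend only on (seed, run,
    cluster), never on the variant, so two variants fed identical inputs
    produce bit-identical results.
    """
    words = list(lexicon)
    missing = [w for w in words if w not in norms]
    if missing:
        raise KeyError(f"words without norms: {missing[:5]}")
    inputs = {w: model_inputs(spec, w, textual, visual, grounded, partition) for w in words}
    cluster_ids = cluster_set.cluster_ids()
    by_cluster: dict[int, list[str]] = {c: [] for c in cluster_ids}
    for w in words:
        by_cluster[cluster_set.assignment[w]].append(w)

    fold_train = {c: [w for w in words if cluster_set.assignment[w] != c] for c in cluster_ids}
    best: CVResult | None = None
    run_means: list[float] = []
    run_results: list[CVResult] = []
    for run_idx in range(runs):
        predictions: dict[str, np.ndarray] = {}
        for c in cluster_ids:
            train_words = fold_train[c]
            if not train_words:
                raise ValueError(f"cluster {c} has an empty training complement")
            items = [(w, inputs[w][0], inputs[w][1], norms[w]) for w in train_words]
            data = TrainingSet.from_items(items, net_cfg.d_text_in, net_cfg.d_vis_in)
            fs = _fold_seed(seed, run_idx, c)
            model = init_network(net_cfg, seed=fs)
            model = train_network(model, data, seed=fs + 1)
            for w in by_cluster[c]:
                t, v = inputs[w]
                predictions[w] = predict_vector(model, t, v)
        rows = {w: score_predictions(predictions[w], norms[w]) for w in words}
        scores = pd.DataFrame.from_dict(rows, orient="index", columns=["pearson", "spearman", "mse"])
        scores = scores.loc[words]
        mean_r = float(np.nanmean(scores["pearson"].to_numpy()))
        run_means.append(mean_r)
        run_results.append(
            CVResult(
                variant=spec.variant,
                predictions=predictions,
                scores=scores,
                cluster_set_seed=cluster_set.seed,
            )
        )
    retained = int(np.argmax(run_means))
    best = run_results[retained]
    best.retained_run = retained
    best.run_mean_r = run_means
    best.fold_train_words = fold_train
    return best


def aggregate_cluster_sets(results: list[CVResult]) -> CVResult:
    """Average per-word scores (and predictions) across cluster sets."""
    if not results:
        raise ValueError("no results to aggregate")
    variants = {r.variant for r in results}
    if len(variants) != 1:
        raise ValueError(f"cannot aggregate across variants {sorted(variants)}")
    words = results[0].words()
    for r in results[1:]:
        if r.words() != words:
            raise ValueError("cluster-set results cover different lexica")
    scores = sum(r.scores.loc[words] for r in results) / len(results)
    predictions = {
        w: np.mean([r.predictions[w] for r in results], axis=0) for w in words
    }
    return CVResult(variant=results[0].variant, predictions=predictions, scores=scores)


def evaluate_variant(
    spec: ModelSpec,
    lexicon: Lexicon,
    textual: EmbeddingSpace,
    visual: EmbeddingSpace,
    grounded: GroundedSpace,
    partition: VocabularyPartition,
    norms: ConceptNorms,
    cluster_sets: list[ClusterSet],
    net_cfg: NetworkConfig,
    runs: int = 3,
    seed: int = 0,
) -> CVResult:
    """Best-of-``runs`` LOCO-CV on every cluster set, averaged."""
    per_set = [
        loco_cv(
            spec, lexicon, textual, visual, grounded, partition, norms,
            cs, net_cfg, runs=runs, seed=seed + 1000 * i,
        )
        for i, cs in enumerate(cluster_sets)
    ]
    return aggregate_cluster_sets(per_set)


# ---------------------------------------------------------------------------
# Model comparison statistics


def friedman_statistic(score_matrix: pd.DataFrame | np.ndarray) -> tuple[float, int, float]:
    """Tie-corrected Friedman chi-square over a words x models matrix.

    Within each word the models are ranked (average ranks for ties); the
    statistic is ``12/(n k (k+1)) * sum_j R_j^2 - 3 n (k+1)`` divided by
    the tie-correction factor ``1 - sum(t^3 - t) / (n k (k^2 - 1))``.
    Works for k = 2 (where scipy's implementation refuses); completely
    tied data yields statistic 0, p = 1.
    """
    X = np.asarray(score_matrix, dtype=np.float64)
    n, k = X.shape
    ranks = stats.rankdata(X, axis=1)
    R = ranks.sum(axis=0)
    raw = 12.0 / (n * k * (k + 1)) * np.sum(R**2) - 3.0 * n * (k + 1)
    ties = 0.0
    for row in X:
        _, counts = np.unique(row, return_counts=True)
        ties += float(np.sum(counts**3 - counts))
    denom = 1.0 - ties / (n * k * (k**2 - 1))
    if denom <= 0.0:  # every row completely tied
        return 0.0, k - 1, 1.0
    chi2 = raw / denom
    p = float(stats.chi2.sf(chi2, k - 1))
    return float(chi2), k - 1, p


def _friedman(score_matrix: pd.DataFrame) -> tuple[float, int, float]:
    return friedman_statistic(score_matrix)


def _wilcoxon_p(a: np.ndarray, b: np.ndarray) -> float:
    """Signed-rank p; zero differences dropped; exact for small n, else
    normal approximation with tie correction."""
    d = a - b
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        return 1.0
    has_ties = len(np.unique(np.abs(d))) < n
    method = "exact" if (n <= 25 and not has_ties) else "approx"
    res = stats.wilcoxon(d, zero_method="wilcox", correction=False, method=method)
    return float(res.pvalue)


def _ryan_alphas(order: list[str], k: int, alpha: float) -> dict[tuple[str, str], float]:
    """Per-pair nominal levels for Ryan's stepwise procedure.

    For a pair whose members are s positions apart in the ordering of the
    k group means, the nominal level is ``2 * alpha / (k * (s - 1))``
    (the extreme pair, s = k, gets the Bonferroni level for all
    k(k-1)/2 comparisons).
    """
    pos = {m: i for i, m in enumerate(order)}
    alphas = {}
    for a, b in itertools.combinations(order, 2):
        s = abs(pos[a] - pos[b]) + 1
        alphas[(a, b)] = 2.0 * alpha / (k * (s - 1))
    return alphas


def compare_models(
    score_matrix: pd.DataFrame,
    alpha: float = 0.05,
    procedure: str = "holm",
) -> ComparisonResult:
    """Friedman omnibus + familywise-controlled pairwise Wilcoxon tests.

    ``score_matrix`` is words x models (per-word scores, no missing
    cells).  ``procedure`` is ``"holm"`` (step-down over all pairwise
    p-values) or ``"ryan"`` (span-adjusted stepwise levels; a pair is
    only declared significant if no enclosing span was retained as
    non-significant).
    """
    if score_matrix.isna().any().any():
        raise ValueError("score matrix contains missing cells")
    n, k = score_matrix.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 words and 2 models")
    chi2, df, p = _friedman(score_matrix)
    models = list(score_matrix.columns)
    pairs = list(itertools.combinations(models, 2))
    p_raw = {
        (a, b): _wilcoxon_p(score_matrix[a].to_numpy(), score_matrix[b].to_numpy())
        for a, b in pairs
    }
    if procedure == "holm":
        from statsmodels.stats.multitest import multipletests

        reject, _, _, _ = multipletests([p_raw[p_] for p_ in pairs], alpha=alpha, method="holm")
        sig = dict(zip(pairs, reject))
    elif procedure == "ryan":
        order = list(score_matrix.mean(axis=0).sort_values(ascending=False).index)
        alphas = _ryan_alphas(order, k, alpha)
        pos = {m: i for i, m in enumerate(order)}
        # widest spans first; a retained (non-significant) span blocks all nested pairs
        sig = {}
        blocked: set[tuple[int, int]] = set()
        for a, b in sorted(pairs, key=lambda ab: -(abs(pos[ab[0]] - pos[ab[1]]))):
            lo, hi = sorted((pos[a], pos[b]))
            nested_block = any(blo <= lo and hi <= bhi for blo, bhi in blocked)
            key = (a, b) if (a, b) in alphas else (b, a)
            if nested_block or p_raw[(a, b)] >= alphas[key]:
                sig[(a, b)] = False
                blocked.add((lo, hi))
            else:
                sig[(a, b)] = True
    else:
        raise ValueError(f"unknown procedure {procedure!r}")
    table = pd.DataFrame(
        [
            {"model_a": a, "model_b": b, "p_raw": p_raw[(a, b)], "significant": bool(sig[(a, b)]), "procedure": procedure}
            for a, b in pairs
        ]
    )
    return ComparisonResult(friedman_chi2=chi2, df=df, p_value=p, n_words=n, pairwise=table)


# ---------------------------------------------------------------------------
# Threshold sweep and diff(r) analyses


def threshold_sweep(
    grid: list[float],
    lexicon: Lexicon,
    textual: EmbeddingSpace,
    visual: EmbeddingSpace,
    ratings: ConcretenessTable,
    norms: ConceptNorms,
    cluster_sets: list[ClusterSet],
    variants: list[str],
    net_cfg: NetworkConfig,
    neighbor_cfg: NeighborConfig = NeighborConfig(),
    runs: int = 3,
    seed: int = 0,
    keep_results: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, dict[float, dict[str, CVResult]]]:
    """Re-run the full pipeline at every concreteness threshold.

    For each theta the vocabulary is re-partitioned, the grounded space
    rebuilt, and LOCO-CV re-run per variant; the row records the abstract
    and concrete word counts and each variant's mean Pearson r over
    abstract, concrete and all words.  With two or more variants the row
    also carries pairwise significance flags on abstract-word scores
    (Holm-controlled Wilcoxon).
    """
    if not grid:
        raise ValueError("empty threshold grid")
    rows = []
    kept: dict[float, dict[str, CVResult]] = {}
    for theta in grid:
        partition = partition_vocabulary(lexicon, ratings, theta)
        grounded = build_grounded_space(lexicon, textual, visual, partition, neighbor_cfg)
        row: dict = {
            "theta_c": float(theta),
            "n_abstract": len(partition.abstract),
            "n_concrete": len(partition.concrete),
        }
        results: dict[str, CVResult] = {}
        for variant in variants:
            res = evaluate_variant(
                ModelSpec(variant), lexicon, textual, visual, grounded, partition,
                norms, cluster_sets, net_cfg, runs=runs, seed=seed,
            )
            results[variant] = res
            row[f"r_abstract_{variant}"] = res.mean_score("pearson", partition.abstract)
            row[f"r_concrete_{variant}"] = res.mean_score("pearson", partition.concrete)
            row[f"r_all_{variant}"] = res.mean_score("pearson")
        if len(variants) >= 2 and len(partition.abstract) >= 2:
            abs_words = [w for w in lexicon if w in partition.abstract]
            mat = pd.DataFrame(
                {v: results[v].scores.loc[abs_words, "pearson"] for v in variants}
            ).dropna()
            if len(mat) >= 2 and mat.std().min() >= 0:
                try:
                    cmp_res = compare_models(mat)
                    for _, prow in cmp_res.pairwise.iterrows():
                        row[f"sig_{prow['model_a']}_vs_{prow['model_b']}"] = bool(prow["significant"])
                except ValueError:
                    pass
        rows.append(row)
        if keep_results:
            kept[float(theta)] = results
    table = pd.DataFrame(rows)
    return (table, kept) if keep_results else table


def diff_analysis(
    results: dict[str, CVResult],
    ratings: ConcretenessTable,
    indirect: str = "indirect_grounding",
    baseline: str = "hybrid",
    interval_width: float = 0.25,
    rating_range: tuple[float, float] = (1.0, 5.0),
    category_map=None,
    min_words: int = 4,
    words: list[str] | None = None,
) -> dict:
    """Localize where indirect grounding helps via diff(r) = r_I - r_baseline.

    Returns a dict with: ``per_word`` (diff(r) and rating per word),
    ``concreteness_correlation`` (Pearson r of diff(r) with rating; NaN
    sentinel when diff(r) has zero variance, e.g. identical models),
    ``intervals`` (mean diff(r) per equal-width concreteness interval,
    with word counts), and — when a category map is supplied —
    ``categories`` (mean diff(r) per category with at least ``min_words``
    words).
    """
    if indirect not in results or baseline not in results:
        raise KeyError(f"results must contain {indirect!r} and {baseline!r}")
    r_i = results[indirect].scores["pearson"]
    r_b = results[baseline].scores["pearson"]
    if words is None:
        words = [w for w in r_i.index if w in r_b.index]
    per_word = pd.DataFrame(
        {
            "diff_r": [r_i[w] - r_b[w] for w in words],
            "rating": [ratings[w] for w in words],
        },
        index=words,
    )
    d = per_word["diff_r"].to_numpy()
    c = per_word["rating"].to_numpy()
    valid = np.isfinite(d)
    if valid.sum() >= 3 and np.std(d[valid]) > 0 and np.std(c[valid]) > 0:
        corr = float(stats.pearsonr(d[valid], c[valid]).statistic)
    else:
        corr = float("nan")
    lo, hi = rating_range
    edges = np.arange(lo, hi + interval_width / 2, interval_width)
    interval_rows = []
    for a, b in zip(edges[:-1], edges[1:]):
        last = np.isclose(b, edges[-1])
        mask = (c >= a) & ((c <= b) if last else (c < b))
        count = int(mask.sum())
        if count == 0:
            continue
        interval_rows.append(
            {
                "lower": float(a),
                "upper": float(b),
                "n_words": count,
                "mean_diff_r": float(np.nanmean(d[mask])),
            }
        )
    out = {
        "per_word": per_word,
        "concreteness_correlation": corr,
        "intervals": pd.DataFrame(interval_rows),
    }
    if category_map is not None:
        cat_rows = []
        by_cat: dict[str, list[float]] = {}
        for w, dv in zip(words, d):
            if w in category_map:
                by_cat.setdefault(category_map[w], []).append(dv)
        for cat in sorted(by_cat):
            vals = by_cat[cat]
            if len(vals) < min_words:
                continue
            cat_rows.append(
                {
                    "category": cat,
                    "cluster": category_map.clusters.get(cat, ""),
                    "n_words": len(vals),
                    "mean_diff_r": float(np.nanmean(vals)),
                }
            )
        out["categories"] = pd.DataFrame(cat_rows)
    return out


def per_word_threshold_curves(
    results_by_theta: dict[float, dict[str, CVResult]],
    words: list[str],
    variant: str = "indirect_grounding",
) -> pd.DataFrame:
    """Per-word correlation as a function of the concreteness threshold.

    One row per theta, one column per requested word — the raw material
    for per-word threshold-curve plots showing where a word benefits
    from being treated as abstract.
    """
    rows = []
    for theta in sorted(results_by_theta):
        res = results_by_theta[theta][variant]
        row = {"theta_c": theta}
        for w in words:
            row[w] = float(res.scores.loc[w, "pearson"]) if w in res.scores.index else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
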