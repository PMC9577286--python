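"""Self-contained synthetic worlds with controllable grounding structure.

Each world draws a latent semantic vector z(w) per word and projects it
into a textual space (t = A z + noise) and a visual space (per-image
features B z + noise).  Concrete words' images always depict their own
latent content.  Abstract words' images depict a mixture
``rho * z(w) + (1 - rho) * u(w)`` of their own content and an
independent draw u(w): the tag-reliability knob rho controls whether an
abstract word's own images are informative (rho = 1) or pure noise about
it (rho = 0).  Concept norms depend on the latent vector and on the
word's *true grounded content* v*(w) — its own projected content for
concrete words, the mean projected content of its nearest concrete
latent neighbors for abstract words — so a predictor only reaches the
grounded share of norm variance through visual information routed the
way the indirect-grounding hypothesis claims.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluation import cluster_words, evaluate_variant
from .grounding import ModelSpec, NeighborConfig, build_grounded_space, partition_vocabulary
from .lexdata import (
    ConceptNorms,
    ConcretenessTable,
    EmbeddingSpace,
    ImageFeatureSet,
    Lexicon,
    visual_space_from_images,
)
from .predictor import NetworkConfig

__all__ = ["SynthConfig", "SynthWorld", "generate_world", "regime_experiment"]


@dataclass(frozen=True)
class SynthConfig:
    """Synthetic-world parameters.

    Desk-scale defaults: 500 words (30% abstract), latent dimension 8,
    textual dimension 32, visual dimension 48, 16 norm attributes, 5
    images per word.  Ratings leave a margin around the default
    threshold 3.0 (concrete uniform on [3.5, 5], abstract on [1, 2.5])
    so partition recovery is unambiguous.  Noise standard deviations are
    0.1 against unit-variance signal components.  ``grounded_share``
    fixes the fraction of (noise-free) norm variance carried by the
    grounded content at 0.4.
    """

    n_words: int = 500
    abstract_fraction: float = 0.3
    latent_dim: int = 8
    d_text: int = 32
    d_vis: int = 48
    d_out: int = 16
    images_per_word: int = 5
    noise_sd_text: float = 0.1
    noise_sd_vis: float = 0.1
    noise_sd_out: float = 0.1
    tag_reliability: float = 1.0
    true_neighbor_count: int = 10
    concrete_rating_range: tuple[float, float] = (3.5, 5.0)
    abstract_rating_range: tuple[float, float] = (1.0, 2.5)
    grounded_share: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.tag_reliability <= 1.0):
            raise ValueError("tag_reliability must be in [0, 1]")
        if not (0.0 < self.abstract_fraction < 1.0):
            raise ValueError("abstract_fraction must be in (0, 1)")
        for name in ("n_words", "latent_dim", "d_text", "d_vis", "d_out", "images_per_word", "true_neighbor_count"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        n_abs = round(self.n_words * self.abstract_fraction)
        if n_abs == 0 or n_abs == self.n_words:
            raise ValueError("config yields no abstract or no concrete words")


@dataclass
class SynthWorld:
    """A generated world plus its generating ground truth."""

    config: SynthConfig
    lexicon: Lexicon
    ratings: ConcretenessTable
    textual: EmbeddingSpace
    image_features: ImageFeatureSet
    norms: ConceptNorms
    latent: dict[str, np.ndarray]
    true_grounded: dict[str, np.ndarray]  # v*(w)
    true_neighbors: dict[str, list[str]]  # abstract word -> latent-space concrete neighbors
    abstract_words: frozenset[str] = field(default_factory=frozenset)

    def visual_space(self) -> EmbeddingSpace:
        """Direct visual vectors: per-word image centroids."""
        return visual_space_from_images(self.image_features)


def _orthonormal_rows(rng: np.random.Generator, m: int, d: int) -> np.ndarray:
    """An m x d matrix with orthonormal rows (m <= d)."""
    if m > d:
        raise ValueError("latent dimension must not exceed the projected dimension")
    Q, _ = np.linalg.qr(rng.standard_normal((d, m)))
    return Q.T


def generate_world(cfg: SynthConfig) -> SynthWorld:
    """Draw a world; a pure function of the config (seed included)."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_words
    m = cfg.latent_dim
    n_abs = round(n * cfg.abstract_fraction)
    width = len(str(n))
    names = [f"w{i:0{width}d}" for i in range(n)]
    abstract_idx = rng.choice(n, size=n_abs, replace=False)
    is_abstract = np.zeros(n, dtype=bool)
    is_abstract[abstract_idx] = True

    ratings = np.where(
        is_abstract,
        rng.uniform(*cfg.abstract_rating_range, size=n),
        rng.uniform(*cfg.concrete_rating_range, size=n),
    )

    Z = rng.standard_normal((n, m))
    # random orthonormal-row projections: noiseless inner products (hence
    # cosines and neighborhoods) in the projected spaces match latent space
    # exactly; scaled for ~unit-variance output components
    A = _orthonormal_rows(rng, m, cfg.d_text) * np.sqrt(cfg.d_text / m)
    B = _orthonormal_rows(rng, m, cfg.d_vis) * np.sqrt(cfg.d_vis / m)
    T = Z @ A + cfg.noise_sd_text * rng.standard_normal((n, cfg.d_text))

    # image content: own latent for concrete; rho-mixture for abstract
    U = rng.standard_normal((n, m))
    rho = cfg.tag_reliability
    content = np.where(is_abstract[:, None], rho * Z + (1.0 - rho) * U, Z)
    images = {}
    for i, w in enumerate(names):
        base = content[i] @ B
        noise = cfg.noise_sd_vis * rng.standard_normal((cfg.images_per_word, cfg.d_vis))
        images[w] = base[None, :] + noise

    # true grounded content v*: own projection for concrete; mean projection
    # of the nearest concrete latent-space neighbors (by cosine) for abstract
    conc_idx = np.flatnonzero(~is_abstract)
    Zc = Z[conc_idx]
    Zc_norm = Zc / np.linalg.norm(Zc, axis=1, keepdims=True)
    v_star = np.empty((n, cfg.d_vis))
    true_neighbors: dict[str, list[str]] = {}
    for i in range(n):
        if not is_abstract[i]:
            v_star[i] = Z[i] @ B
            continue
        q = Z[i] / np.linalg.norm(Z[i])
        cos = Zc_norm @ q
        top = np.argsort(-cos, kind="stable")[: cfg.true_neighbor_count]
        nb_idx = conc_idx[top]
        true_neighbors[names[i]] = [names[j] for j in nb_idx]
        v_star[i] = Z[nb_idx].mean(axis=0) @ B

    C = rng.standard_normal((m, cfg.d_out)) / np.sqrt(m)
    D = rng.standard_normal((cfg.d_vis, cfg.d_out)) / np.sqrt(cfg.d_vis)
    y_lat = Z @ C
    y_grd = v_star @ D
    # rescale the grounded component so it carries `grounded_share` of the
    # noise-free norm variance
    share = cfg.grounded_share
    scale = np.sqrt((share / (1.0 - share)) * y_lat.var() / y_grd.var())
    Y = y_lat + scale * y_grd + cfg.noise_sd_out * rng.standard_normal((n, cfg.d_out))
    # per-attribute affine rescale into [0, 6]; clip guards float overshoot
    ymin, ymax = Y.min(axis=0), Y.max(axis=0)
    span = np.where(ymax > ymin, ymax - ymin, 1.0)
    Y = np.clip(6.0 * (Y - ymin) / span, 0.0, 6.0)

    return SynthWorld(
        config=cfg,
        lexicon=Lexicon(names),
        ratings=ConcretenessTable(dict(zip(names, ratings))),
        textual=EmbeddingSpace("textual", {w: T[i] for i, w in enumerate(names)}),
        image_features=ImageFeatureSet({w: images[w] for w in names}, min_images=cfg.images_per_word),
        norms=ConceptNorms(
            attribute_names=[f"attr{j:02d}" for j in range(cfg.d_out)],
            norms={w: Y[i] for i, w in enumerate(names)},
        ),
        latent={w: Z[i] for i, w in enumerate(names)},
        true_grounded={w: v_star[i] for i, w in enumerate(names)},
        true_neighbors=true_neighbors,
        abstract_words=frozenset(names[i] for i in range(n) if is_abstract[i]),
    )


def default_net_config(cfg: SynthConfig, epochs: int = 30) -> NetworkConfig:
    """Desk-scale network sized to a synthetic world (16/16 hidden units)."""
    return NetworkConfig(
        d_text_in=cfg.d_text,
        d_vis_in=cfg.d_vis,
        d_text_hidden=16,
        d_vis_hidden=16,
        d_out=cfg.d_out,
        epochs=epochs,
    )


def regime_experiment(
    cfg: SynthConfig,
    variants: list[str] = ["indirect_grounding", "hybrid"],
    theta_c: float = 3.0,
    net_cfg: NetworkConfig | None = None,
    n_seeds: int = 5,
    neighbor_cfg: NeighborConfig = NeighborConfig(),
    n_cluster_sets: int = 1,
    cluster_restarts: int = 20,
    n_clusters: int = 20,
    runs: int = 3,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Run the full pipeline over fresh worlds and summarize per variant.

    For each seed a world is generated from ``cfg`` (with that seed), the
    grounding and LOCO-CV evaluation pipeline is run for every requested
    variant, and mean Pearson r over abstract, concrete and all words is
    recorded.  The returned table has one row per (seed, variant) plus a
    ``delta_r_abstract`` summary column (indirect minus hybrid) when both
    variants are present.
    """
    rows = []
    for s in range(n_seeds):
        wseed = base_seed + s
        world = generate_world(dataclasses.replace(cfg, seed=wseed))
        visual = world.visual_space()
        partition = partition_vocabulary(world.lexicon, world.ratings, theta_c)
        grounded = build_grounded_space(world.lexicon, world.textual, visual, partition, neighbor_cfg)
        cluster_sets = cluster_words(
            world.textual,
            lexicon=world.lexicon,
            n_clusters=n_clusters,
            restarts=cluster_restarts,
            n_sets=n_cluster_sets,
            seed=wseed,
        )
        ncfg = net_cfg if net_cfg is not None else default_net_config(cfg)
        for variant in variants:
            res = evaluate_variant(
                ModelSpec(variant), world.lexicon, world.textual, visual, grounded,
                partition, world.norms, cluster_sets, ncfg, runs=runs, seed=wseed,
            )
            rows.append(
                {
                    "seed": wseed,
                    "variant": variant,
                    "r_abstract": res.mean_score("pearson", partition.abstract),
                    "r_concrete": res.mean_score("pearson", partition.concrete),
                    "r_all": res.mean_score("pearson"),
                }
            )
    table = pd.DataFrame(rows)
    if {"indirect_grounding", "hybrid"} <= set(variants):
        wide = table.pivot(index="seed", columns="variant", values="r_abstract")
        delta = wide["indirect_grounding"] - wide["hybrid"]
        table = table.merge(
            delta.rename("delta_r_abstract").reset_index(), on="seed", how="left"
        )
    return table
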