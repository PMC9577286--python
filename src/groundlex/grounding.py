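"""Indirect visual grounding: concreteness partition, semantic-neighbor
selection, and neighbor-averaged visual vectors.

The model's premise is that abstract concepts are grounded through
language: an abstract word's visual content is borrowed from the concrete
words it is most similar to in textual distributional space.  Concretely,
a word w is abstract when its concreteness rating falls below a threshold
theta_c.  For an abstract word, the top-N textual-cosine neighbors are
collected from the whole vocabulary, filtered to concrete words, and
truncated to the k highest-cosine survivors; the grounded vector g(w) is
the mean of those neighbors' direct visual vectors.  Concrete words keep
their own direct visual vector.  When the N-pool contains no concrete
word at all, w gets no visual vector and is represented textually only —
the two-stage N-then-k construction exists precisely so that highly
abstract words without concrete associates are left ungrounded rather
than forced onto distant images.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lexdata import ConcretenessTable, EmbeddingSpace, Lexicon

__all__ = [
    "VocabularyPartition",
    "NeighborConfig",
    "GroundedSpace",
    "ModelSpec",
    "MODEL_VARIANTS",
    "partition_vocabulary",
    "select_semantic_neighbors",
    "build_grounded_space",
    "indirect_visual_vector",
    "model_inputs",
    "IndirectGroundingTransformer",
]


@dataclass(frozen=True)
class VocabularyPartition:
    """Split of the lexicon into concrete (V_C) and abstract (V_A) words.

    A word is abstract iff its rating is strictly below ``theta_c``.
    """

    theta_c: float
    concrete: frozenset[str]
    abstract: frozenset[str]

    def __post_init__(self) -> None:
        if self.concrete & self.abstract:
            raise ValueError("concrete and abstract sets overlap")

    def is_abstract(self, word: str) -> bool:
        if word in self.abstract:
            return True
        if word in self.concrete:
            return False
        raise KeyError(f"word {word!r} not in partition")


@dataclass(frozen=True)
class NeighborConfig:
    """Semantic-neighbor selection parameters.

    N is the size of the overall nearest-neighbor candidate pool and k the
    number of concrete neighbors retained from it (N > k).  Defaults
    N=300, k=10 are the grid-search optimum of the reference experiments.
    """

    N: int = 300
    k: int = 10

    def __post_init__(self) -> None:
        if self.k < 1 or self.N < 1:
            raise ValueError("N and k must be positive")
        if self.N <= self.k:
            raise ValueError(f"need N > k, got N={self.N}, k={self.k}")


@dataclass
class GroundedSpace:
    """Word -> optional grounded visual vector g(w).

    ``textual_only`` collects abstract words whose neighbor set came back
    empty; they carry no grounded vector.  ``neighbor_log`` records, for
    each abstract word, the ordered neighbor list its vector was averaged
    from (empty list for textual-only words).
    """

    dim: int
    grounded: dict[str, np.ndarray]
    textual_only: set[str] = field(default_factory=set)
    neighbor_log: dict[str, list[str]] = field(default_factory=dict)

    def __contains__(self, word: object) -> bool:
        return word in self.grounded

    def __getitem__(self, word: str) -> np.ndarray:
        return self.grounded[word]

    def as_embedding_space(self) -> EmbeddingSpace:
        return EmbeddingSpace(label="grounded", vectors=self.grounded, dim=self.dim)


def partition_vocabulary(
    lexicon: Lexicon, ratings: ConcretenessTable, theta_c: float
) -> VocabularyPartition:
    """Partition the lexicon by the concreteness threshold.

    Strict comparison: rating < theta_c -> abstract, otherwise concrete.
    """
    concrete, abstract = [], []
    for w in lexicon:
        if w not in ratings:
            raise KeyError(f"word {w!r} has no concreteness rating")
        (abstract if ratings[w] < theta_c else concrete).append(w)
    return VocabularyPartition(
        theta_c=float(theta_c), concrete=frozenset(concrete), abstract=frozenset(abstract)
    )


def _cosine_row(query: np.ndarray, mat: np.ndarray) -> np.ndarray:
    """Cosines between one query and the rows of mat; zero-norm rows -> -inf."""
    qn = np.linalg.norm(query)
    norms = np.linalg.norm(mat, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = (mat @ query) / (norms * qn)
    cos[~np.isfinite(cos)] = -np.inf
    return cos


def select_semantic_neighbors(
    word: str,
    textual: EmbeddingSpace,
    partition: VocabularyPartition,
    cfg: NeighborConfig,
    lexicon: Lexicon | None = None,
) -> list[str]:
    """Pick a word's concrete semantic neighbors SN_k(w).

    Two-stage procedure: rank every other lexicon word by textual cosine
    similarity, keep the top N, filter that pool to concrete words, then
    truncate to the k highest-cosine survivors (descending cosine; ties
    broken lexicographically for cross-platform determinism).  The result
    may hold fewer than k words — or none, when the N-pool contains no
    concrete word.  Words with zero-norm textual vectors have no defined
    cosine: they are never selected, and as queries they yield [].
    """
    if word not in textual:
        raise KeyError(f"word {word!r} not in textual space")
    words = list(lexicon) if lexicon is not None else list(textual.words())
    candidates = [w for w in words if w != word and w in textual]
    if not candidates:
        return []
    query = textual[word]
    if np.linalg.norm(query) == 0.0:
        return []
    mat = textual.matrix(candidates)
    cos = _cosine_row(query, mat)
    order = sorted(range(len(candidates)), key=lambda i: (-cos[i], candidates[i]))
    # top-N pool, dropping undefined (zero-norm) candidates
    pool = [candidates[i] for i in order if np.isfinite(cos[i])][: cfg.N]
    return [w for w in pool if w in partition.concrete][: cfg.k]


def indirect_visual_vector(
    word: str,
    partition: VocabularyPartition,
    visual: EmbeddingSpace,
    neighbors: list[str],
) -> np.ndarray | None:
    """Grounded vector g(w) for one word.

    Concrete words pass their direct visual vector through unchanged.
    Abstract words receive the elementwise mean of their m >= 1 neighbors'
    visual vectors (mean over the neighbors actually found, so a short
    neighbor list is averaged over m rather than diluted by k); with no
    neighbors the word is textual-only and the result is None.
    """
    if not partition.is_abstract(word):
        if word not in visual:
            raise KeyError(f"concrete word {word!r} lacks a direct visual vector")
        return visual[word]
    if not neighbors:
        return None
    bad = [n for n in neighbors if n not in partition.concrete]
    if bad:
        raise ValueError(f"neighbors {bad} of {word!r} are not concrete")
    missing = [n for n in neighbors if n not in visual]
    if missing:
        raise KeyError(f"neighbors {missing} of {word!r} lack visual vectors")
    return visual.matrix(neighbors).mean(axis=0)


def build_grounded_space(
    lexicon: Lexicon,
    textual: EmbeddingSpace,
    visual: EmbeddingSpace,
    partition: VocabularyPartition,
    cfg: NeighborConfig,
) -> GroundedSpace:
    """Compute g(w) for every lexicon word.

    With theta_c at or below the minimum rating every word is concrete
    and the result is vector-for-vector identical to the direct visual
    space; with theta_c above the maximum rating V_C is empty and every
    word is textual-only.
    """
    grounded: dict[str, np.ndarray] = {}
    textual_only: set[str] = set()
    neighbor_log: dict[str, list[str]] = {}
    for w in lexicon:
        if partition.is_abstract(w):
            nb = select_semantic_neighbors(w, textual, partition, cfg, lexicon=lexicon)
            neighbor_log[w] = nb
            g = indirect_visual_vector(w, partition, visual, nb)
            if g is None:
                textual_only.add(w)
            else:
                grounded[w] = g
        else:
            grounded[w] = indirect_visual_vector(w, partition, visual, [])
    return GroundedSpace(
        dim=visual.dim, grounded=grounded, textual_only=textual_only, neighbor_log=neighbor_log
    )


# ---------------------------------------------------------------------------
# Model variants

# per-word input contract: (use_textual, visual_source)
_CONTRACTS: dict[str, tuple[bool, str]] = {
    "indirect_grounding": (True, "grounded"),
    "hybrid": (True, "direct"),
    "dual_coding": (True, "direct_concrete_only"),
    "visual": (False, "direct"),
    "textual": (True, "none"),
    "indirect_visual": (False, "grounded"),
}

MODEL_VARIANTS: tuple[str, ...] = tuple(_CONTRACTS)


@dataclass(frozen=True)
class ModelSpec:
    """One of the six model variants and its per-word input contract.

    - ``indirect_grounding``: textual + grounded visual (textual-only
      words degrade to textual alone);
    - ``hybrid``: textual + direct visual for every word;
    - ``dual_coding``: textual + direct visual for concrete words,
      textual alone for abstract words;
    - ``visual``: direct visual only;
    - ``textual``: textual only;
    - ``indirect_visual``: grounded visual only.
    """

    variant: str

    def __post_init__(self) -> None:
        if self.variant not in _CONTRACTS:
            raise ValueError(f"unknown model variant {self.variant!r}; choose from {MODEL_VARIANTS}")

    @property
    def uses_textual(self) -> bool:
        return _CONTRACTS[self.variant][0]

    @property
    def visual_source(self) -> str:
        return _CONTRACTS[self.variant][1]


def model_inputs(
    spec: ModelSpec,
    word: str,
    textual: EmbeddingSpace,
    visual: EmbeddingSpace,
    grounded: GroundedSpace,
    partition: VocabularyPartition,
) -> tuple[np.ndarray | None, np.ndarray | None]:
    """Resolve one word's (textual, visual) input pair under a variant's contract."""
    t = textual[word] if spec.uses_textual else None
    src = spec.visual_source
    if src == "none":
        v = None
    elif src == "direct":
        if word not in visual:
            raise KeyError(f"variant {spec.variant!r} requires a direct visual vector for {word!r}")
        v = visual[word]
    elif src == "direct_concrete_only":
        if partition.is_abstract(word):
            v = None
        else:
            if word not in visual:
                raise KeyError(f"concrete word {word!r} lacks a direct visual vector")
            v = visual[word]
    elif src == "grounded":
        if word in grounded:
            v = grounded[word]
        elif word in grounded.textual_only:
            if not spec.uses_textual:
                raise KeyError(
                    f"variant {spec.variant!r} has no input for textual-only word {word!r}"
                )
            v = None
        else:
            raise KeyError(f"word {word!r} not in grounded space")
    else:  # pragma: no cover
        raise AssertionError(src)
    if t is None and v is None and src != "direct_concrete_only" and spec.variant != "indirect_visual":
        raise KeyError(f"no inputs for word {word!r} under variant {spec.variant!r}")
    return t, v


class IndirectGroundingTransformer:
    """Estimator-style wrapper around the grounding construction.

    Follows the scikit-learn parameter protocol (``get_params`` /
    ``set_params``, fitted attributes with trailing underscores).  ``fit``
    consumes the lexical resources and builds the partition and grounded
    space; ``transform`` maps words to their grounded vectors (rows of
    NaN for textual-only words).
    """

    def __init__(self, theta_c: float = 3.0, N: int = 300, k: int = 10) -> None:
        self.theta_c = theta_c
        self.N = N
        self.k = k

    def get_params(self, deep: bool = True) -> dict:
        return {"theta_c": self.theta_c, "N": self.N, "k": self.k}

    def set_params(self, **params) -> "IndirectGroundingTransformer":
        for key, val in params.items():
            if key not in ("theta_c", "N", "k"):
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, val)
        return self

    def fit(
        self,
        lexicon: Lexicon,
        textual: EmbeddingSpace,
        visual: EmbeddingSpace,
        ratings: ConcretenessTable,
    ) -> "IndirectGroundingTransformer":
        self.partition_ = partition_vocabulary(lexicon, ratings, self.theta_c)
        self.grounded_ = build_grounded_space(
            lexicon, textual, visual, self.partition_, NeighborConfig(N=self.N, k=self.k)
        )
        self.lexicon_ = lexicon
        return self

    def transform(self, words: list[str]) -> np.ndarray:
        if not hasattr(self, "grounded_"):
            raise RuntimeError("transformer is not fitted")
        out = np.full((len(words), self.grounded_.dim), np.nan)
        for i, w in enumerate(words):
            if w in self.grounded_:
                out[i] = self.grounded_[w]
            elif w not in self.grounded_.textual_only:
                raise KeyError(f"word {w!r} was not seen during fit")
        return out

    def fit_transform(self, lexicon, textual, visual, ratings) -> np.ndarray:
        return self.fit(lexicon, textual, visual, ratings).transform(list(lexicon))
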