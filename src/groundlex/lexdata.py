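"""Domain types and plain-text I/O for lexical resources.

Everything downstream consumes four kinds of tables: word embeddings
(textual, visual or grounded) in the word2vec text dialect, per-image
feature vectors, concreteness ratings on the 1-5 Brysbaert scale, and
real-valued concept norms (featural attribute ratings, 0-6 scale by
default).  Words are matched by exact surface form after stripping
surrounding whitespace; no case folding is applied, because silently
merging distinct surface forms across resources corrupts vocabularies.
Duplicate words in any table are a hard error for the same reason.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Lexicon",
    "EmbeddingSpace",
    "ImageFeatureSet",
    "ConcretenessTable",
    "ConceptNorms",
    "CategoryMap",
    "read_embeddings",
    "write_embeddings",
    "read_word_table",
    "image_centroid",
    "build_lexicon",
]


def _normalize_word(word: str) -> str:
    w = str(word).strip()
    if not w:
        raise ValueError("empty word after whitespace normalization")
    return w


class Lexicon:
    """Ordered set of unique words; iteration follows insertion order."""

    def __init__(self, words: Iterable[str]) -> None:
        seen: dict[str, None] = {}
        for w in words:
            w = _normalize_word(w)
            if w in seen:
                raise ValueError(f"duplicate word in lexicon: {w!r}")
            seen[w] = None
        self._words: tuple[str, ...] = tuple(seen)
        self._set = frozenset(self._words)

    @property
    def words(self) -> tuple[str, ...]:
        return self._words

    def __iter__(self) -> Iterator[str]:
        return iter(self._words)

    def __len__(self) -> int:
        return len(self._words)

    def __contains__(self, word: object) -> bool:
        return word in self._set

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Lexicon) and self._words == other._words

    def __repr__(self) -> str:
        return f"Lexicon({len(self._words)} words)"


class EmbeddingSpace:
    """A word -> fixed-dimension real vector map.

    Parameters
    ----------
    label : str
        One of ``"textual"``, ``"visual"``, ``"grounded"``.
    vectors : mapping of word to 1-d array
        All vectors must share one dimension.
    dim : int, optional
        Expected dimension; inferred from the first vector if omitted.
    """

    VALID_LABELS = ("textual", "visual", "grounded")

    def __init__(self, label: str, vectors: Mapping[str, np.ndarray], dim: int | None = None) -> None:
        if label not in self.VALID_LABELS:
            raise ValueError(f"label must be one of {self.VALID_LABELS}, got {label!r}")
        self.label = label
        store: dict[str, np.ndarray] = {}
        for w, v in vectors.items():
            w = _normalize_word(w)
            if w in store:
                raise ValueError(f"duplicate word in embedding space: {w!r}")
            arr = np.asarray(v, dtype=np.float64)
            if arr.ndim != 1:
                raise ValueError(f"vector for {w!r} is not 1-dimensional")
            if dim is None:
                dim = arr.shape[0]
            if arr.shape[0] != dim:
                raise ValueError(
                    f"vector for {w!r} has length {arr.shape[0]}, expected {dim}"
                )
            store[w] = arr
        if dim is None or dim <= 0:
            raise ValueError("embedding dimension must be a positive integer")
        self.dim = int(dim)
        self.vectors = store

    def __contains__(self, word: object) -> bool:
        return word in self.vectors

    def __getitem__(self, word: str) -> np.ndarray:
        try:
            return self.vectors[word]
        except KeyError:
            raise KeyError(f"word {word!r} not in {self.label} embedding space") from None

    def __len__(self) -> int:
        return len(self.vectors)

    def words(self) -> tuple[str, ...]:
        return tuple(self.vectors)

    def matrix(self, words: Sequence[str]) -> np.ndarray:
        """Stack vectors for ``words`` into an (n, dim) array."""
        return np.stack([self[w] for w in words]) if len(words) else np.empty((0, self.dim))

    def __repr__(self) -> str:
        return f"EmbeddingSpace(label={self.label!r}, n={len(self)}, dim={self.dim})"


@dataclass
class ImageFeatureSet:
    """Per-image feature vectors grouped by word.

    ``features[word]`` is an (n_images, dim) array; all words share one
    feature dimension.  ``min_images`` is the filtering threshold applied
    at lexicon construction (20 in the reference setting: words need at
    least 20 associated images to enter the vocabulary).
    """

    features: dict[str, np.ndarray]
    min_images: int = 20

    def __post_init__(self) -> None:
        dim: int | None = None
        clean: dict[str, np.ndarray] = {}
        for w, mats in self.features.items():
            w = _normalize_word(w)
            if w in clean:
                raise ValueError(f"duplicate word in image feature set: {w!r}")
            arr = np.asarray(mats, dtype=np.float64)
            if arr.ndim != 2 or arr.shape[0] < 1:
                raise ValueError(f"features for {w!r} must be a non-empty list of vectors")
            if dim is None:
                dim = arr.shape[1]
            if arr.shape[1] != dim:
                raise ValueError(f"features for {w!r} have dimension {arr.shape[1]}, expected {dim}")
            clean[w] = arr
        self.features = clean
        self.dim = dim

    def n_images(self, word: str) -> int:
        return self.features[word].shape[0] if word in self.features else 0

    def __contains__(self, word: object) -> bool:
        return word in self.features


@dataclass
class ConcretenessTable:
    """Word -> concreteness rating on the closed interval [1, 5]."""

    ratings: dict[str, float]

    def __post_init__(self) -> None:
        clean: dict[str, float] = {}
        for w, r in self.ratings.items():
            w = _normalize_word(w)
            if w in clean:
                raise ValueError(f"duplicate word in concreteness table: {w!r}")
            r = float(r)
            if not (1.0 <= r <= 5.0):
                raise ValueError(f"concreteness rating for {w!r} is {r}, outside [1, 5]")
            clean[w] = r
        self.ratings = clean

    def __getitem__(self, word: str) -> float:
        try:
            return self.ratings[word]
        except KeyError:
            raise KeyError(f"word {word!r} has no concreteness rating") from None

    def __contains__(self, word: object) -> bool:
        return word in self.ratings

    def __len__(self) -> int:
        return len(self.ratings)


@dataclass
class ConceptNorms:
    """Per-word real-valued attribute vectors (feature norms).

    The reference norms are 65 brain-motivated attributes rated 0-6; the
    attribute count M and value range are configurable.
    """

    attribute_names: list[str]
    norms: dict[str, np.ndarray]
    value_range: tuple[float, float] = (0.0, 6.0)

    def __post_init__(self) -> None:
        m = len(self.attribute_names)
        if m < 1:
            raise ValueError("concept norms need at least one attribute")
        clean: dict[str, np.ndarray] = {}
        for w, v in self.norms.items():
            w = _normalize_word(w)
            if w in clean:
                raise ValueError(f"duplicate word in concept norms: {w!r}")
            arr = np.asarray(v, dtype=np.float64)
            if arr.shape != (m,):
                raise ValueError(f"norm vector for {w!r} has shape {arr.shape}, expected ({m},)")
            clean[w] = arr
        self.norms = clean

    @property
    def n_attributes(self) -> int:
        return len(self.attribute_names)

    def __getitem__(self, word: str) -> np.ndarray:
        try:
            return self.norms[word]
        except KeyError:
            raise KeyError(f"word {word!r} has no concept norms") from None

    def __contains__(self, word: object) -> bool:
        return word in self.norms

    def matrix(self, words: Sequence[str]) -> np.ndarray:
        return np.stack([self[w] for w in words]) if len(words) else np.empty((0, self.n_attributes))


@dataclass
class CategoryMap:
    """Word -> semantic category, with optional category -> supercluster grouping."""

    categories: dict[str, str]
    clusters: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, str] = {}
        for w, c in self.categories.items():
            w = _normalize_word(w)
            c = str(c).strip()
            if not c:
                raise ValueError(f"empty category label for word {w!r}")
            if w in clean:
                raise ValueError(f"duplicate word in category map: {w!r}")
            clean[w] = c
        self.categories = clean
        self.clusters = {str(k).strip(): str(v).strip() for k, v in self.clusters.items()}

    def __getitem__(self, word: str) -> str:
        return self.categories[word]

    def __contains__(self, word: object) -> bool:
        return word in self.categories


# ---------------------------------------------------------------------------
# Readers / writers


def read_embeddings(
    path: str | Path,
    label: str = "textual",
    expected_dim: int | None = None,
) -> EmbeddingSpace:
    """Read an embedding space from the word2vec text dialect.

    The file holds an optional ``"<n> <dim>"`` header line followed by one
    record per line: a word, then ``dim`` whitespace-separated reals.
    Both headered and headerless files are accepted; the dimension is
    inferred from the first record when no header is present.

    Raises
    ------
    ValueError
        On duplicate words (named in the message), rows whose length
        disagrees with the dimension (with line number), or a mismatch
        with ``expected_dim``.
    """
    path = Path(path)
    vectors: dict[str, np.ndarray] = {}
    dim: int | None = None
    declared_n: int | None = None
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if lineno == 1 and len(parts) == 2:
                try:
                    declared_n, dim = int(parts[0]), int(parts[1])
                    if dim <= 0 or declared_n < 0:
                        raise ValueError
                    continue
                except ValueError:
                    declared_n, dim = None, None  # not a header after all
            word, vals = parts[0], parts[1:]
            try:
                vec = np.array([float(x) for x in vals], dtype=np.float64)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric embedding value") from exc
            if dim is None:
                dim = vec.shape[0]
            if vec.shape[0] != dim:
                raise ValueError(
                    f"{path}:{lineno}: row has {vec.shape[0]} values, expected {dim}"
                )
            word = _normalize_word(word)
            if word in vectors:
                raise ValueError(f"{path}:{lineno}: duplicate word {word!r}")
            vectors[word] = vec
    if not vectors:
        raise ValueError(f"{path}: empty embedding file")
    if declared_n is not None and declared_n != len(vectors):
        raise ValueError(
            f"{path}: header declares {declared_n} records but file has {len(vectors)}"
        )
    if expected_dim is not None and dim != expected_dim:
        raise ValueError(f"{path}: dimension {dim} does not match expected {expected_dim}")
    return EmbeddingSpace(label=label, vectors=vectors, dim=dim)


def write_embeddings(space: EmbeddingSpace, path: str | Path, header: bool = True) -> None:
    """Write an embedding space in the word2vec text dialect.

    Values are printed with 17 significant digits, which round-trips
    float64 bit-exactly through :func:`read_embeddings`.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        if header:
            fh.write(f"{len(space)} {space.dim}\n")
        for w, v in space.vectors.items():
            fh.write(w + " " + " ".join(f"{x:.17g}" for x in v) + "\n")


def read_image_features(path: str | Path, min_images: int = 20) -> ImageFeatureSet:
    """Read per-image feature vectors: one image per line, ``word v1 ... vd``.

    Words repeat across lines (one line per image); images are grouped in
    file order.
    """
    path = Path(path)
    groups: dict[str, list[np.ndarray]] = {}
    dim: int | None = None
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            word, vals = _normalize_word(parts[0]), parts[1:]
            try:
                vec = np.array([float(x) for x in vals], dtype=np.float64)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric feature value") from exc
            if dim is None:
                dim = vec.shape[0]
            if vec.shape[0] != dim:
                raise ValueError(f"{path}:{lineno}: row has {vec.shape[0]} values, expected {dim}")
            groups.setdefault(word, []).append(vec)
    if not groups:
        raise ValueError(f"{path}: empty image feature file")
    return ImageFeatureSet(
        features={w: np.stack(v) for w, v in groups.items()}, min_images=min_images
    )


def write_image_features(features: ImageFeatureSet, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for w, mats in features.features.items():
            for row in mats:
                fh.write(w + " " + " ".join(f"{x:.17g}" for x in row) + "\n")


def read_word_table(path: str | Path, kind: str):
    """Read a header-bearing TSV whose first column is the word.

    ``kind`` selects the target type: ``"ratings"`` ->
    :class:`ConcretenessTable` (single numeric column, range-checked to
    [1, 5]); ``"norms"`` -> :class:`ConceptNorms` (M numeric attribute
    columns); ``"categories"`` -> :class:`CategoryMap` (category column,
    optional supercluster column).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.empty or df.shape[1] < 2:
        raise ValueError(f"{path}: empty or single-column table")
    words = [_normalize_word(w) for w in df.iloc[:, 0]]
    if len(set(words)) != len(words):
        dupes = sorted({w for w in words if words.count(w) > 1})
        raise ValueError(f"{path}: duplicate words {dupes[:5]}")
    if kind == "ratings":
        try:
            vals = df.iloc[:, 1].astype(np.float64)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: non-numeric rating value") from exc
        return ConcretenessTable(ratings=dict(zip(words, vals)))
    if kind == "norms":
        attrs = [str(c) for c in df.columns[1:]]
        try:
            mat = df.iloc[:, 1:].astype(np.float64).to_numpy()
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: non-numeric norm value") from exc
        return ConceptNorms(attribute_names=attrs, norms={w: mat[i] for i, w in enumerate(words)})
    if kind == "categories":
        cats = dict(zip(words, df.iloc[:, 1].astype(str)))
        clusters: dict[str, str] = {}
        if df.shape[1] >= 3:
            for w, cat, clu in zip(words, df.iloc[:, 1], df.iloc[:, 2]):
                if isinstance(clu, str) and clu.strip():
                    clusters[str(cat).strip()] = clu.strip()
        return CategoryMap(categories=cats, clusters=clusters)
    raise ValueError(f"unknown table kind {kind!r}")


# ---------------------------------------------------------------------------
# Operations


def image_centroid(features: ImageFeatureSet, word: str) -> np.ndarray:
    """Elementwise mean of a word's per-image feature vectors.

    This is the direct visual vector: the centroid of the deep-network
    activation vectors of the images tagged with the word.
    """
    if word not in features:
        raise KeyError(f"word {word!r} has no image features")
    mats = features.features[word]
    return mats.mean(axis=0)


def visual_space_from_images(features: ImageFeatureSet, words: Iterable[str] | None = None) -> EmbeddingSpace:
    """Centroid every word's image stack into a visual embedding space."""
    words = list(words) if words is not None else list(features.features)
    return EmbeddingSpace(
        label="visual",
        vectors={w: image_centroid(features, w) for w in words},
    )


def build_lexicon(
    textual: EmbeddingSpace,
    ratings: ConcretenessTable,
    features_or_visual: ImageFeatureSet | EmbeddingSpace,
    min_images: int = 20,
) -> Lexicon:
    """Intersect resources into the working vocabulary.

    A word enters the lexicon when it has a textual vector, a
    concreteness rating, and either at least ``min_images`` per-image
    feature vectors or (when a precomputed visual space is supplied) a
    visual vector.  Order follows the textual space, so the result is
    deterministic.
    """
    kept = []
    for w in textual.words():
        if w not in ratings:
            continue
        if isinstance(features_or_visual, ImageFeatureSet):
            if features_or_visual.n_images(w) < min_images:
                continue
        else:
            if w not in features_or_visual:
                continue
        kept.append(w)
    if not kept:
        raise ValueError("lexicon construction produced an empty vocabulary")
    return Lexicon(kept)
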