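"""Query expansion with k-nearest neighbours in a word-embedding space.

Two weighting models are provided. Model 1 keeps every original term at
unit weight and adds its k nearest vocabulary terms weighted by cosine
similarity. Model 2 additionally down-weights each *non key-relevant*
original term and all of its expansions by a loss factor ``l`` (default 1%).
A query term is *key-relevant* when its collection document frequency is at
or below the median document frequency of the query's terms — rare terms
carry the query's discriminative content.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np

from .preprocess import normalize

if TYPE_CHECKING:  # pragma: no cover
    from .index import InvertedIndex

logger = logging.getLogger(__name__)

__all__ = [
    "EmbeddingSpace",
    "QueryTerm",
    "WeightedQuery",
    "classify_key_relevance",
    "expand",
    "train_embeddings",
]

RELEVANT = "relevant"
KEY_RELEVANT = "key-relevant"


class EmbeddingSpace:
    """Term -> dense vector table; similarity is cosine."""

    def __init__(self, vectors: Mapping[str, Sequence[float]]):
        if not vectors:
            self.terms: list[str] = []
            self.matrix = np.zeros((0, 0))
        else:
            dims = {len(v) for v in vectors.values()}
            if len(dims) != 1:
                raise ValueError(f"inconsistent vector dimensionalities: {sorted(dims)}")
            self.terms = list(vectors)
            self.matrix = np.asarray([vectors[t] for t in self.terms], dtype=float)
        self._row = {t: i for i, t in enumerate(self.terms)}
        norms = np.linalg.norm(self.matrix, axis=1) if len(self.terms) else np.zeros(0)
        norms[norms == 0] = 1.0
        self._unit = self.matrix / norms[:, None] if len(self.terms) else self.matrix

    @property
    def dim(self) -> int:
        return self.matrix.shape[1] if self.matrix.size else 0

    def __contains__(self, term: str) -> bool:
        return term in self._row

    def __len__(self) -> int:
        return len(self.terms)

    def vector(self, term: str) -> np.ndarray:
        return self.matrix[self._row[term]]

    def cosine(self, a: str, b: str) -> float:
        return float(self._unit[self._row[a]] @ self._unit[self._row[b]])

    def nearest(
        self,
        term: str,
        k: int,
        exclude: Iterable[str] = (),
        min_similarity: float = 0.0,
    ) -> list[tuple[str, float]]:
        """Top-k vocabulary terms by cosine to ``term``, the term itself and
        ``exclude`` left out; ties at the cut broken lexicographically."""
        if term not in self._row or k <= 0:
            return []
        excluded = set(exclude) | {term}
        sims = self._unit @ self._unit[self._row[term]]
        candidates = [
            (t, float(sims[i]))
            for i, t in enumerate(self.terms)
            if t not in excluded and (min_similarity <= 0 or sims[i] >= min_similarity)
        ]
        candidates.sort(key=lambda e: (-e[1], e[0]))
        if k > len(candidates):
            logger.warning(
                "requested k=%d neighbours of %r but only %d available", k, term, len(candidates)
            )
        return candidates[:k]

    # -- persistence (word2vec text format) ---------------------------------

    def save(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{len(self.terms)} {self.dim}\n")
            for term in self.terms:
                vec = " ".join(f"{x:.8g}" for x in self.vector(term))
                fh.write(f"{term} {vec}\n")

    @classmethod
    def load(cls, path: str | Path) -> "EmbeddingSpace":
        vectors: dict[str, list[float]] = {}
        with open(path, "r", encoding="utf-8", errors="replace") as fh:
            header = fh.readline().split()
            if len(header) != 2:
                raise ValueError(f"{path}:1: expected 'count dim' header")
            _, dim = (int(x) for x in header)
            for lineno, line in enumerate(fh, 2):
                if not line.strip():
                    continue
                fields = line.split()
                if len(fields) != dim + 1:
                    raise ValueError(
                        f"{path}:{lineno}: expected {dim + 1} fields, got {len(fields)}"
                    )
                term = fields[0]
                if term in vectors:
                    logger.warning("%s:%d: duplicate term %r; last wins", path, lineno, term)
                vectors[term] = [float(x) for x in fields[1:]]
        return cls(vectors)


@dataclass(frozen=True)
class QueryTerm:
    term: str
    weight: float
    origin: str = "original"  # original | expanded
    parent: str | None = None
    relevance_class: str = RELEVANT


@dataclass
class WeightedQuery:
    """Per-term weights after cleaning/expansion.

    ``terms`` lists original terms (query order) before expansions
    (descending weight); ``length`` is the number of original non-stopword
    terms (the L of the ranking model).
    """

    terms: list[QueryTerm]
    length: int

    @property
    def originals(self) -> list[QueryTerm]:
        return [t for t in self.terms if t.origin == "original"]

    @property
    def expansions(self) -> list[QueryTerm]:
        return [t for t in self.terms if t.origin == "expanded"]

    def weight_of(self, term: str) -> float:
        for t in self.terms:
            if t.term == term:
                return t.weight
        return 0.0

    @classmethod
    def from_tokens(cls, tokens: Iterable[str]) -> "WeightedQuery":
        """Unexpanded, unit-weight query (all terms treated as relevant)."""
        seen: list[str] = []
        for t in tokens:
            if t not in seen:
                seen.append(t)
        return cls([QueryTerm(t, 1.0) for t in seen], length=len(seen))


def classify_key_relevance(
    terms: Sequence[str],
    index: "InvertedIndex",
) -> dict[str, str]:
    """Split query terms into relevant / key-relevant by document frequency.

    A term is key-relevant iff its collection document frequency is at or
    below the median of the query terms' document frequencies (even-count
    median = mean of the middle pair). Terms absent from the index (df = 0)
    are always key-relevant.
    """
    uniq = list(dict.fromkeys(terms))
    if not uniq:
        raise ValueError("cannot classify an empty term list")
    dfs = {t: index.document_frequency(t) for t in uniq}
    med = float(np.median([dfs[t] for t in uniq]))
    return {t: (KEY_RELEVANT if dfs[t] <= med else RELEVANT) for t in uniq}


def expand(
    query: Sequence[str],
    space: EmbeddingSpace | None = None,
    k: int = 10,
    model: int = 1,
    l: float = 0.01,
    index: "InvertedIndex | None" = None,
    min_similarity: float = 0.0,
    loss_mode: str = "reduce",
) -> WeightedQuery:
    """Expand a cleaned query with its k nearest embedded neighbours.

    Parameters
    ----------
    query:
        normalized query tokens (the originals keep weight 1).
    k:
        neighbours per term (default 10); ``k=0`` disables expansion.
    model:
        1 = cosine weights only; 2 = weights of non-key-relevant originals
        and their expansions reduced by the loss factor ``l``.
    l:
        loss factor in [0, 1] (default 1%). ``loss_mode='reduce'`` multiplies
        by (1 - l); ``loss_mode='multiply'`` multiplies by l itself.
    min_similarity:
        optional cosine cut-off on expansion candidates (0 = off).

    Out-of-vocabulary terms stay in the query but contribute no expansions.
    Expansion candidates are re-normalized through the text pipeline so they
    match index terms; duplicates keep the maximum weight. Expanded terms
    inherit the relevance class of their parent.
    """
    if model not in (1, 2):
        raise ValueError(f"model must be 1 or 2, got {model}")
    if not 0.0 <= l <= 1.0:
        raise ValueError(f"loss factor must lie in [0, 1], got {l}")
    if k < 0:
        raise ValueError(f"k must be >= 0, got {k}")
    if loss_mode not in ("reduce", "multiply"):
        raise ValueError(f"loss_mode must be 'reduce' or 'multiply', got {loss_mode}")

    originals = list(dict.fromkeys(query))
    if not originals:
        return WeightedQuery([], length=0)

    if index is not None:
        classes = classify_key_relevance(originals, index)
    else:
        if model == 2:
            raise ValueError("model 2 requires an index to classify key relevance")
        classes = {t: RELEVANT for t in originals}

    factor = (1.0 - l) if loss_mode == "reduce" else l
    penalized = {t for t in originals if model == 2 and classes[t] != KEY_RELEVANT}

    entries: list[QueryTerm] = []
    for t in originals:
        w = factor if t in penalized else 1.0
        entries.append(QueryTerm(t, w, origin="original", relevance_class=classes[t]))

    expanded: dict[str, QueryTerm] = {}
    if space is not None and k > 0:
        original_set = set(originals)
        for t in originals:
            if t not in space:
                continue
            for neigh, cos in space.nearest(
                t, k, exclude=original_set, min_similarity=min_similarity
            ):
                if cos <= 0:
                    continue
                for norm_tok in dict.fromkeys(normalize(neigh, mode="corpus")):
                    if norm_tok in original_set:
                        continue
                    w = cos * (factor if t in penalized else 1.0)
                    prev = expanded.get(norm_tok)
                    if prev is None or w > prev.weight:
                        expanded[norm_tok] = QueryTerm(
                            norm_tok, w, origin="expanded", parent=t,
                            relevance_class=classes[t],
                        )
    entries.extend(sorted(expanded.values(), key=lambda e: (-e.weight, e.term)))
    return WeightedQuery(entries, length=len(originals))


# ---------------------------------------------------------------------------
# embedding training (CBOW with negative sampling)


def train_embeddings(
    sentences: Sequence[Sequence[str]],
    dim: int = 200,
    window: int = 5,
    seed: int = 0,
    epochs: int = 25,
    negative: int = 5,
    learning_rate: float = 0.05,
    min_count: int = 1,
) -> EmbeddingSpace:
    """Train continuous bag-of-words embeddings with negative sampling.

    A compact numpy implementation of the standard CBOW objective: the mean
    of the context vectors predicts the centre word against ``negative``
    noise words drawn from the unigram^0.75 distribution. Deterministic for
    a fixed seed.
    """
    counts: dict[str, int] = {}
    for sent in sentences:
        for tok in sent:
            counts[tok] = counts.get(tok, 0) + 1
    vocab = [t for t, c in sorted(counts.items()) if c >= min_count]
    if not vocab:
        raise ValueError("empty vocabulary: corpus smaller than required")
    total_tokens = sum(counts[t] for t in vocab)
    if total_tokens < window + 1:
        raise ValueError(
            f"corpus of {total_tokens} tokens is smaller than the context window {window}"
        )
    tok2id = {t: i for i, t in enumerate(vocab)}
    V = len(vocab)

    rng = np.random.default_rng(seed)
    w_in = (rng.random((V, dim)) - 0.5) / dim
    w_out = np.zeros((V, dim))

    freqs = np.array([counts[t] for t in vocab], dtype=float) ** 0.75
    noise_p = freqs / freqs.sum()

    encoded = [
        np.array([tok2id[t] for t in sent if t in tok2id], dtype=int)
        for sent in sentences
    ]
    encoded = [s for s in encoded if len(s) >= 2]

    for epoch in range(epochs):
        lr = learning_rate * (1.0 - epoch / epochs) + 1e-4
        for sent in encoded:
            n = len(sent)
            spans = rng.integers(1, window + 1, size=n)
            for pos in range(n):
                span = int(spans[pos])
                lo, hi = max(0, pos - span), min(n, pos + span + 1)
                ctx = np.concatenate([sent[lo:pos], sent[pos + 1: hi]])
                if len(ctx) == 0:
                    continue
                centre = sent[pos]
                h = w_in[ctx].mean(axis=0)
                targets = np.empty(negative + 1, dtype=int)
                targets[0] = centre
                targets[1:] = rng.choice(V, size=negative, p=noise_p)
                labels = np.zeros(negative + 1)
                labels[0] = 1.0
                scores = w_out[targets] @ h
                preds = 1.0 / (1.0 + np.exp(-np.clip(scores, -30, 30)))
                g = (preds - labels) * lr
                grad_h = g @ w_out[targets]
                for t_i, g_i in zip(targets, g):
                    w_out[t_i] -= g_i * h
                w_in[ctx] -= grad_h / len(ctx)
    return EmbeddingSpace({t: w_in[tok2id[t]] for t in vocab})
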