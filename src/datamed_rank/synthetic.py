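"""Seeded synthetic test collections with known ground truth.

Generates everything the pipeline consumes — a DOC-format corpus, queries,
graded qrels and a planted embedding table — plus a manifest recording each
document's topic, per-query relevance grade and class labels, so expected
outcomes are recomputable without any external download.

The generator emulates the gross shape of a dataset-discovery corpus:
Zipf-distributed background vocabulary (few terms carry most mass),
repository sizes drawn heavy-tailed so a handful of repositories hold most
documents, short noisy titles, and per-query planted topics: *relevant*
documents contain every query term (grade 2), *partially relevant* ones a
majority of them (grade 1). Synonym groups planted in the embedding table
have within-group cosine >= 0.9 and cross-group cosine <= 0.3, enabling
exact nearest-neighbour expectations for expansion tests.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Any

import numpy as np

from .corpus_io import DatasetRecord, GradedQrels, write_corpus
from .expansion import EmbeddingSpace
from .preprocess import normalize

__all__ = [
    "SyntheticCollection",
    "SyntheticSpec",
    "generate",
    "make_corpus",
    "make_embeddings",
    "make_qrels",
]

_REPOSITORIES = (
    "clinicaltrials_030116", "bioproject_030116", "pdb_030116", "geo_030116",
    "dryad_030116", "arrayexpress_030116", "dataverse_030116",
    "neuromorpho_030116", "gemma_030116", "proteomexchange_030116",
)
# heavy-tailed repository mass: top four hold ~70% of documents
_REPO_WEIGHTS = np.array([0.24, 0.20, 0.14, 0.13, 0.09, 0.08, 0.05, 0.04, 0.02, 0.01])

_CONSONANTS = "bcdfglmnprstvz"
_VOWELS = "aeiou"


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions of a synthetic collection (same spec + seed ->
    byte-identical outputs)."""

    seed: int = 0
    vocab_size: int = 400
    n_docs: int = 300
    n_queries: int = 8
    terms_per_query: int = 3
    n_relevant: int = 12
    n_partial: int = 8
    n_distractors: int = 10  # docs holding a single query term (graded 0)
    judged_nonrelevant: int = 20
    doc_len_mean: int = 60
    zipf_exponent: float = 1.1
    synonyms_per_term: int = 2
    embed_dim: int = 32
    plant_repeats: int = 3  # occurrences of each planted term in a relevant doc


@dataclass
class SyntheticCollection:
    records: list[DatasetRecord]
    queries: dict[str, str]
    manifest: dict[str, Any]

    def query_terms(self, qid: str) -> list[str]:
        return list(self.manifest["queries"][qid]["terms"])


def _make_word(rng: np.random.Generator, n_syllables: int) -> str:
    return "".join(
        _CONSONANTS[rng.integers(len(_CONSONANTS))] + _VOWELS[rng.integers(len(_VOWELS))]
        for _ in range(n_syllables)
    )


def _make_vocab(rng: np.random.Generator, size: int) -> list[str]:
    """Surface words whose normalized (stemmed) forms are unique."""
    vocab: list[str] = []
    seen_stems: set[str] = set()
    while len(vocab) < size:
        word = _make_word(rng, int(rng.integers(2, 5)))
        toks = list(normalize(word, mode="corpus"))
        if len(toks) != 1 or toks[0] in seen_stems:
            continue
        seen_stems.add(toks[0])
        vocab.append(word)
    return vocab


def generate(spec: SyntheticSpec | None = None) -> SyntheticCollection:
    """Build the full collection: records, query texts and the manifest."""
    spec = spec or SyntheticSpec()
    n_planted_docs = spec.n_queries * (
        spec.n_relevant + spec.n_partial + spec.n_distractors
    )
    if n_planted_docs > spec.n_docs:
        raise ValueError(
            f"infeasible spec: {n_planted_docs} planted docs needed but only "
            f"{spec.n_docs} requested"
        )
    rng = np.random.default_rng(spec.seed)

    n_special = spec.n_queries * spec.terms_per_query * (1 + spec.synonyms_per_term)
    vocab = _make_vocab(rng, spec.vocab_size + n_special)
    special, background = vocab[:n_special], vocab[n_special:]

    # query terms and their synonym groups (all disjoint from background)
    it = iter(special)
    query_terms: dict[str, list[str]] = {}
    synonyms: dict[str, list[str]] = {}
    for qi in range(spec.n_queries):
        qid = f"Q{qi + 1}"
        terms = [next(it) for _ in range(spec.terms_per_query)]
        query_terms[qid] = terms
        for t in terms:
            synonyms[t] = [next(it) for _ in range(spec.synonyms_per_term)]

    # Zipf mass over background vocabulary
    ranks = np.arange(1, len(background) + 1, dtype=float)
    probs = ranks ** (-spec.zipf_exponent)
    probs /= probs.sum()

    def background_text(n_tokens: int) -> list[str]:
        idx = rng.choice(len(background), size=max(n_tokens, 1), p=probs)
        return [background[i] for i in idx]

    doc_ids = [f"{100000 + i}" for i in range(spec.n_docs)]
    repos = rng.choice(len(_REPOSITORIES), size=spec.n_docs, p=_REPO_WEIGHTS)

    # assign planted roles: disjoint blocks of documents per query
    order = rng.permutation(spec.n_docs)
    grades: dict[str, dict[str, int]] = {d: {} for d in doc_ids}
    topics: dict[str, str | None] = {d: None for d in doc_ids}
    planted_terms: dict[str, list[str]] = {d: [] for d in doc_ids}
    cursor = 0
    for qid, terms in query_terms.items():
        rel_block = order[cursor: cursor + spec.n_relevant]
        cursor += spec.n_relevant
        par_block = order[cursor: cursor + spec.n_partial]
        cursor += spec.n_partial
        for pos in rel_block:
            d = doc_ids[pos]
            grades[d][qid] = 2
            topics[d] = qid
            plant = list(terms) * spec.plant_repeats
            # a synonym of each query term also appears, so expansion helps
            plant += [synonyms[t][0] for t in terms]
            planted_terms[d] = plant
        n_major = max(2, spec.terms_per_query - 1)
        for j, pos in enumerate(par_block):
            d = doc_ids[pos]
            grades[d][qid] = 1
            topics[d] = qid
            # most partials hold a majority of the concepts; every fourth
            # holds them all yet is still no answer to the question
            planted_terms[d] = list(terms) if j % 4 == 0 else list(terms[:n_major])
        dis_block = order[cursor: cursor + spec.n_distractors]
        cursor += spec.n_distractors
        for j, pos in enumerate(dis_block):
            d = doc_ids[pos]
            grades[d][qid] = 0
            # judged non-relevant: a single concept, or term-wise
            # indistinguishable from a majority partial (grades are human
            # judgments, not a function of term counts)
            planted_terms[d] = (
                list(terms[:n_major]) if j % 2 else [terms[j % len(terms)]]
            )

    records: list[DatasetRecord] = []
    doc_classes: dict[str, list[str]] = {}
    for i, d in enumerate(doc_ids):
        repo = _REPOSITORIES[repos[i]]
        n_tokens = max(10, int(rng.normal(spec.doc_len_mean, spec.doc_len_mean / 4)))
        body = background_text(n_tokens)
        plant = planted_terms[d]
        if plant:
            positions = sorted(rng.integers(0, len(body) + 1, size=len(plant)))
            for off, (pos, term) in enumerate(zip(positions, plant)):
                body.insert(pos + off, term)
        classes: list[str] = []
        if repo.startswith("clinicaltrials"):
            classes.append("Clinical trial")
            body += ["clinical", "trial"]
        doc_classes[d] = classes
        meta = {
            "dataset": {"description": " ".join(body)},
            "organism": {"name": " ".join(background_text(2))},
        }
        records.append(
            DatasetRecord(
                doc_id=d,
                title=" ".join(background_text(3)),
                repository=repo,
                metadata_text=" ".join(
                    [meta["dataset"]["description"], meta["organism"]["name"]]
                ),
                raw_metadata=meta,
            )
        )

    # judged non-relevant pool entries
    for qid in query_terms:
        candidates = [d for d in doc_ids if qid not in grades[d]]
        chosen = rng.choice(len(candidates), size=min(spec.judged_nonrelevant, len(candidates)), replace=False)
        for ci in chosen:
            grades[candidates[ci]][qid] = 0

    queries = {
        qid: f"Find {' '.join(terms)} data across all databases"
        for qid, terms in query_terms.items()
    }

    manifest = {
        "spec": asdict(spec),
        "queries": {
            qid: {
                "text": queries[qid],
                "terms": [normalize(t, mode="corpus")[0] for t in query_terms[qid]],
                "surface_terms": query_terms[qid],
            }
            for qid in query_terms
        },
        "synonyms": {
            normalize(t, mode="corpus")[0]: syns for t, syns in synonyms.items()
        },
        "surface_synonyms": synonyms,
        "docs": {
            d: {
                "topic": topics[d],
                "grades": grades[d],
                "classes": doc_classes[d],
            }
            for d in doc_ids
        },
    }
    return SyntheticCollection(records=records, queries=queries, manifest=manifest)


def make_corpus(
    spec: SyntheticSpec | None = None,
    out_dir: str | Path | None = None,
) -> SyntheticCollection:
    """Generate the collection and optionally write corpus + manifest files."""
    coll = generate(spec)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_corpus(coll.records, out / "corpus.doc")
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(coll.manifest, fh, indent=1, sort_keys=True)
        with open(out / "queries.tsv", "w", encoding="utf-8") as fh:
            for qid, text in coll.queries.items():
                fh.write(f"{qid}\t{text}\n")
    return coll


def make_embeddings(
    spec: SyntheticSpec | None = None,
    collection: SyntheticCollection | None = None,
    n_background: int = 50,
) -> EmbeddingSpace:
    """Planted embedding table for the collection's synonym groups.

    Group centroids are mutually orthogonal unit vectors; members sit within
    cosine >= 0.9 of their centroid, hence cross-group member cosines stay
    <= 0.3. Background vocabulary lives in the orthogonal complement.
    """
    spec = spec or SyntheticSpec()
    if spec.embed_dim < 2:
        raise ValueError("embedding dimension must be >= 2")
    coll = collection or generate(spec)
    rng = np.random.default_rng(spec.seed + 1)

    groups: list[list[str]] = []
    for qid in coll.manifest["queries"]:
        for surface in coll.manifest["queries"][qid]["surface_terms"]:
            groups.append([surface] + coll.manifest["surface_synonyms"][surface])

    dim = max(spec.embed_dim, len(groups) + 2)
    basis, _ = np.linalg.qr(rng.normal(size=(dim, dim)))
    vectors: dict[str, np.ndarray] = {}
    for gi, group in enumerate(groups):
        centroid = basis[:, gi]
        for mi, term in enumerate(group):
            # small perpendicular perturbation keeps cosine to centroid >= 0.9
            noise_dir = basis[:, len(groups) + (mi % (dim - len(groups)))]
            angle = 0.05 + 0.05 * mi
            vectors[term] = np.cos(angle) * centroid + np.sin(angle) * noise_dir

    free = basis[:, len(groups):]
    for bi in range(min(n_background, 200)):
        coeffs = rng.normal(size=free.shape[1])
        vec = free @ coeffs
        vec /= np.linalg.norm(vec)
        vectors[f"bg{bi:03d}"] = vec
    return EmbeddingSpace(vectors)


def make_qrels(
    manifest: dict[str, Any],
    subsample_rate: float = 0.0,
    seed: int = 0,
) -> GradedQrels:
    """Qrels from the manifest's planted grades.

    ``subsample_rate`` marks that fraction of the judged entries as
    unjudged (-1), exercising the inferred metrics.
    """
    if not 0.0 <= subsample_rate <= 1.0:
        raise ValueError("subsample_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    qrels = GradedQrels()
    for doc_id in sorted(manifest["docs"]):
        for qid, grade in sorted(manifest["docs"][doc_id]["grades"].items()):
            if subsample_rate > 0 and rng.random() < subsample_rate:
                qrels.set(qid, doc_id, -1)
            else:
                qrels.set(qid, doc_id, grade)
    return qrels
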