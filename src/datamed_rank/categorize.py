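"""Query/dataset categorization and category-constrained rank boosting.

Queries and datasets are mapped onto the 11 UniProt annotation categories
(Expression, Family & Domains, Function, Interaction, Names, Pathology &
Biotech, PTM/processing, Sequences, Structure, Subcellular location,
Unclassified) plus a Clinical trial class. Query classification is pure
string matching: unigrams, 2-skip-2-grams and 3-skip-2-grams of the
normalized query against the class descriptor phrases, with a keyword rule
for clinical trials. Dataset classification combines a trained multi-label
classifier (document embeddings feeding a multilayer perceptron) with the
clinical-trial keyword rule. A re-ranking step then multiplies the score of
datasets in the top positions whose classes intersect the query's classes
by a gain factor ``1 + g``.
"""

from __future__ import annotations

import math
import pickle
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.decomposition import TruncatedSVD
from sklearn.feature_extraction.text import TfidfVectorizer
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import MultiLabelBinarizer

from .corpus_io import DatasetRecord
from .porter import stem
from .preprocess import normalize, skipgrams

__all__ = [
    "CLINICAL_TRIAL_QUERY_KEYWORDS",
    "CLINICAL_TRIAL_TEXT_KEYWORDS",
    "CategoryScheme",
    "DatasetClassifier",
    "boost",
    "classify_dataset",
    "classify_query",
    "train_dataset_classifier",
]

CLINICAL_TRIAL = "Clinical trial"

#: words whose presence in a query marks it as a clinical-trial search
CLINICAL_TRIAL_QUERY_KEYWORDS = (
    "inclusion", "exclusion", "criteria", "patients",
    "subjects", "stage", "duration", "study",
)
_CT_QUERY_STEMS = frozenset(stem(w) for w in CLINICAL_TRIAL_QUERY_KEYWORDS)

#: words whose presence in a dataset's text marks it as a clinical trial
CLINICAL_TRIAL_TEXT_KEYWORDS = ("clinical", "trial", "clinicaltrial")


@dataclass
class CategoryScheme:
    """Class name -> set of normalized descriptor phrases."""

    classes: dict[str, set[str]] = field(default_factory=dict)

    def add(self, class_name: str, descriptor: str) -> None:
        phrase = " ".join(normalize(descriptor, mode="corpus"))
        if phrase:
            self.classes.setdefault(class_name, set()).add(phrase)

    @property
    def class_names(self) -> list[str]:
        return sorted(self.classes)

    @classmethod
    def from_file(cls, path: str | Path) -> "CategoryScheme":
        scheme = cls()
        for line in Path(path).read_text("utf-8").splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            name, _, descriptor = line.partition("\t")
            if descriptor.strip():
                scheme.add(name.strip(), descriptor.strip())
        return scheme

    @classmethod
    def default(cls) -> "CategoryScheme":
        scheme = cls()
        text = resources.files("datamed_rank.resources").joinpath(
            "uniprot_scheme.tsv"
        ).read_text("utf-8")
        for line in text.splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            name, _, descriptor = line.partition("\t")
            if descriptor.strip():
                scheme.add(name.strip(), descriptor.strip())
        return scheme


def classify_query(tokens: Sequence[str], scheme: CategoryScheme) -> set[str]:
    """Assign classes whose descriptors match a query gram.

    ``tokens`` should be the stemmed query *before* search-intent stopword
    removal, so that constraint words ("data", "expression", ...) can take
    part in descriptor grams. Grams used: unigrams, 2-skip-2-grams and
    3-skip-2-grams. The Clinical trial class is additionally triggered by
    the dedicated keyword list.
    """
    toks = list(tokens)
    classes: set[str] = set()
    if not toks:
        return classes
    grams = {g for g in skipgrams(toks, 1)}
    grams |= skipgrams(toks, 2, 2)
    grams |= skipgrams(toks, 2, 3)
    gram_strings = {" ".join(g) for g in grams}
    for name, descriptors in scheme.classes.items():
        if gram_strings & descriptors:
            classes.add(name)
    if any(t in _CT_QUERY_STEMS for t in toks):
        classes.add(CLINICAL_TRIAL)
    return classes


# ---------------------------------------------------------------------------
# dataset classifier


def _record_text(record: DatasetRecord | str) -> str:
    if isinstance(record, str):
        return record
    return f"{record.title} {record.metadata_text}"


class DatasetClassifier:
    """Multi-label dataset classifier: document embedding + MLP.

    Documents are embedded with TF-IDF followed by a truncated-SVD
    projection (latent semantic document vectors) and scored by a
    multilayer perceptron with one sigmoid output per class. Training is
    deterministic under a fixed seed and the artifact pickles losslessly.
    """

    def __init__(self, embed_dim: int = 50, seed: int = 0, hidden: int = 32):
        self.embed_dim = embed_dim
        self.seed = seed
        self.hidden = hidden
        self.classes_: list[str] = []
        self._vectorizer: TfidfVectorizer | None = None
        self._svd: TruncatedSVD | None = None
        self._mlp: MLPClassifier | None = None
        self._binarizer: MultiLabelBinarizer | None = None

    @property
    def is_trained(self) -> bool:
        return self._mlp is not None

    def fit(self, docs: Sequence[str], labels: Sequence[Iterable[str]]) -> "DatasetClassifier":
        label_sets = [set(ls) for ls in labels]
        distinct = sorted(set().union(*label_sets)) if label_sets else []
        if len(distinct) < 2:
            raise ValueError("training needs at least two distinct classes")
        texts = [" ".join(normalize(_record_text(d), mode="corpus")) for d in docs]
        self._vectorizer = TfidfVectorizer(token_pattern=r"\S+")
        tfidf = self._vectorizer.fit_transform(texts)
        n_comp = min(self.embed_dim, tfidf.shape[1] - 1, len(texts) - 1)
        if n_comp < 1:
            raise ValueError("corpus too small for the requested embedding dimension")
        self._svd = TruncatedSVD(n_components=n_comp, random_state=self.seed)
        embedded = self._svd.fit_transform(tfidf)
        self._binarizer = MultiLabelBinarizer(classes=distinct)
        y = self._binarizer.fit_transform(label_sets)
        self._mlp = MLPClassifier(
            hidden_layer_sizes=(self.hidden,),
            random_state=self.seed,
            max_iter=2000,
        )
        self._mlp.fit(embedded, y)
        self.classes_ = distinct
        return self

    def scores(self, record: DatasetRecord | str) -> dict[str, float]:
        """Per-class probability-like scores in [0, 1]."""
        if not self.is_trained:
            raise ValueError("classifier is not trained")
        text = " ".join(normalize(_record_text(record), mode="corpus"))
        emb = self._svd.transform(self._vectorizer.transform([text]))
        proba = self._mlp.predict_proba(emb)
        proba = np.asarray(proba)
        if proba.ndim == 1:
            proba = proba[None, :]
        row = proba[0]
        # sklearn returns one column per class for multilabel y
        return {c: float(row[i]) for i, c in enumerate(self.classes_)}

    def save(self, path: str | Path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @classmethod
    def load(cls, path: str | Path) -> "DatasetClassifier":
        with open(path, "rb") as fh:
            obj = pickle.load(fh)
        if not isinstance(obj, cls):
            raise TypeError(f"{path} does not hold a {cls.__name__}")
        return obj


def train_dataset_classifier(
    docs: Sequence[DatasetRecord | str],
    labels: Sequence[Iterable[str]],
    embed_dim: int = 50,
    seed: int = 0,
) -> DatasetClassifier:
    """Train the multi-label dataset classifier on labelled documents."""
    if len(docs) != len(labels):
        raise ValueError("docs and labels must align")
    texts = [_record_text(d) for d in docs]
    return DatasetClassifier(embed_dim=embed_dim, seed=seed).fit(texts, labels)


def _clinical_trial_keyword_match(text: str) -> bool:
    toks = set(normalize(text, mode="corpus"))
    raw_toks = set(re.findall(r"[a-z0-9_]+", text.lower()))
    for kw in CLINICAL_TRIAL_TEXT_KEYWORDS:
        if kw in raw_toks or stem(kw) in toks:
            return True
    return any(t.startswith("clinicaltrial") for t in raw_toks)


def classify_dataset(
    record: DatasetRecord | str,
    model: DatasetClassifier | None = None,
    threshold: float = 0.5,
    keyword_only: bool = False,
) -> set[str]:
    """Classes of one dataset: classifier scores >= threshold, plus the
    Clinical trial class whenever the record text contains one of the
    clinical/trial keywords. ``keyword_only=True`` skips the classifier
    (the only mode available without a trained model)."""
    classes: set[str] = set()
    if not keyword_only:
        if model is None or not model.is_trained:
            raise ValueError("no trained model; pass keyword_only=True for the keyword rule")
        for name, score in model.scores(record).items():
            if score >= threshold:
                classes.add(name)
    text = _record_text(record)
    if _clinical_trial_keyword_match(text):
        classes.add(CLINICAL_TRIAL)
    return classes


# ---------------------------------------------------------------------------
# boosting


def boost(
    ranking: Sequence[tuple[str, float]],
    query_classes: Iterable[str],
    doc_classes: Mapping[str, Iterable[str]],
    g: float = 0.10,
    top_fraction: float = 0.5,
) -> list[tuple[str, float]]:
    """Boost class-matching documents inside the top positions.

    Documents ranked within the top ``ceil(top_fraction * n)`` positions
    whose class set intersects the query's classes get their score
    multiplied by (1 + g); the list is re-sorted by the new scores with
    ties keeping the previous order. An empty query class set (or g = 0)
    leaves the ranking untouched; documents outside the eligible window
    always keep their exact score.
    """
    if g < 0:
        raise ValueError(f"gain must be >= 0, got {g}")
    if not 0 < top_fraction <= 1:
        raise ValueError(f"top_fraction must lie in (0, 1], got {top_fraction}")
    items = [(str(d), float(s)) for d, s in ranking]
    qcls = set(query_classes)
    if not qcls or g == 0:
        return items
    n_eligible = math.ceil(top_fraction * len(items))
    boosted: list[tuple[str, float]] = []
    for pos, (doc, score) in enumerate(items):
        if pos < n_eligible and qcls & set(doc_classes.get(doc, ())):
            score *= 1.0 + g
        boosted.append((doc, score))
    order = sorted(range(len(boosted)), key=lambda i: (-boosted[i][1], i))
    return [boosted[i] for i in order]
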