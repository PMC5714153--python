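"""Inverted index over normalized dataset records.

Exposes the per-term statistics the ranking functions need: within-document
occurrence counts f(t,d), the collection document frequency n_t, the corpus
size N = |D| and document/average lengths. Title and metadata text are pooled
into a single field (the source records carry no per-field weights).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Iterable

from .preprocess import StopwordConfig, normalize

if TYPE_CHECKING:  # pragma: no cover
    from .corpus_io import DatasetRecord

__all__ = ["InvertedIndex", "TermStats", "build_index", "term_stats"]

INDEX_FORMAT_VERSION = 1


@dataclass
class TermStats:
    """Statistics of one term: postings {doc -> f(t,d)}, document frequency
    n_t (or total occurrences under ``df_mode='occurrences'``) and N."""

    term: str
    postings: dict[str, int]
    df: int
    n_docs: int


class InvertedIndex:
    """Postings term -> {doc_id -> count}, plus document lengths.

    Supports incremental addition; building in batches equals a one-shot
    build for the same record order.
    """

    def __init__(self, df_mode: str = "docs"):
        if df_mode not in ("docs", "occurrences"):
            raise ValueError("df_mode must be 'docs' or 'occurrences'")
        self.df_mode = df_mode
        self.postings: dict[str, dict[str, int]] = {}
        self.doc_len: dict[str, int] = {}

    # -- construction -------------------------------------------------------

    def add_document(self, doc_id: str, tokens: Iterable[str]) -> None:
        if doc_id in self.doc_len:
            raise ValueError(f"duplicate doc_id {doc_id!r}")
        toks = list(tokens)
        self.doc_len[doc_id] = len(toks)
        for tok in toks:
            self.postings.setdefault(tok, {})
            self.postings[tok][doc_id] = self.postings[tok].get(doc_id, 0) + 1

    def add_record(self, record: "DatasetRecord", config: StopwordConfig | None = None) -> None:
        text = f"{record.title} {record.metadata_text}"
        self.add_document(record.doc_id, normalize(text, config=config, mode="corpus"))

    # -- statistics ---------------------------------------------------------

    @property
    def n_docs(self) -> int:
        return len(self.doc_len)

    @property
    def avg_len(self) -> float:
        if not self.doc_len:
            return 0.0
        return sum(self.doc_len.values()) / len(self.doc_len)

    def document_frequency(self, term: str) -> int:
        posting = self.postings.get(term)
        if not posting:
            return 0
        if self.df_mode == "docs":
            return len(posting)
        return sum(posting.values())

    def term_frequency(self, term: str, doc_id: str) -> int:
        return self.postings.get(term, {}).get(doc_id, 0)

    def doc_terms(self, doc_id: str) -> dict[str, int]:
        return {t: p[doc_id] for t, p in self.postings.items() if doc_id in p}

    def __contains__(self, term: str) -> bool:
        return term in self.postings

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, InvertedIndex)
            and self.df_mode == other.df_mode
            and self.postings == other.postings
            and self.doc_len == other.doc_len
        )

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        payload = {
            "format_version": INDEX_FORMAT_VERSION,
            "df_mode": self.df_mode,
            "doc_len": self.doc_len,
            "postings": self.postings,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path: str | Path) -> "InvertedIndex":
        with open(path, "r", encoding="utf-8") as fh:
            payload = json.load(fh)
        if payload.get("format_version") != INDEX_FORMAT_VERSION:
            raise ValueError(f"unsupported index format: {payload.get('format_version')}")
        idx = cls(df_mode=payload["df_mode"])
        idx.doc_len = {str(k): int(v) for k, v in payload["doc_len"].items()}
        idx.postings = {
            t: {d: int(c) for d, c in posting.items()}
            for t, posting in payload["postings"].items()
        }
        return idx


def build_index(
    records: Iterable["DatasetRecord"],
    config: StopwordConfig | None = None,
    df_mode: str = "docs",
) -> InvertedIndex:
    """Index a record sequence (deterministic for a fixed input order)."""
    idx = InvertedIndex(df_mode=df_mode)
    for rec in records:
        idx.add_record(rec, config=config)
    return idx


def term_stats(index: InvertedIndex, term: str) -> TermStats:
    """Stats for a (normalized) term; unseen terms yield df=0, no error."""
    posting = dict(index.postings.get(term, {}))
    return TermStats(
        term=term,
        postings=posting,
        df=index.document_frequency(term),
        n_docs=index.n_docs,
    )
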