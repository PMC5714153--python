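"""Readers and writers for every artifact the retrieval pipeline touches.

Formats
-------
* dataset corpus dump: pseudo-XML ``<DOC>`` blocks carrying ``<DOCNO>``,
  ``<TITLE>``, ``<REPOSITORY>`` and a ``<METADATA>`` JSON payload. The
  container is treated as a line-tolerant tag format, not strict XML, because
  real dumps embed raw HTML inside metadata notes.
* relevance judgments (qrels): whitespace-separated
  ``query_id 0 doc_id grade`` lines with grades in {-1, 0, 1, 2}
  (unjudged / not relevant / partially relevant / relevant).
* runs: six-column TREC lines ``query_id Q0 doc_id rank score tag``.
* embedding tables: word2vec text format (``V dim`` header then
  ``term v1 ... vdim`` rows).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Iterator, Mapping

logger = logging.getLogger(__name__)

VALID_GRADES = (-1, 0, 1, 2)

__all__ = [
    "CorpusFormatError",
    "DatasetRecord",
    "GradedQrels",
    "RankedRun",
    "VALID_GRADES",
    "flatten_metadata",
    "iter_corpus",
    "read_corpus",
    "read_embeddings",
    "read_qrels",
    "read_run",
    "write_corpus",
    "write_embeddings",
    "write_qrels",
    "write_run",
]


class CorpusFormatError(ValueError):
    """Raised for structurally broken corpus/qrels/run/embedding files."""


# ---------------------------------------------------------------------------
# dataset records


@dataclass(frozen=True)
class DatasetRecord:
    """One dataset entry of the challenge dump.

    ``metadata_text`` is the concatenation of every string-valued leaf of the
    metadata JSON payload (depth-first, sorted-key order) and is what gets
    indexed together with the title; ``raw_metadata`` keeps the untouched
    structured payload (or the raw string when the JSON was unparseable).
    """

    doc_id: str
    title: str = ""
    repository: str = ""
    metadata_text: str = ""
    raw_metadata: Any = None


def flatten_metadata(obj: Any, include_keys: bool = False) -> str:
    """Collect string leaves of a JSON-like object, depth-first in key order.

    Only string values (and string elements of arrays) contribute; keys are
    excluded unless ``include_keys`` is set. Numbers/booleans are skipped —
    dataset payload content lives in the string values.
    """
    parts: list[str] = []

    def walk(node: Any) -> None:
        if isinstance(node, str):
            parts.append(node)
        elif isinstance(node, Mapping):
            for key in sorted(node):
                if include_keys:
                    parts.append(str(key))
                walk(node[key])
        elif isinstance(node, (list, tuple)):
            for item in node:
                walk(item)

    walk(obj)
    return " ".join(parts)


def _tag_content(block: str, tag: str) -> str | None:
    open_t, close_t = f"<{tag}>", f"</{tag}>"
    start = block.find(open_t)
    if start < 0:
        return None
    end = block.find(close_t, start)
    if end < 0:
        return None
    return block[start + len(open_t): end]


def iter_corpus(path: str | Path, include_keys: bool = False) -> Iterator[DatasetRecord]:
    """Stream ``DatasetRecord`` objects from a DOC dump, one block at a time.

    Records without a DOCNO are skipped with a warning; a ``<DOC>`` still open
    at end of file raises :class:`CorpusFormatError` naming the byte offset.
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8", errors="replace") as fh:
        buf: list[str] = []
        in_doc = False
        doc_start_offset = 0
        offset = 0
        for line in fh:
            if not in_doc:
                pos = line.find("<DOC>")
                if pos >= 0:
                    in_doc = True
                    doc_start_offset = offset + pos
                    buf = [line[pos:]]
            else:
                buf.append(line)
            offset += len(line.encode("utf-8", errors="replace"))
            if in_doc and "</DOC>" in line:
                block = "".join(buf)
                block = block[: block.find("</DOC>")]
                in_doc = False
                buf = []
                rec = _parse_block(block, include_keys=include_keys)
                if rec is not None:
                    yield rec
        if in_doc:
            raise CorpusFormatError(
                f"{path}: truncated <DOC> block starting at byte {doc_start_offset}"
            )


def _parse_block(block: str, include_keys: bool = False) -> DatasetRecord | None:
    doc_id = _tag_content(block, "DOCNO")
    if doc_id is None or not doc_id.strip():
        logger.warning("corpus record without DOCNO rejected")
        return None
    doc_id = doc_id.strip()
    title = (_tag_content(block, "TITLE") or "").strip()
    repository = (_tag_content(block, "REPOSITORY") or "").strip()
    meta_raw = _tag_content(block, "METADATA")
    metadata_text = ""
    raw_metadata: Any = None
    if meta_raw is not None:
        try:
            raw_metadata = json.loads(meta_raw)
            metadata_text = flatten_metadata(raw_metadata, include_keys=include_keys)
        except (json.JSONDecodeError, ValueError):
            logger.warning("unparseable METADATA JSON for doc %s; kept as raw text", doc_id)
            raw_metadata = meta_raw
            metadata_text = meta_raw.strip()
    return DatasetRecord(
        doc_id=doc_id,
        title=title,
        repository=repository,
        metadata_text=metadata_text,
        raw_metadata=raw_metadata,
    )


def read_corpus(path: str | Path, include_keys: bool = False) -> list[DatasetRecord]:
    records = list(iter_corpus(path, include_keys=include_keys))
    seen: set[str] = set()
    for rec in records:
        if rec.doc_id in seen:
            raise CorpusFormatError(f"duplicate doc_id {rec.doc_id!r} in corpus")
        seen.add(rec.doc_id)
    return records


def write_corpus(records: Iterable[DatasetRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            meta = rec.raw_metadata
            meta_str = meta if isinstance(meta, str) else json.dumps(
                meta if meta is not None else {}, sort_keys=True
            )
            fh.write(
                "<DOC>\n"
                f"<DOCNO>{rec.doc_id}</DOCNO>\n"
                f"<TITLE>{rec.title}</TITLE>\n"
                f"<REPOSITORY>{rec.repository}</REPOSITORY>\n"
                f"<METADATA>{meta_str}</METADATA>\n"
                "</DOC>\n"
            )


# ---------------------------------------------------------------------------
# qrels


class GradedQrels:
    """Graded relevance judgments: (query_id, doc_id) -> grade in {-1,0,1,2}."""

    def __init__(self, grades: Mapping[tuple[str, str], int] | None = None):
        self._grades: dict[tuple[str, str], int] = {}
        if grades:
            for (qid, doc), g in grades.items():
                self.set(qid, doc, g)

    def set(self, query_id: str, doc_id: str, grade: int) -> None:
        if grade not in VALID_GRADES:
            raise ValueError(
                f"grade {grade!r} for ({query_id}, {doc_id}) not in {VALID_GRADES}"
            )
        self._grades[(query_id, doc_id)] = int(grade)

    def get(self, query_id: str, doc_id: str, default: int | None = None) -> int | None:
        return self._grades.get((query_id, doc_id), default)

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self._grades

    def __len__(self) -> int:
        return len(self._grades)

    def __eq__(self, other) -> bool:
        return isinstance(other, GradedQrels) and self._grades == other._grades

    def items(self):
        return self._grades.items()

    @property
    def query_ids(self) -> list[str]:
        return sorted({qid for qid, _ in self._grades})

    def for_query(self, query_id: str) -> dict[str, int]:
        return {doc: g for (qid, doc), g in self._grades.items() if qid == query_id}


def read_qrels(path: str | Path) -> GradedQrels:
    qrels = GradedQrels()
    seen: set[tuple[str, str]] = set()
    with open(path, "r", encoding="utf-8", errors="replace") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 4:
                raise CorpusFormatError(
                    f"{path}:{lineno}: expected 4 whitespace-separated fields, got {len(fields)}"
                )
            qid, _, doc, grade_s = fields
            try:
                grade = int(grade_s)
            except ValueError:
                raise CorpusFormatError(
                    f"{path}:{lineno}: non-integer grade {grade_s!r}"
                ) from None
            if grade not in VALID_GRADES:
                raise CorpusFormatError(
                    f"{path}:{lineno}: grade {grade} outside {VALID_GRADES}"
                )
            if (qid, doc) in seen:
                logger.warning("%s:%d: duplicate (%s, %s); last grade wins", path, lineno, qid, doc)
            seen.add((qid, doc))
            qrels.set(qid, doc, grade)
    return qrels


def write_qrels(qrels: GradedQrels, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for (qid, doc), grade in sorted(qrels.items()):
            fh.write(f"{qid} 0 {doc} {grade}\n")


# ---------------------------------------------------------------------------
# runs


@dataclass
class RankedRun:
    """Per-query ranked result lists in TREC run form.

    Each entry list is kept sorted by (score desc, doc_id asc); duplicate
    doc_ids within a query are rejected.
    """

    tag: str = "run"
    results: dict[str, list[tuple[str, float]]] = field(default_factory=dict)

    def set_query(self, query_id: str, entries: Iterable[tuple[str, float]]) -> None:
        items = [(str(d), float(s)) for d, s in entries]
        docs = [d for d, _ in items]
        if len(docs) != len(set(docs)):
            raise ValueError(f"duplicate doc_id in run entry for query {query_id}")
        items.sort(key=lambda e: (-e[1], e[0]))
        self.results[query_id] = items

    def __getitem__(self, query_id: str) -> list[tuple[str, float]]:
        return self.results[query_id]

    @property
    def query_ids(self) -> list[str]:
        return sorted(self.results)

    def ordering(self, query_id: str) -> list[str]:
        return [d for d, _ in self.results[query_id]]


def read_run(path: str | Path, tag: str | None = None) -> RankedRun:
    """Read a six-column TREC run; ranks are re-derived from the scores
    (ties broken by doc_id), and a stored rank disagreeing with score order
    only logs a warning — the score wins."""
    per_query: dict[str, list[tuple[str, float, int]]] = {}
    file_tag = tag
    with open(path, "r", encoding="utf-8", errors="replace") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 6:
                raise CorpusFormatError(
                    f"{path}:{lineno}: expected 6 fields, got {len(fields)}"
                )
            qid, _, doc, rank_s, score_s, line_tag = fields
            try:
                rank = int(rank_s)
                score = float(score_s)
            except ValueError:
                raise CorpusFormatError(f"{path}:{lineno}: bad rank/score") from None
            if file_tag is None:
                file_tag = line_tag
            per_query.setdefault(qid, []).append((doc, score, rank))
    run = RankedRun(tag=file_tag or "run")
    for qid, items in per_query.items():
        ordered = sorted(items, key=lambda e: (-e[1], e[0]))
        for derived_rank, (doc, score, stored_rank) in enumerate(ordered, 1):
            if stored_rank != derived_rank:
                logger.warning(
                    "%s: query %s doc %s stored rank %d != score-derived rank %d; score wins",
                    path, qid, doc, stored_rank, derived_rank,
                )
        run.set_query(qid, [(doc, score) for doc, score, _ in ordered])
    return run


def write_run(run: RankedRun, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for qid in run.query_ids:
            for rank, (doc, score) in enumerate(run.results[qid], 1):
                fh.write(f"{qid} Q0 {doc} {rank} {score:.6g} {run.tag}\n")


# ---------------------------------------------------------------------------
# embeddings (delegate to the expansion module's EmbeddingSpace)


def read_embeddings(path: str | Path):
    """Read a word2vec-text embedding table into an ``EmbeddingSpace``."""
    from .expansion import EmbeddingSpace

    return EmbeddingSpace.load(path)


def write_embeddings(space, path: str | Path) -> None:
    space.save(path)
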