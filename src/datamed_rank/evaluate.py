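"""Retrieval evaluation over graded, possibly incomplete judgments.

Metrics: precision at k with partially relevant documents counted as
relevant (+partial) or not (-partial), NDCG@k, inferred average precision
(infAP) and inferred NDCG — the two estimators designed for pools in which
only a sample of the retrieved documents was ever judged — plus the
Unanimous Improvement Ratio (UIR) for multi-measure system comparison.

Grades follow the challenge convention: 2 relevant, 1 partially relevant,
0 not relevant, -1 pooled but never judged. Documents absent from the
qrels altogether ("unpooled") are distinct from grade -1 and are treated
as not relevant.

Unjudged handling (``unjudged_mode``):

* ``sampled`` — the official semantics: grade -1 documents are the unjudged
  part of the pool and the judged part is treated as a uniform sample of it;
  infAP estimates the precision above each relevant rank from the judged
  sample (with epsilon smoothing), and infNDCG scales judged gains by the
  inverse of the per-query sampling rate. Unpooled documents are treated as
  judged non-relevant inside these estimates.
* ``zero`` (as-nonrelevant) — grade -1 is mapped to grade 0 and the exact
  metric is computed.
* ``remove`` — grade -1 documents are removed from the ranking (and from
  the pool) and the exact metric is computed on the remainder.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from scipy import stats as _scipy_stats

from .corpus_io import GradedQrels, RankedRun

logger = logging.getLogger(__name__)

__all__ = [
    "JudgedRanking",
    "MetricReport",
    "average_precision",
    "evaluate_run",
    "inf_ap",
    "inf_ndcg",
    "judge_run",
    "ndcg_at_k",
    "p_at_k",
    "paired_ttest",
    "uir",
]

UNJUDGED_MODES = ("sampled", "zero", "remove")
#: smoothing constant of the inferred estimators
EPSILON = 1e-5


@dataclass(frozen=True)
class JudgedRanking:
    """A ranked document list joined with grades.

    ``grades[i]`` is the grade of the i-th retrieved document: -1/0/1/2 from
    the qrels, or None when the document never entered the pool. ``pool``
    is the full qrels entry for the query (doc -> grade), needed for ideal
    rankings and sampling rates.
    """

    query_id: str
    doc_ids: tuple[str, ...]
    grades: tuple[int | None, ...]
    pool: Mapping[str, int]


def judge_run(run: RankedRun, qrels: GradedQrels, query_id: str) -> JudgedRanking:
    """Annotate one query's ranking with grades (a pure join)."""
    entries = run.results.get(query_id, [])
    pool = qrels.for_query(query_id)
    docs = tuple(d for d, _ in entries)
    grades = tuple(pool.get(d) for d in docs)
    return JudgedRanking(query_id=query_id, doc_ids=docs, grades=grades, pool=pool)


def _binary(grade: int | None, threshold: int) -> bool:
    return grade is not None and grade >= threshold


def p_at_k(judged: JudgedRanking, k: int = 10, partial_mode: str = "include") -> float:
    """Fraction of the top-k documents that are relevant.

    ``partial_mode='include'`` counts grade >= 1 as relevant, ``'exclude'``
    only grade 2. Unjudged (-1) and unpooled documents count as not
    relevant; rankings shorter than k are still divided by k.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if partial_mode not in ("include", "exclude"):
        raise ValueError(f"partial_mode must be include/exclude, got {partial_mode!r}")
    threshold = 1 if partial_mode == "include" else 2
    top = judged.grades[:k]
    return sum(1 for g in top if _binary(g, threshold)) / k


def _dcg(gains: Iterable[float]) -> float:
    return sum(g / math.log2(i + 2) for i, g in enumerate(gains))


def ndcg_at_k(judged: JudgedRanking, k: int = 10) -> float | None:
    """NDCG@k with linear gain = grade (negative and unpooled -> 0),
    discount 1/log2(rank+1), ideal from the full pool. Queries without a
    positive grade in the pool are undefined (None; excluded from means)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ideal_gains = sorted((g for g in judged.pool.values() if g > 0), reverse=True)[:k]
    if not ideal_gains:
        return None
    gains = [max(g, 0) if g is not None else 0 for g in judged.grades[:k]]
    return _dcg(gains) / _dcg(ideal_gains)


def _apply_mode(judged: JudgedRanking, mode: str) -> JudgedRanking:
    if mode == "zero":
        return JudgedRanking(
            judged.query_id,
            judged.doc_ids,
            tuple(0 if g == -1 else g for g in judged.grades),
            {d: (0 if g == -1 else g) for d, g in judged.pool.items()},
        )
    if mode == "remove":
        kept = [(d, g) for d, g in zip(judged.doc_ids, judged.grades) if g != -1]
        return JudgedRanking(
            judged.query_id,
            tuple(d for d, _ in kept),
            tuple(g for _, g in kept),
            {d: g for d, g in judged.pool.items() if g != -1},
        )
    return judged


def average_precision(judged: JudgedRanking, rel_threshold: int = 1) -> float | None:
    """Exact AP: mean of P@k over relevant ranks, divided by the number of
    relevant documents in the pool (unjudged/unpooled = not relevant)."""
    n_rel = sum(1 for g in judged.pool.values() if g >= rel_threshold)
    if n_rel == 0:
        return None
    hits = 0
    total = 0.0
    for rank, g in enumerate(judged.grades, 1):
        if _binary(g, rel_threshold):
            hits += 1
            total += hits / rank
    return total / n_rel


def inf_ap(
    judged: JudgedRanking,
    unjudged_mode: str = "sampled",
    rel_threshold: int = 1,
    eps: float = EPSILON,
) -> float | None:
    """Inferred average precision.

    In ``sampled`` mode the expected precision above each judged relevant
    rank k is estimated from the judged sample of the pooled documents
    among the k-1 above:

        E[P@k] = 1/k + (pooled/k) * (rel + eps)/(rel + nonrel + 2eps)

    where ``pooled`` counts the documents above that belong to the pool
    (judged or sampled out) and rel/nonrel split the judged ones; documents
    above that never entered the pool count as non-relevant with certainty.
    The estimate is averaged over the judged relevant documents of the
    pool. Under complete judgments this reduces to exact AP (within eps).
    Queries whose pool holds no judged relevant document are undefined
    (None).
    """
    if unjudged_mode not in UNJUDGED_MODES:
        raise ValueError(f"unjudged_mode must be one of {UNJUDGED_MODES}")
    if unjudged_mode in ("zero", "remove"):
        return average_precision(_apply_mode(judged, unjudged_mode), rel_threshold)

    n_rel_sampled = sum(1 for g in judged.pool.values() if g >= rel_threshold)
    if n_rel_sampled == 0:
        return None
    total = 0.0
    pooled_above = 0
    rel_above = 0
    nonrel_above = 0
    for rank, g in enumerate(judged.grades, 1):
        if _binary(g, rel_threshold):
            if rank == 1:
                total += 1.0
            else:
                within = (rel_above + eps) / (rel_above + nonrel_above + 2 * eps)
                total += 1.0 / rank + (pooled_above / rank) * within
        if g is not None:
            pooled_above += 1
            if g != -1:
                if _binary(g, rel_threshold):
                    rel_above += 1
                else:
                    nonrel_above += 1
    return total / n_rel_sampled


def _sampling_rate(pool: Mapping[str, int]) -> float:
    n_pool = len(pool)
    if n_pool == 0:
        return 1.0
    n_judged = sum(1 for g in pool.values() if g != -1)
    if n_judged == 0:
        return 1.0
    return n_judged / n_pool


def _weighted_ideal_dcg(pool: Mapping[str, int], weight: float) -> float:
    """Ideal DCG where each judged positive document occupies ``weight``
    consecutive rank units (fractional ranks integrate the discount)."""
    gains = sorted((g for g in pool.values() if g is not None and g > 0), reverse=True)
    total = 0.0
    pos = 0.0
    for g in gains:
        remaining = weight
        while remaining > 1e-12:
            rank = math.floor(pos) + 1
            fill = min(remaining, rank - pos)
            total += g * fill / math.log2(rank + 1)
            pos += fill
            remaining -= fill
    return total


def inf_ndcg(
    judged: JudgedRanking,
    unjudged_mode: str = "sampled",
) -> float | None:
    """Inferred NDCG.

    ``sampled`` mode scales each judged gain by the inverse per-query
    sampling rate (judged pool entries / pool size) at its observed rank,
    and normalizes by an ideal DCG in which every judged positive document
    likewise stands for 1/rate pool documents. Reduces to exact NDCG under
    complete judgments; the estimate is clipped into [0, 1].
    """
    if unjudged_mode not in UNJUDGED_MODES:
        raise ValueError(f"unjudged_mode must be one of {UNJUDGED_MODES}")
    judged = _apply_mode(judged, unjudged_mode)
    if not any(g is not None and g > 0 for g in judged.pool.values()):
        return None
    rate = _sampling_rate(judged.pool) if unjudged_mode == "sampled" else 1.0
    inv = 1.0 / rate
    dcg = 0.0
    for rank, g in enumerate(judged.grades, 1):
        if g is not None and g > 0:
            dcg += (g * inv) / math.log2(rank + 1)
    idcg = _weighted_ideal_dcg(judged.pool, inv)
    if idcg <= 0:
        return None
    return min(dcg / idcg, 1.0)


# ---------------------------------------------------------------------------
# reports and system comparison


@dataclass
class MetricReport:
    """Per-query and mean metric values for one run."""

    tag: str
    unjudged_mode: str
    per_query: dict[str, dict[str, float]] = field(default_factory=dict)
    excluded: dict[str, list[str]] = field(default_factory=dict)

    def mean(self, metric: str) -> float:
        vals = [
            q[metric]
            for q in self.per_query.values()
            if metric in q and q[metric] is not None
        ]
        return sum(vals) / len(vals) if vals else 0.0

    @property
    def metrics(self) -> list[str]:
        names: set[str] = set()
        for q in self.per_query.values():
            names.update(q)
        return sorted(names)

    def summary(self) -> dict[str, float]:
        return {m: self.mean(m) for m in self.metrics}


def evaluate_run(
    run: RankedRun,
    qrels: GradedQrels,
    k: int = 10,
    unjudged_mode: str = "sampled",
    tag: str | None = None,
) -> MetricReport:
    """All challenge metrics for every query of the run present in the qrels.

    Run queries absent from the qrels are skipped with a warning; queries
    with no (judged) relevant document are excluded per metric.
    """
    report = MetricReport(tag=tag or run.tag, unjudged_mode=unjudged_mode)
    qrels_queries = set(qrels.query_ids)
    for qid in run.query_ids:
        if qid not in qrels_queries:
            logger.warning("query %s absent from qrels; skipped", qid)
            continue
        judged = judge_run(run, qrels, qid)
        row: dict[str, float] = {}
        row["P@10+partial"] = p_at_k(judged, k, "include")
        row["P@10-partial"] = p_at_k(judged, k, "exclude")
        for name, value in (
            (f"NDCG@{k}", ndcg_at_k(judged, k)),
            ("infAP", inf_ap(judged, unjudged_mode)),
            ("infNDCG", inf_ndcg(judged, unjudged_mode)),
        ):
            if value is None:
                report.excluded.setdefault(name, []).append(qid)
            else:
                row[name] = value
        report.per_query[qid] = row
    return report


def uir(
    systems: Mapping[str, MetricReport],
    measures: Sequence[str],
    mode: str = "per_query",
) -> dict[str, float]:
    """Unanimous Improvement Ratio across systems.

    For a pair (A, B), count the test cases where A >= B on every measure
    with at least one strict win (N_A), and symmetrically N_B;
    UIR(A, B) = (N_A - N_B) / cases. A system's score is the mean of its
    pairwise UIR against every other system. ``mode='per_query'`` uses the
    shared queries as test cases (each compared on the measure vector);
    ``mode='single_vector'`` uses one case per system pair — the vector of
    mean measures.
    """
    if len(systems) < 2:
        raise ValueError("UIR needs at least two systems")
    if not measures:
        raise ValueError("UIR needs at least one measure")
    if mode not in ("per_query", "single_vector"):
        raise ValueError(f"unknown mode {mode!r}")

    tags = sorted(systems)
    if mode == "per_query":
        shared = set.intersection(*(set(systems[t].per_query) for t in tags))
        if not shared:
            raise ValueError("systems share no test cases (queries)")
        cases = sorted(shared)

        def vectors(tag: str) -> list[tuple[float, ...]]:
            out = []
            for qid in cases:
                row = systems[tag].per_query[qid]
                try:
                    out.append(tuple(row[m] for m in measures))
                except KeyError as exc:
                    raise ValueError(
                        f"system {tag} lacks measure {exc} for query {qid}"
                    ) from None
            return out
    else:
        def vectors(tag: str) -> list[tuple[float, ...]]:
            return [tuple(systems[tag].mean(m) for m in measures)]

    vecs = {t: vectors(t) for t in tags}

    def pair_uir(a: str, b: str) -> float:
        n_a = n_b = 0
        n_cases = len(vecs[a])
        for va, vb in zip(vecs[a], vecs[b]):
            ge = all(x >= y for x, y in zip(va, vb))
            le = all(x <= y for x, y in zip(va, vb))
            if ge and not le:
                n_a += 1
            elif le and not ge:
                n_b += 1
        return (n_a - n_b) / n_cases

    return {
        t: sum(pair_uir(t, other) for other in tags if other != t) / (len(tags) - 1)
        for t in tags
    }


def paired_ttest(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Paired two-tailed t-test; returns (statistic, p-value)."""
    res = _scipy_stats.ttest_rel(list(a), list(b))
    return float(res.statistic), float(res.pvalue)
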