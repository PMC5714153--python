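"""Document scoring: the RTRL term-relevance measure and a DFR baseline.

RTRL ("robust term relevance logic") ranks documents into integer relevance
bins. Each query term t present in a document d contributes
``w(t, d) = wd + wq`` where the document component wd is a two-level step
function of the within-document count f(t,d) (wd' = 1 if f = 1, wd'' = 2wd'
if f > 1) and the query component wq is wq' = 1 for *relevant* terms or
wq'' = c(2L - 2) for *key-relevant* terms (L = query length, gain c >= 1).
The key-relevant weight is the smallest value for which a document holding
all k ~ L/2 key-relevant terms at low document relevance cannot be outranked
by one holding k - 1 of them plus every relevant term at high document
relevance. Documents sharing a bin are ordered by a tf-idf tie-break
(tf = 0.5 + 0.5 f(t,d)/max_f, idf = log N/n_t) normalized inside the bin to
lie strictly in (0, 1), so the tie-break can never cross bin boundaries.

The baseline scorer is the InL2 model of the Divergence-from-Randomness
family with term-frequency normalization parameter ``c_norm``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

from .corpus_io import RankedRun
from .expansion import KEY_RELEVANT, WeightedQuery
from .index import InvertedIndex

logger = logging.getLogger(__name__)

__all__ = [
    "RtrlParams",
    "ScoredDoc",
    "bin_tiebreak",
    "dfr_rank",
    "doc_weight",
    "key_weight",
    "query_weight",
    "rank_queries",
    "rtrl_bin_score",
    "rtrl_rank",
]

#: uniform tie-break for bins whose members all have zero tf-idf
TIE_EPSILON = 1e-6


@dataclass(frozen=True)
class RtrlParams:
    """Weights of the term-relevance model.

    c:        gain of key-relevant terms (>= 1)
    wd_low:   wd', weight of a term occurring once in the document
    wd_high:  wd'', weight of a repeated term (default 2 wd')
    wq_low:   wq', weight of a merely relevant query term
    idf_base: logarithm base of the tie-break idf (natural log by default)
    """

    c: float = 1.0
    wd_low: float = 1.0
    wd_high: float | None = None
    wq_low: float = 1.0
    idf_base: float = math.e

    def __post_init__(self):
        if self.c < 1:
            raise ValueError(f"c must be >= 1, got {self.c}")
        high = self.wd_high if self.wd_high is not None else 2 * self.wd_low
        if not (high >= self.wd_low > 0):
            raise ValueError("need wd_high >= wd_low > 0")

    @property
    def wd_high_(self) -> float:
        return self.wd_high if self.wd_high is not None else 2 * self.wd_low


@dataclass(frozen=True)
class ScoredDoc:
    """A ranked document: integer-ish bin score plus in-bin tie-break.

    ``final_score`` adds the (gap-scaled) tie-break to the bin score so the
    scalar is monotone with the (bin, tie_break) lexicographic order.
    """

    doc_id: str
    bin_score: float
    tie_break: float
    final_score: float


def key_weight(length: int, params: RtrlParams | None = None) -> float:
    """Weight wq'' = c(2L - 2) of a key-relevant term for query length L.

    This is the minimal weight satisfying the bin-dominance inequality
    k(wd' + wq'') >= (k-1)(wd'' + wq'') + (L-k)(wd'' + wq') at k = L/2 with
    the default document weights. Single-term queries (L < 2) degenerate;
    they get c * max(2L - 2, 1) with a warning.
    """
    params = params or RtrlParams()
    if length < 2:
        logger.warning("key_weight called with degenerate query length L=%d", length)
        return params.c * max(2 * length - 2, 1)
    return params.c * (2 * length - 2)


def doc_weight(ftd: int, params: RtrlParams | None = None) -> float:
    """Two-level document component: wd' if the term occurs once, wd'' else."""
    params = params or RtrlParams()
    if ftd <= 0:
        raise ValueError("doc_weight is undefined for absent terms (ftd <= 0)")
    return params.wd_low if ftd == 1 else params.wd_high_


def query_weight(
    relevance_class: str,
    length: int,
    params: RtrlParams | None = None,
) -> float:
    """wq' for relevant terms, wq'' = c(2L-2) for key-relevant terms."""
    params = params or RtrlParams()
    if relevance_class == KEY_RELEVANT:
        return key_weight(length, params)
    return params.wq_low


def rtrl_bin_score(
    doc_id: str,
    query: WeightedQuery,
    index: InvertedIndex,
    params: RtrlParams | None = None,
) -> float:
    """Bin score of one document: sum of weight(t) * (wd + wq) over query
    terms present in the document (expansion weights multiply; original
    terms have weight 1 so unexpanded queries reduce to wd + wq sums)."""
    params = params or RtrlParams()
    score = 0.0
    for entry in query.terms:
        ftd = index.term_frequency(entry.term, doc_id)
        if ftd <= 0:
            continue
        wd = doc_weight(ftd, params)
        wq = query_weight(entry.relevance_class, query.length, params)
        score += entry.weight * (wd + wq)
    return score


def _tf(ftd: int, max_ftd: int) -> float:
    return 0.5 + 0.5 * ftd / max_ftd


def _idf(index: InvertedIndex, term: str, base: float) -> float:
    nt = len(index.postings.get(term, {}))
    if nt == 0 or index.n_docs == 0:
        return 0.0
    return math.log(index.n_docs / nt) / math.log(base)


def bin_tiebreak(
    doc_ids: Sequence[str],
    query: WeightedQuery,
    index: InvertedIndex,
    params: RtrlParams | None = None,
) -> dict[str, float]:
    """tf-idf tie-break for documents sharing one bin, scaled into (0, 1).

    Raw value per doc: sum over query terms present of tf(t,d) * idf(t) with
    tf = 0.5 + 0.5 f(t,d)/max_f(d) (max over all terms of d) and idf the
    log of N/n_t. Raw values are divided by a hair more than the bin maximum
    so every tie-break lies strictly between 0 and 1; a bin whose members
    all score zero gets a uniform epsilon (doc_id order decides)."""
    params = params or RtrlParams()
    raw: dict[str, float] = {}
    for doc_id in doc_ids:
        doc_terms = index.doc_terms(doc_id)
        max_ftd = max(doc_terms.values(), default=0)
        total = 0.0
        if max_ftd > 0:
            for entry in query.terms:
                ftd = doc_terms.get(entry.term, 0)
                if ftd > 0:
                    total += _tf(ftd, max_ftd) * _idf(index, entry.term, params.idf_base)
        # quantize so float summation noise cannot flip doc_id tie-breaking
        raw[doc_id] = round(total, 12)
    max_raw = max(raw.values(), default=0.0)
    if max_raw <= 0.0:
        return {d: TIE_EPSILON for d in doc_ids}
    denom = max_raw * (1.0 + 1e-9)
    scaled = {d: v / denom for d, v in raw.items()}
    nonzero_min = min((s for s in scaled.values() if s > 0), default=1.0)
    zero_val = min(TIE_EPSILON, nonzero_min / 2)
    return {d: (s if s > 0 else zero_val) for d, s in scaled.items()}


def rtrl_rank(
    query: WeightedQuery,
    index: InvertedIndex,
    params: RtrlParams | None = None,
    cutoff: int = 1000,
) -> list[ScoredDoc]:
    """Rank the union of the query terms' postings by (bin, tie-break).

    The emitted scalar score is bin + tie_break * min(1, smallest bin gap),
    which keeps run-file scores monotone with the ranking even when
    expansion weights produce fractional bins closer than 1 apart. With
    integral parameters and unexpanded queries the scale factor is 1.
    """
    params = params or RtrlParams()
    candidates: set[str] = set()
    for entry in query.terms:
        candidates.update(index.postings.get(entry.term, {}))
    if not candidates:
        return []

    bins: dict[float, list[str]] = {}
    for doc_id in candidates:
        b = round(rtrl_bin_score(doc_id, query, index, params), 9)
        bins.setdefault(b, []).append(doc_id)

    distinct = sorted(bins, reverse=True)
    if len(distinct) > 1:
        min_gap = min(a - b for a, b in zip(distinct, distinct[1:]))
        scale = min(1.0, min_gap)
    else:
        scale = 1.0

    out: list[ScoredDoc] = []
    for b in distinct:
        ties = bin_tiebreak(bins[b], query, index, params)
        members = sorted(bins[b], key=lambda d: (-ties[d], d))
        for doc_id in members:
            out.append(
                ScoredDoc(
                    doc_id=doc_id,
                    bin_score=b,
                    tie_break=ties[doc_id],
                    final_score=b + ties[doc_id] * scale,
                )
            )
    return out[:cutoff]


def dfr_rank(
    query: WeightedQuery,
    index: InvertedIndex,
    c_norm: float = 1.0,
    cutoff: int = 1000,
) -> list[tuple[str, float]]:
    """InL2 divergence-from-randomness scoring.

    Per term: tfn = f(t,d) * log2(1 + c_norm * avg_len / len(d)); the term
    contributes weight(t) * tfn/(tfn + 1) * log2((N + 1)/(n_t + 0.5)).
    ``c_norm`` is the term-frequency normalization parameter (the two values
    used operationally are 1 and 33).
    """
    if c_norm <= 0:
        raise ValueError(f"c_norm must be > 0, got {c_norm}")
    n_docs = index.n_docs
    avg_len = index.avg_len
    scores: dict[str, float] = {}
    for entry in query.terms:
        posting = index.postings.get(entry.term)
        if not posting:
            continue
        nt = len(posting)
        idf_part = math.log2((n_docs + 1) / (nt + 0.5))
        for doc_id, ftd in posting.items():
            dl = index.doc_len[doc_id] or 1
            tfn = ftd * math.log2(1.0 + c_norm * avg_len / dl)
            contrib = entry.weight * (tfn / (tfn + 1.0)) * idf_part
            scores[doc_id] = scores.get(doc_id, 0.0) + contrib
    ranked = sorted(scores.items(), key=lambda e: (-e[1], e[0]))
    return ranked[:cutoff]


def rank_queries(
    queries: dict[str, WeightedQuery],
    index: InvertedIndex,
    model: str = "rtrl",
    params: RtrlParams | None = None,
    c_norm: float = 1.0,
    cutoff: int = 1000,
    tag: str | None = None,
) -> RankedRun:
    """Score every query and collect the results into a run."""
    if model not in ("rtrl", "dfr"):
        raise ValueError(f"model must be 'rtrl' or 'dfr', got {model}")
    run = RankedRun(tag=tag or model)
    for qid, query in queries.items():
        if model == "rtrl":
            scored = rtrl_rank(query, index, params=params, cutoff=cutoff)
            run.set_query(qid, [(d.doc_id, d.final_score) for d in scored])
        else:
            run.set_query(qid, dfr_rank(query, index, c_norm=c_norm, cutoff=cutoff))
    return run
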