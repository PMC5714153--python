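"""Independent brute-force reference implementations used only by tests.

These re-derive the scoring equations from first principles on plain
dictionaries, deliberately sharing no code with the package's index or
ranking modules, so that agreement between the two is meaningful.
"""

from __future__ import annotations

import math


def median(values):
    xs = sorted(values)
    n = len(xs)
    if n % 2:
        return float(xs[n // 2])
    return (xs[n // 2 - 1] + xs[n // 2]) / 2.0


def key_classes(query_terms, docs):
    """term -> True if key-relevant (df <= median df of the query terms)."""
    dfs = {t: sum(1 for d in docs.values() if t in d) for t in query_terms}
    med = median(dfs.values())
    return {t: dfs[t] <= med for t in query_terms}


def brute_force_rank(docs, query_terms, c=1.0, weights=None):
    """Rank {doc_id: {term: count}} against a query, from the equations.

    ``weights`` optionally maps term -> (weight, parent_is_key) for expanded
    queries; by default every term is an original with weight 1. Returns
    [(doc_id, bin_score, raw_tiebreak)] in final ranking order.
    """
    terms = list(dict.fromkeys(query_terms))
    L = len(terms)
    is_key = key_classes(terms, docs)
    wq_high = c * (2 * L - 2) if L >= 2 else c * max(2 * L - 2, 1)
    n_docs = len(docs)

    all_terms = terms if weights is None else list(weights)
    if weights is None:
        weights = {t: (1.0, is_key[t]) for t in terms}

    def df(t):
        return sum(1 for d in docs.values() if t in d)

    scored = []
    for doc_id, counts in docs.items():
        bin_score = 0.0
        for t in all_terms:
            ftd = counts.get(t, 0)
            if ftd <= 0:
                continue
            w, key = weights[t]
            wd = 1.0 if ftd == 1 else 2.0
            wq = wq_high if key else 1.0
            bin_score += w * (wd + wq)
        raw_tie = 0.0
        max_ftd = max(counts.values(), default=0)
        if max_ftd > 0:
            for t in all_terms:
                ftd = counts.get(t, 0)
                if ftd > 0 and df(t) > 0:
                    tf = 0.5 + 0.5 * ftd / max_ftd
                    idf = math.log(n_docs / df(t))
                    raw_tie += tf * idf
        if bin_score > 0:
            scored.append((doc_id, bin_score, raw_tie))
    scored.sort(key=lambda e: (-round(e[1], 9), -round(e[2], 12), e[0]))
    return scored


def exact_average_precision(grades_in_rank, n_relevant, threshold=1):
    """Plain AP over a graded ranking (grade >= threshold counts)."""
    if n_relevant == 0:
        return None
    hits, total = 0, 0.0
    for rank, g in enumerate(grades_in_rank, 1):
        if g is not None and g >= threshold:
            hits += 1
            total += hits / rank
    return total / n_relevant


def exact_ndcg(grades_in_rank, pool_grades, k=None):
    """Plain NDCG with linear gains and log2 discounts."""
    if k is None:
        k = len(grades_in_rank)
    gains = [max(g, 0) if g is not None else 0 for g in grades_in_rank[:k]]
    ideal = sorted((g for g in pool_grades if g > 0), reverse=True)[:k]
    if not ideal:
        return None
    dcg = sum(g / math.log2(i + 2) for i, g in enumerate(gains))
    idcg = sum(g / math.log2(i + 2) for i, g in enumerate(ideal))
    return dcg / idcg


def knn_by_exhaustion(vectors, term, k, exclude=()):
    """Exhaustive cosine scan; returns [(term, cos)] sorted (-cos, term)."""
    import numpy as np

    q = np.asarray(vectors[term], dtype=float)
    qn = q / np.linalg.norm(q)
    out = []
    for t, v in vectors.items():
        if t == term or t in exclude:
            continue
        v = np.asarray(v, dtype=float)
        out.append((t, float(qn @ (v / np.linalg.norm(v)))))
    out.sort(key=lambda e: (-e[1], e[0]))
    return out[:k]
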