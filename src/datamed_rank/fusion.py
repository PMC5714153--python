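"""Linear rank fusion of two runs.

The combined score of a document is ``alpha * norm(score_A) +
(1 - alpha) * norm(score_B)`` per query, over the union of the two result
lists (a document missing from one run contributes 0 there). Because the
two input runs typically come from scorers on different scales, scores are
min-max normalized per query by default; ``norm="none"`` reproduces raw
summation. Ties are broken by doc_id for determinism.
"""

from __future__ import annotations

from dataclasses import dataclass

from .corpus_io import RankedRun

__all__ = ["FusionParams", "combine"]


@dataclass(frozen=True)
class FusionParams:
    alpha: float = 0.5
    norm: str = "minmax"  # minmax | none

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if self.norm not in ("minmax", "none"):
            raise ValueError(f"norm must be 'minmax' or 'none', got {self.norm}")


def _normalized(entries: list[tuple[str, float]], mode: str) -> dict[str, float]:
    scores = {d: s for d, s in entries}
    if mode == "none" or not scores:
        return scores
    lo, hi = min(scores.values()), max(scores.values())
    if hi == lo:
        return {d: 1.0 for d in scores}
    return {d: (s - lo) / (hi - lo) for d, s in scores.items()}


def combine(
    run_a: RankedRun,
    run_b: RankedRun,
    params: FusionParams | None = None,
    tag: str | None = None,
) -> RankedRun:
    """Fuse two runs query by query (union of query ids and of documents)."""
    params = params or FusionParams()
    out = RankedRun(tag=tag or f"fuse({run_a.tag},{run_b.tag},a={params.alpha:g})")
    for qid in sorted(set(run_a.query_ids) | set(run_b.query_ids)):
        a = _normalized(run_a.results.get(qid, []), params.norm)
        b = _normalized(run_b.results.get(qid, []), params.norm)
        fused = {
            d: params.alpha * a.get(d, 0.0) + (1.0 - params.alpha) * b.get(d, 0.0)
            for d in set(a) | set(b)
        }
        out.set_query(qid, sorted(fused.items(), key=lambda e: (-e[1], e[0])))
    return out
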