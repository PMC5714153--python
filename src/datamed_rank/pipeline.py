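"""End-to-end retrieval pipelines: the five sibtex preset configurations.

* ``sibtex-1`` — DFR (InL2) baseline, cleaned queries only.
* ``sibtex-2`` — DFR + embedding expansion (model 1) + category boosting.
* ``sibtex-3`` — DFR + expansion with loss-penalized terms (model 2) + boosting.
* ``sibtex-4`` — RTRL term-relevance ranking + category boosting.
* ``sibtex-5`` — linear fusion of sibtex-3 and sibtex-4 (alpha = 0.5).

All tunables (neighbour count k = 10, loss factor l = 0.01, key-term gain c,
DFR normalization c_norm in {1, 33}, boost gain g = 0.10, boosted
top-fraction 0.5, fusion alpha = 0.5, cutoff 1000) live in
:class:`PipelineConfig`; presets expand to fully explicit configs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict, replace
from pathlib import Path
from typing import Mapping

import yaml

from .categorize import CategoryScheme, DatasetClassifier, classify_dataset, classify_query, boost
from .corpus_io import DatasetRecord, GradedQrels, RankedRun, write_run
from .evaluate import MetricReport, evaluate_run
from .expansion import EmbeddingSpace, WeightedQuery, classify_key_relevance, expand
from .fusion import FusionParams, combine
from .index import InvertedIndex, build_index
from .preprocess import normalize
from .ranking import RtrlParams, rank_queries

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PRESETS", "PipelineResult", "run_pipeline"]

PRESETS: dict[str, dict] = {
    "sibtex-1": {"ranker": "dfr", "expansion_model": 0, "boost_enabled": False},
    "sibtex-2": {"ranker": "dfr", "expansion_model": 1, "boost_enabled": True},
    "sibtex-3": {"ranker": "dfr", "expansion_model": 2, "boost_enabled": True},
    "sibtex-4": {"ranker": "rtrl", "expansion_model": 0, "boost_enabled": True},
    "sibtex-5": {"ranker": "fusion", "expansion_model": 2, "boost_enabled": True},
}


@dataclass(frozen=True)
class PipelineConfig:
    """Fully explicit stage configuration (presets fill the stage fields)."""

    preset: str | None = None
    ranker: str = "dfr"            # dfr | rtrl | fusion
    expansion_model: int = 0       # 0 = off, 1, 2
    boost_enabled: bool = False
    k: int = 10
    l: float = 0.01
    c: float = 1.0
    c_norm: float = 1.0
    g: float = 0.10
    top_fraction: float = 0.5
    alpha: float = 0.5
    cutoff: int = 1000
    min_similarity: float = 0.0
    classifier_threshold: float = 0.5

    @classmethod
    def from_preset(cls, name: str, **overrides) -> "PipelineConfig":
        if name not in PRESETS:
            raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
        fields = dict(PRESETS[name])
        fields.update(overrides)
        return cls(preset=name, **fields)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass
class PipelineResult:
    run: RankedRun
    intermediate: dict[str, RankedRun]
    report: MetricReport | None
    config: PipelineConfig


def _prepare_queries(
    raw_queries: Mapping[str, str],
    index: InvertedIndex,
    config: PipelineConfig,
    embeddings: EmbeddingSpace | None,
) -> dict[str, WeightedQuery]:
    queries: dict[str, WeightedQuery] = {}
    for qid, text in raw_queries.items():
        tokens = list(normalize(text, mode="query"))
        if not tokens:
            queries[qid] = WeightedQuery([], length=0)
            continue
        if config.expansion_model in (1, 2):
            if embeddings is None:
                raise ValueError(
                    f"preset {config.preset or config.ranker} needs an embedding file "
                    "for query expansion but none was provided"
                )
            queries[qid] = expand(
                tokens,
                space=embeddings,
                k=config.k,
                model=config.expansion_model,
                l=config.l,
                index=index,
                min_similarity=config.min_similarity,
            )
        else:
            wq = WeightedQuery.from_tokens(tokens)
            classes = classify_key_relevance([t.term for t in wq.terms], index)
            wq = WeightedQuery(
                [replace(t, relevance_class=classes[t.term]) for t in wq.terms],
                length=wq.length,
            )
            queries[qid] = wq
    return queries


def _apply_boost(
    run: RankedRun,
    raw_queries: Mapping[str, str],
    records: Mapping[str, DatasetRecord],
    config: PipelineConfig,
    scheme: CategoryScheme,
    classifier: DatasetClassifier | None,
) -> RankedRun:
    boosted = RankedRun(tag=f"{run.tag}+boost")
    doc_class_cache: dict[str, set[str]] = {}

    def classes_of(doc_id: str) -> set[str]:
        if doc_id not in doc_class_cache:
            rec = records.get(doc_id)
            if rec is None:
                doc_class_cache[doc_id] = set()
            else:
                doc_class_cache[doc_id] = classify_dataset(
                    rec,
                    model=classifier,
                    threshold=config.classifier_threshold,
                    keyword_only=classifier is None,
                )
        return doc_class_cache[doc_id]

    for qid in run.query_ids:
        qtokens = normalize(raw_queries[qid], mode="corpus")
        qclasses = classify_query(qtokens, scheme)
        entries = run.results[qid]
        if not qclasses:
            boosted.results[qid] = list(entries)
            continue
        doc_classes = {d: classes_of(d) for d, _ in entries}
        new_entries = boost(
            entries, qclasses, doc_classes,
            g=config.g, top_fraction=config.top_fraction,
        )
        boosted.results[qid] = new_entries
    return boosted


def run_pipeline(
    records: list[DatasetRecord],
    queries: Mapping[str, str],
    config: PipelineConfig,
    embeddings: EmbeddingSpace | None = None,
    scheme: CategoryScheme | None = None,
    classifier: DatasetClassifier | None = None,
    qrels: GradedQrels | None = None,
    index: InvertedIndex | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run one preset (or explicit config) end to end.

    Returns the final run, every intermediate run, and a metric report when
    qrels are given. With ``out_dir`` set, all runs and the explicit config
    are persisted.
    """
    index = index or build_index(records)
    scheme = scheme or CategoryScheme.default()
    record_map = {r.doc_id: r for r in records}
    intermediate: dict[str, RankedRun] = {}

    def ranked(ranker: str, expansion_model: int, tag: str) -> RankedRun:
        cfg = replace(config, expansion_model=expansion_model)
        wqueries = _prepare_queries(queries, index, cfg, embeddings)
        run = rank_queries(
            wqueries, index,
            model=ranker,
            params=RtrlParams(c=config.c),
            c_norm=config.c_norm,
            cutoff=config.cutoff,
            tag=tag,
        )
        intermediate[tag] = run
        if config.boost_enabled:
            run = _apply_boost(run, queries, record_map, config, scheme, classifier)
            intermediate[run.tag] = run
        return run

    if config.ranker == "fusion":
        run_a = ranked("dfr", 2, "sibtex-3")
        run_b = ranked("rtrl", 0, "sibtex-4")
        final = combine(run_a, run_b, FusionParams(alpha=config.alpha),
                        tag=config.preset or "fused")
    elif config.ranker in ("dfr", "rtrl"):
        final = ranked(config.ranker, config.expansion_model,
                       config.preset or config.ranker)
    else:
        raise ValueError(f"unknown ranker {config.ranker!r}")

    report = evaluate_run(final, qrels) if qrels is not None else None

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for tag, run in intermediate.items():
            write_run(run, out / f"{tag}.run")
        write_run(final, out / f"{final.tag}.final.run")
        config.to_yaml(out / "config.yaml")
    logger.info(
        "pipeline %s finished: %d queries, ranker=%s expansion=%d boost=%s",
        config.preset or "custom", len(queries), config.ranker,
        config.expansion_model, config.boost_enabled,
    )
    return PipelineResult(run=final, intermediate=intermediate, report=report, config=config)
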