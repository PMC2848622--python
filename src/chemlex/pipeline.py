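"""Four-stage curation-and-tagging pipeline with a stage report.

The pipeline mirrors the standard comparison layout for dictionary-based
chemical taggers: the same corpus is indexed with the dictionary in four
cumulative conditions —

1. **unprocessed** — the raw dictionary, largest-match tagging only;
2. **filtered** — after the rule-1/2 term removals and the three rewrite
   rules;
3. **frequent terms correction** — additionally applying the reviewed
   stoplist of general-English terms;
4. **disambiguation** — additionally applying the homonym rules.

Each stage is scored against gold with exact boundaries, so the report
shows precision/recall/F per condition, and every removal, rewrite and
disambiguation decision is logged machine-readably — the final annotation
set is reproducible from the raw dictionary plus the logs.

Replicating the comparison on real data is a configuration swap: point the
pipeline at a real dictionary TSV and a real .txt/.ann corpus.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .dictionary import Dictionary
from .disambiguation import DisambiguationConfig, build_keyword_table, disambiguate
from .evaluation import (
    EvaluationReport, GoldAnnotation, categorize_errors, evaluate, round_half_up,
)
from .filters import FilterConfig, RemovalLogEntry, apply_removal_rules, apply_rewrite_rules
from .matcher import Annotation, build_index, find_matches
from .tokenizer import TokenizerConfig

__all__ = ["PipelineConfig", "StageResult", "PipelineResult", "run_pipeline",
           "format_stage_table"]

STAGES = ("unprocessed", "filtered", "stoplisted", "disambiguated")


@dataclass(frozen=True)
class PipelineConfig:
    """Aggregate of the per-module configurations.

    ``from_yaml`` reads a nested mapping with sections ``filter``,
    ``tokenizer`` and ``disambiguation``; unknown keys anywhere are
    rejected so a typo cannot silently fall back to a default.
    """

    filter: FilterConfig = field(default_factory=FilterConfig)
    tokenizer: TokenizerConfig = field(default_factory=TokenizerConfig)
    disambiguation: DisambiguationConfig = field(default_factory=DisambiguationConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known_sections = {"filter", "tokenizer", "disambiguation"}
        unknown = set(raw) - known_sections
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")

        def build(section: str, factory, **coerce):
            data = dict(raw.get(section, {}))
            import dataclasses

            allowed = {f.name for f in dataclasses.fields(factory)}
            bad = set(data) - allowed
            if bad:
                raise ValueError(f"unknown keys in [{section}]: {sorted(bad)}")
            for key, fn in coerce.items():
                if key in data:
                    data[key] = fn(data[key])
            return factory(**data)

        tok = build(
            "tokenizer", TokenizerConfig,
            delimiter_exceptions=frozenset, suffix_list=tuple,
        )
        flt = build(
            "filter", FilterConfig,
            stopwords=frozenset, stoplist=frozenset, roman_allowlist=frozenset,
            feature_patterns=lambda v: tuple(tuple(p) for p in v),
        )
        flt = replace(flt, tokenizer=tok)
        dis = build("disambiguation", DisambiguationConfig)
        return cls(filter=flt, tokenizer=tok, disambiguation=dis)


@dataclass(frozen=True)
class StageResult:
    stage: str
    n_active_terms: int
    annotations: tuple[Annotation, ...]
    report: EvaluationReport | None


@dataclass(frozen=True)
class PipelineResult:
    stages: tuple[StageResult, ...]
    raw_dictionary: Dictionary
    final_dictionary: Dictionary
    removal_log: tuple[RemovalLogEntry, ...]
    n_rewrites_added: int
    error_table: dict[str, int]

    def stage(self, name: str) -> StageResult:
        for s in self.stages:
            if s.stage == name:
                return s
        raise KeyError(name)


def _tag_corpus(
    d: Dictionary, docs: Mapping[str, str], cfg: PipelineConfig
) -> list[Annotation]:
    idx = build_index(d, cfg.tokenizer)
    out: list[Annotation] = []
    for doc_id in sorted(docs):
        out.extend(find_matches(docs[doc_id], idx, cfg.tokenizer, doc_id=doc_id))
    return out


def run_pipeline(
    d: Dictionary,
    docs: Mapping[str, str],
    gold: Sequence[GoldAnnotation] | None = None,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run all four stages over ``docs`` and score each against ``gold``.

    Stage 2 applies removal rules 1-2 with an *empty* stoplist plus the
    rewrite rules; stage 3 re-applies removal with the configured stoplist
    (idempotent on the earlier removals); stage 4 adds disambiguation.
    """
    cfg = config or PipelineConfig()
    stages: list[StageResult] = []

    def _stage(name: str, dictionary: Dictionary, anns: list[Annotation]) -> None:
        kept = [a for a in anns if a.status == "kept"]
        report = evaluate(kept, gold) if gold is not None else None
        stages.append(StageResult(name, dictionary.n_terms(), tuple(anns), report))

    # 1. unprocessed
    anns_raw = _tag_corpus(d, docs, cfg)
    _stage("unprocessed", d, anns_raw)

    # 2. filtered: rules 1-2, then rewrites
    no_stoplist = replace(cfg.filter, stoplist=frozenset())
    d_filt, log12 = apply_removal_rules(d, no_stoplist)
    d_filt, n_added = apply_rewrite_rules(d_filt)
    anns_filt = _tag_corpus(d_filt, docs, cfg)
    _stage("filtered", d_filt, anns_filt)

    # 3. frequent terms correction: the reviewed stoplist
    d_stop, log3 = apply_removal_rules(d_filt, cfg.filter)
    anns_stop = _tag_corpus(d_stop, docs, cfg)
    _stage("stoplisted", d_stop, anns_stop)

    # 4. disambiguation
    kt = build_keyword_table(d_stop, cfg.disambiguation, cfg.tokenizer)
    idx = build_index(d_stop, cfg.tokenizer)
    by_doc: dict[str, list[Annotation]] = {}
    for a in anns_stop:
        by_doc.setdefault(a.doc_id, []).append(a)
    anns_dis: list[Annotation] = []
    for doc_id in sorted(docs):
        anns_dis.extend(
            disambiguate(by_doc.get(doc_id, []), docs[doc_id], d_stop, kt,
                         cfg.disambiguation, cfg.tokenizer, idx=idx)
        )
    _stage("disambiguated", d_stop, anns_dis)

    error_table: dict[str, int] = {}
    if gold is not None:
        kept_final = [a for a in anns_dis if a.status == "kept"]
        error_table, _, _ = categorize_errors(
            kept_final, gold, d, d_stop, anns_stop, tuple(log12) + tuple(log3)
        )
    return PipelineResult(
        stages=tuple(stages),
        raw_dictionary=d,
        final_dictionary=d_stop,
        removal_log=tuple(log12) + tuple(log3),
        n_rewrites_added=n_added,
        error_table=error_table,
    )


def format_stage_table(result: PipelineResult) -> str:
    """Four-condition P/R/F table (two decimals, round-half-up)."""
    header = "stage\tactive_terms\tTP\tFP\tFN\tP\tR\tF"
    lines = [header]
    for s in result.stages:
        if s.report is None:
            lines.append(f"{s.stage}\t{s.n_active_terms}\t-\t-\t-\t-\t-\t-")
            continue
        r = s.report
        lines.append(
            f"{s.stage}\t{s.n_active_terms}\t{r.counts.tp}\t{r.counts.fp}\t{r.counts.fn}\t"
            f"{round_half_up(r.precision):.2f}\t{round_half_up(r.recall):.2f}\t"
            f"{round_half_up(r.f_score):.2f}"
        )
    return "\n".join(lines)
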