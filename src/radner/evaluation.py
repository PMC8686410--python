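"""Strict-boundary entity-level evaluation and the man–machine comparison.

A predicted entity counts as a true positive only if its type, start
boundary and end boundary all equal a gold entity's in the same document
(strict matching).  Precision, recall and F1 = 2PR/(P+R) are computed from
TP/FP/FN counts pooled per entity type and — for the micro average — pooled
over all types.  Zero-denominator convention: P (or R) is 0 when its
denominator is 0, and F1 is 0 when P + R = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import mean, stdev
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .documents import ENTITY_TYPES, AnnotatedDocument

MICRO = "micro"


@dataclass(frozen=True)
class TypeScore:
    """TP/FP/FN counts and the derived precision/recall/F1 (fractions)."""

    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else 0.0

    @property
    def recall(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0

    def __add__(self, other: "TypeScore") -> "TypeScore":
        return TypeScore(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


@dataclass(frozen=True)
class EvalReport:
    """Per-type scores plus the pooled micro average."""

    per_type: Mapping[str, TypeScore]
    micro: TypeScore

    def as_frame(self, percent: bool = True) -> pd.DataFrame:
        scale = 100.0 if percent else 1.0
        rows = []
        for name in (*ENTITY_TYPES, MICRO):
            s = self.micro if name == MICRO else self.per_type[name]
            rows.append(
                {
                    "entity": name,
                    "tp": s.tp, "fp": s.fp, "fn": s.fn,
                    "precision": scale * s.precision,
                    "recall": scale * s.recall,
                    "f1": scale * s.f1,
                }
            )
        return pd.DataFrame(rows)


def f1(p: float, r: float) -> float:
    """Harmonic mean 2PR/(P+R) on the scale of its inputs (e.g. percents)."""
    if p < 0 or r < 0:
        raise ValueError("precision and recall must be non-negative")
    if p + r == 0:
        return 0.0
    return 2 * p * r / (p + r)


def _pair_by_id(
    gold: Sequence[AnnotatedDocument], pred: Sequence[AnnotatedDocument]
) -> list[tuple[AnnotatedDocument, AnnotatedDocument]]:
    gmap = {d.doc_id: d for d in gold}
    pmap = {d.doc_id: d for d in pred}
    if len(gmap) != len(gold) or len(pmap) != len(pred):
        raise ValueError("duplicate doc_id in gold or prediction list")
    if set(gmap) != set(pmap):
        missing = set(gmap) ^ set(pmap)
        raise ValueError(f"gold/prediction doc_id mismatch: {sorted(missing)[:5]}")
    return [(gmap[i], pmap[i]) for i in sorted(gmap)]


def strict_match_score(
    gold: Sequence[AnnotatedDocument], pred: Sequence[AnnotatedDocument]
) -> EvalReport:
    """Strict-match entity scoring, pooled per type and micro over all types."""
    counts = {t: [0, 0, 0] for t in ENTITY_TYPES}  # tp, fp, fn
    for g, p in _pair_by_id(gold, pred):
        gset, pset = g.span_set(), p.span_set()
        for etype, start, end in pset & gset:
            counts[etype][0] += 1
        for etype, start, end in pset - gset:
            counts[etype][1] += 1
        for etype, start, end in gset - pset:
            counts[etype][2] += 1
    per_type = {t: TypeScore(*c) for t, c in counts.items()}
    micro = TypeScore(0, 0, 0)
    for s in per_type.values():
        micro = micro + s
    return EvalReport(per_type, micro)


@dataclass(frozen=True)
class RunAggregate:
    """Mean and sample standard deviation (n-1) of metrics over n runs."""

    n_runs: int
    table: pd.DataFrame  # entity x {precision,recall,f1} x {mean,sd}

    def formatted(self, decimals: int = 1, sd_decimals: int = 2) -> pd.DataFrame:
        """"mean (SD)" strings per entity and metric, on the percent scale."""
        out = {}
        for metric in ("precision", "recall", "f1"):
            out[metric] = [
                f"{m:.{decimals}f} ({s:.{sd_decimals}f})"
                for m, s in zip(
                    self.table[(metric, "mean")], self.table[(metric, "sd")]
                )
            ]
        return pd.DataFrame(out, index=self.table.index)


def aggregate_runs(reports: Sequence[EvalReport]) -> RunAggregate:
    """Aggregate repeated-run reports: per-metric mean and sample SD (percent)."""
    if len(reports) < 2:
        raise ValueError("need at least 2 runs to aggregate")
    type_sets = {tuple(sorted(r.per_type)) for r in reports}
    if len(type_sets) != 1:
        raise ValueError("reports disagree on entity types")
    rows = {}
    for name in (*ENTITY_TYPES, MICRO):
        scores = [
            r.micro if name == MICRO else r.per_type[name] for r in reports
        ]
        row = {}
        for metric in ("precision", "recall", "f1"):
            vals = [100.0 * getattr(s, metric) for s in scores]
            row[(metric, "mean")] = mean(vals)
            row[(metric, "sd")] = stdev(vals)
        rows[name] = row
    table = pd.DataFrame(rows).T
    table.columns = pd.MultiIndex.from_tuples(table.columns)
    return RunAggregate(len(reports), table)


@dataclass(frozen=True)
class Disagreement:
    """Spans one candidate got wrong in one document."""

    candidate: str
    doc_id: str
    missing: tuple[tuple[str, int, int], ...]   # gold spans not predicted
    spurious: tuple[tuple[str, int, int], ...]  # predicted spans not in gold


@dataclass(frozen=True)
class ComparisonResult:
    """Side-by-side candidate evaluation (the man–machine comparison shape)."""

    table: pd.DataFrame
    reports: Mapping[str, EvalReport]
    disagreements: tuple[Disagreement, ...] = field(default=())


def compare_candidates(
    gold: Sequence[AnnotatedDocument],
    candidates: Mapping[str, Sequence[AnnotatedDocument]],
) -> ComparisonResult:
    """Evaluate several candidate annotation sets against one gold standard.

    Used for man–machine comparison: candidates are e.g. a model's
    predictions and human annotators' extractions over the same documents.
    Returns per-candidate per-type and micro P/R/F1 plus per-document
    disagreement listings.
    """
    reports = {}
    rows = []
    disagreements: list[Disagreement] = []
    for name, pred in candidates.items():
        report = strict_match_score(gold, pred)
        reports[name] = report
        frame = report.as_frame()
        frame.insert(0, "candidate", name)
        rows.append(frame)
        for g, p in _pair_by_id(gold, pred):
            missing = tuple(sorted(g.span_set() - p.span_set()))
            spurious = tuple(sorted(p.span_set() - g.span_set()))
            if missing or spurious:
                disagreements.append(
                    Disagreement(name, g.doc_id, missing, spurious)
                )
    table = pd.concat(rows, ignore_index=True)
    return ComparisonResult(table, reports, tuple(disagreements))
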