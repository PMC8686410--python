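"""Synthetic annotated ADE-narrative generator.

Real adverse-drug-event report narratives are short clinical stories —
why a drug was given (Reason), which drug (Drug, including trade names and
mixed-script abbreviations like "10%GS"), what reaction followed (ADR), and
how it resolved — and are not publicly available.  This generator emulates
their *structure*: Chinese-character templates with typed slots
(reason → drug administration → ADR onset → outcome) filled from closed
entity lexicons, with optional distractor filler sentences.  Every placed
lexicon item is recorded as an entity span whose text slice equals the
surface form exactly, so generated corpora are valid gold annotations by
construction.

``corrupt_annotations`` simulates an imperfect human annotator (dropped,
boundary-shifted, or type-swapped spans) for exercising the man–machine
comparison.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np

from .documents import ENTITY_TYPES, AnnotatedDocument, EntitySpan

REASONS = (
    "糖尿病", "高血压", "冠心病", "肺部感染", "上呼吸道感染", "支气管哮喘",
    "慢性胃炎", "腰椎间盘突出", "术后感染", "关节炎", "骨折", "乙型肝炎",
    "胆囊炎", "消化性溃疡", "脑梗死", "急性咽炎",
)
DRUGS = (
    "左氧氟沙星", "阿莫西林", "头孢拉定", "青霉素", "甲硝唑", "阿奇霉素",
    "布洛芬", "对乙酰氨基酚", "阿司匹林", "氯化钠注射液", "葡萄糖注射液",
    "10%GS", "0.9%NS", "VitC", "地塞米松", "泼尼松", "胰岛素", "环丙沙星",
)
ADRS = (
    "皮疹", "瘙痒", "恶心", "呕吐", "头晕", "腹泻", "胸闷", "心悸", "寒战",
    "面色苍白", "呼吸困难", "四肢乏力", "皮肤潮红", "局部红肿", "烦躁不安",
    "静脉炎",
)

#: Narrative skeletons.  {Reason}/{Drug}/{ADR} are entity slots (a trailing
#: digit distinguishes repeated slots); {N} is a small number, not an entity.
TEMPLATES = (
    "患者因{Reason}使用{Drug}，用药后出现{ADR}，停药后症状缓解。",
    "患者因{Reason}静滴{Drug}，约{N}分钟后出现{ADR}，经对症处理后好转。",
    "患者因{Reason}口服{Drug}治疗，{N}天后出现{ADR}，停药后症状消失。",
    "患者因{Reason}给予{Drug}及{Drug2}联合治疗，用药期间出现{ADR}。",
    "患者因{Reason}输注{Drug}，输液过程中出现{ADR}及{ADR2}，立即停药。",
    "患者自述因{Reason}服用{Drug}后出现{ADR}，就诊后给予对症治疗。",
    "患者因{Reason}使用{Drug}，第{N}天出现{ADR}，医嘱停药并观察。",
    "患者因{Reason}应用{Drug}抗感染治疗，用药后出现{ADR}，减慢滴速后缓解。",
)

#: Distractor sentences containing no entity mention, inserted at the
#: configured noise rate to break up the template regularity.
FILLERS = (
    "具体用药情况不详。",
    "患者既往体健。",
    "门诊随访未见异常。",
    "复查血常规大致正常。",
    "嘱患者多饮水休息。",
)

_SLOT = re.compile(r"\{(Reason|Drug|ADR)(\d*)\}|\{N\}")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for corpus generation.

    ``n_docs`` documents are built from ``templates`` filled from the
    per-type ``lexicons``; each document concatenates template sentences
    until its length falls inside ``length_range``.  ``noise_rate`` is the
    per-sentence probability of appending a distractor filler sentence.
    Identical (config, seed) pairs regenerate byte-identical corpora.
    """

    n_docs: int = 200
    seed: int = 0
    lexicons: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {"Reason": REASONS, "Drug": DRUGS, "ADR": ADRS}
    )
    templates: tuple[str, ...] = TEMPLATES
    fillers: tuple[str, ...] = FILLERS
    noise_rate: float = 0.1
    length_range: tuple[int, int] = (20, 160)

    def __post_init__(self) -> None:
        if self.n_docs < 0:
            raise ValueError("n_docs must be non-negative")
        if not (0.0 <= self.noise_rate <= 1.0):
            raise ValueError("noise_rate must be a probability")
        for etype in ENTITY_TYPES:
            if not self.lexicons.get(etype):
                raise ValueError(f"empty lexicon for entity type {etype}")
        for tpl in self.templates:
            for m in _SLOT.finditer(tpl):
                if m.group(1) and not self.lexicons.get(m.group(1)):
                    raise ValueError(
                        f"template references empty lexicon {m.group(1)!r}"
                    )
        lo, hi = self.length_range
        if not (0 < lo <= hi):
            raise ValueError("invalid length_range")


def _fill_template(
    tpl: str, lexicons: dict[str, tuple[str, ...]], rng: np.random.Generator
) -> tuple[str, list[EntitySpan]]:
    """Fill one template; returns the sentence and its entity spans."""
    out: list[str] = []
    spans: list[EntitySpan] = []
    pos = 0
    cursor = 0
    for m in _SLOT.finditer(tpl):
        out.append(tpl[cursor : m.start()])
        pos += m.start() - cursor
        cursor = m.end()
        if m.group(1) is None:  # {N}
            surface = str(rng.integers(1, 15))
        else:
            etype = m.group(1)
            lex = lexicons[etype]
            surface = lex[rng.integers(len(lex))]
            spans.append(EntitySpan(pos, pos + len(surface), etype))
        out.append(surface)
        pos += len(surface)
    out.append(tpl[cursor:])
    return "".join(out), spans


def generate_corpus(cfg: GeneratorConfig) -> list[AnnotatedDocument]:
    """Generate ``cfg.n_docs`` annotated narratives (deterministic in seed)."""
    rng = np.random.default_rng(cfg.seed)
    docs = []
    lo, hi = cfg.length_range
    for i in range(cfg.n_docs):
        text_parts: list[str] = []
        spans: list[EntitySpan] = []
        length = 0
        while length < lo:
            tpl = cfg.templates[rng.integers(len(cfg.templates))]
            sent, sent_spans = _fill_template(tpl, cfg.lexicons, rng)
            if length + len(sent) > hi and length > 0:
                break
            text_parts.append(sent)
            spans.extend(sp.shifted(length) for sp in sent_spans)
            length += len(sent)
            if cfg.fillers and rng.random() < cfg.noise_rate:
                filler = cfg.fillers[rng.integers(len(cfg.fillers))]
                if length + len(filler) <= hi:
                    text_parts.append(filler)
                    length += len(filler)
        docs.append(
            AnnotatedDocument(f"syn-{i:04d}", "".join(text_parts), tuple(spans))
        )
    return docs


def train_test_corpora(
    n_train: int = 200, n_test: int = 50, seed: int = 0, **kwargs
) -> tuple[list[AnnotatedDocument], list[AnnotatedDocument]]:
    """Disjoint train/test corpora from consecutive seed streams."""
    train = generate_corpus(GeneratorConfig(n_docs=n_train, seed=seed, **kwargs))
    test = generate_corpus(GeneratorConfig(n_docs=n_test, seed=seed + 1, **kwargs))
    test = [replace(d, doc_id=d.doc_id.replace("syn-", "syn-test-")) for d in test]
    return train, test


def corrupt_annotations(
    docs: list[AnnotatedDocument],
    error_rate: float,
    seed: int = 0,
    drop_prob: float = 0.5,
    shift_prob: float = 0.3,
    swap_prob: float = 0.2,
) -> list[AnnotatedDocument]:
    """Simulate an imperfect annotator: corrupt each span with ``error_rate``.

    A corrupted span is dropped, boundary-shifted by ±1 character, or
    type-swapped, with the given relative sub-probabilities.  A shift that
    would leave the document's bounds or collide with a neighboring span
    falls back to dropping.  Every corruption breaks strict matching, so
    expected recall against the originals is 1 − error_rate.
    """
    if not (0.0 <= error_rate <= 1.0):
        raise ValueError("error_rate must be a probability")
    total = drop_prob + shift_prob + swap_prob
    if total <= 0:
        raise ValueError("sub-probabilities must not all be zero")
    cut_drop = drop_prob / total
    cut_shift = cut_drop + shift_prob / total
    rng = np.random.default_rng(seed)
    out = []
    for doc in docs:
        kept: list[EntitySpan] = []
        for sp in doc.entities:
            if rng.random() >= error_rate:
                kept.append(sp)
                continue
            u = rng.random()
            if u < cut_drop:
                continue
            if u < cut_shift:
                delta = 1 if rng.random() < 0.5 else -1
                side_start = rng.random() < 0.5
                start = sp.start + (delta if side_start else 0)
                end = sp.end + (0 if side_start else delta)
                # conservative neighbor check against all original spans so a
                # shift can never produce an overlapping annotation set
                neighbors = [o for o in doc.entities if o != sp]
                if 0 <= start < end <= len(doc.text) and not any(
                    o.start < end and start < o.end for o in neighbors
                ):
                    kept.append(EntitySpan(start, end, sp.etype))
                continue
            others = [t for t in ENTITY_TYPES if t != sp.etype]
            kept.append(
                EntitySpan(sp.start, sp.end, others[rng.integers(len(others))])
            )
        out.append(AnnotatedDocument(doc.doc_id, doc.text, tuple(sorted(kept))))
    return out
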