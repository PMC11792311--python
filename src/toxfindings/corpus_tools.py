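"""Corpus-side computations: agreement, consensus, statistics, evaluation.

Inter-annotator agreement uses Krippendorff's alpha with the nominal
distance, computed from the coincidence matrix over pairable values.  The
agreement unit is the token-level category label (ADVERSE_OBSERVATION /
CDOG / OUTSIDE) — the strictest unit compatible with span annotations.
Group-level coefficients are averaged with decimal half-up rounding.

Evaluation follows the exact-match regime for NER (a predicted mention is
correct only if start, end and category all equal a gold mention) and
standard per-class precision/recall/F1 plus confusion matrix and error
rate for the sentence classifier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np

from .model import Category, EntityMention, Sentence
from .normalise import TerminologyStore, normalise_all
from .preprocess import preprocess_text

OUTSIDE = "OUTSIDE"
ADVERSE_OBSERVATION = "ADVERSE_OBSERVATION"
CDOG = "CDOG"

#: expression label -> entity categories it may contain
EXPRESSION_CATEGORIES = {
    ADVERSE_OBSERVATION: {Category.STUDY_TEST, Category.MANIFESTATION,
                          Category.FINDING, Category.SPECIMEN, Category.SEX},
    CDOG: {Category.DOSE, Category.GROUP},
}


def round_half_up(x: float, decimals: int = 2) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class AnnotatedSentence:
    text: str
    token_spans: list[tuple[int, int]]  # sentence-local token offsets
    labels: list[Optional[str]]  # one label per token; None = not coded

    def __post_init__(self) -> None:
        if len(self.token_spans) != len(self.labels):
            raise ValueError("one label per token required")
        for start, end in self.token_spans:
            if not (0 <= start < end <= len(self.text)):
                raise ValueError("token span outside sentence bounds")


@dataclass
class AnnotationDoc:
    annotator_id: str
    sentences: list[AnnotatedSentence]


def doc_from_spans(annotator_id: str, texts: Sequence[str],
                   spans: Sequence[Sequence[tuple[int, int, str]]]) -> AnnotationDoc:
    """Build a token-labelled doc from (start, end, label) expression spans."""
    sentences = []
    for text, sent_spans in zip(texts, spans):
        toks = []
        for s in preprocess_text(text):
            toks.extend((t.start, t.end) for t in s.tokens)
        labels: list[Optional[str]] = []
        for t_start, t_end in toks:
            label = OUTSIDE
            for s_start, s_end, s_label in sent_spans:
                if t_start >= s_start and t_end <= s_end:
                    label = s_label
                    break
            labels.append(label)
        sentences.append(AnnotatedSentence(text=text, token_spans=toks,
                                           labels=labels))
    return AnnotationDoc(annotator_id=annotator_id, sentences=sentences)


@dataclass
class AlphaResult:
    category: str
    alpha: float
    n_units: int
    n_coders: int
    undefined: bool = False


def _unit_values(docs: Sequence[AnnotationDoc],
                 category: Optional[str]) -> list[list[str]]:
    """Pairable values per unit (token position), across coders.

    With a specific category, labels are binarised to category/OUTSIDE
    ("nominal/strict" per category); with None or "General" the full label
    set is kept.
    """
    shape = [(len(s.labels)) for s in docs[0].sentences]
    for doc in docs[1:]:
        if [(len(s.labels)) for s in doc.sentences] != shape:
            raise ValueError("annotators must cover the same tokenised "
                             "sentences")
    binarise = category is not None and category.lower() != "general"
    units: list[list[str]] = []
    for si in range(len(shape)):
        for ti in range(shape[si]):
            values = []
            for doc in docs:
                label = doc.sentences[si].labels[ti]
                if label is None:
                    continue
                if binarise:
                    label = label if label == category else OUTSIDE
                values.append(label)
            units.append(values)
    return units


def krippendorff_alpha(docs: Sequence[AnnotationDoc],
                       category: Optional[str] = None) -> AlphaResult:
    """Nominal Krippendorff's alpha over token-level labels.

    alpha = 1 - D_o/D_e via the coincidence matrix; units with fewer than
    two codings are excluded.  When every pairable value is identical the
    expected disagreement is zero and the result is flagged undefined
    rather than raising.
    """
    if len(docs) < 2:
        raise ValueError("at least two annotators required")
    units = [u for u in _unit_values(docs, category) if len(u) >= 2]
    values = sorted({v for u in units for v in u})
    index = {v: i for i, v in enumerate(values)}
    k = len(values)
    coincidence = np.zeros((k, k))
    for u in units:
        m = len(u)
        for i, a in enumerate(u):
            for j, b in enumerate(u):
                if i != j:
                    coincidence[index[a], index[b]] += 1.0 / (m - 1)
    n_c = coincidence.sum(axis=1)
    n = n_c.sum()
    d_o = (coincidence.sum() - np.trace(coincidence)) / n if n else 0.0
    d_e = (n * n - (n_c ** 2).sum()) / (n * (n - 1)) if n > 1 else 0.0
    if d_e == 0.0:
        return AlphaResult(category=category or "General", alpha=math.nan,
                           n_units=len(units), n_coders=len(docs),
                           undefined=True)
    return AlphaResult(category=category or "General",
                       alpha=1.0 - d_o / d_e, n_units=len(units),
                       n_coders=len(docs))


def average_group_alphas(values: Sequence[float], decimals: int = 2) -> float:
    """Arithmetic mean of per-group coefficients, rounded half-up."""
    if not values:
        raise ValueError("no group coefficients to average")
    return round_half_up(sum(values) / len(values), decimals)


def divide_into_sets(n: int, k: int = 4, seed: int = 0) -> list[list[int]]:
    """Near-equal seeded division of 0..n-1 into k sets.

    The first ``n % k`` sets receive one extra element (2933 items over 4
    sets gives 734/733/733/733).
    """
    if k <= 0:
        raise ValueError("k must be positive")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n).tolist()
    base, extra = divmod(n, k)
    sets, pos = [], 0
    for i in range(k):
        size = base + (1 if i < extra else 0)
        sets.append(perm[pos:pos + size])
        pos += size
    return sets


def harmonise(docs: Sequence[AnnotationDoc]
              ) -> tuple[AnnotationDoc, list[tuple[int, int, dict[str, int]]]]:
    """Token-level majority-vote consensus.

    A label enters the consensus when chosen by a strict majority of the
    coders; ties and majority-absent tokens become conflicts
    (sentence index, token index, label counts) for human adjudication.
    """
    if len(docs) < 2:
        raise ValueError("at least two annotators required")
    shape = [len(s.labels) for s in docs[0].sentences]
    for doc in docs[1:]:
        if [len(s.labels) for s in doc.sentences] != shape:
            raise ValueError("annotators must cover the same sentences")
    n_coders = len(docs)
    consensus_sentences = []
    conflicts: list[tuple[int, int, dict[str, int]]] = []
    for si, ref in enumerate(docs[0].sentences):
        labels: list[Optional[str]] = []
        for ti in range(len(ref.labels)):
            counts: dict[str, int] = {}
            for doc in docs:
                label = doc.sentences[si].labels[ti]
                if label is not None:
                    counts[label] = counts.get(label, 0) + 1
            best = max(counts.values(), default=0)
            winners = [l for l, c in counts.items() if c == best]
            if len(winners) == 1 and best > n_coders / 2:
                labels.append(winners[0])
            else:
                labels.append(None)
                conflicts.append((si, ti, counts))
        consensus_sentences.append(AnnotatedSentence(
            text=ref.text, token_spans=list(ref.token_spans), labels=labels))
    return (AnnotationDoc(annotator_id="consensus",
                          sentences=consensus_sentences), conflicts)


def expressions_to_entities(doc: AnnotationDoc, store: TerminologyStore
                            ) -> tuple[list[tuple[str, list[EntityMention]]],
                                       list[tuple[int, tuple[int, int, str]]]]:
    """Standardise expression spans into entity mentions.

    The gazetteer/pattern tagger and the normaliser run inside the
    expression spans only: ADVERSE_OBSERVATION spans may yield study
    test / manifestation / finding / specimen / sex mentions, CDOG spans
    dose / group.  Expressions with no lexicon hit are flagged for review
    as (sentence index, span).
    """
    from .ner import tag_baseline  # local import avoids a cycle

    out: list[tuple[str, list[EntityMention]]] = []
    flagged: list[tuple[int, tuple[int, int, str]]] = []
    for si, sent_ann in enumerate(doc.sentences):
        spans = _runs_to_spans(sent_ann)
        sentences = preprocess_text(sent_ann.text)
        mentions: list[EntityMention] = []
        for s in sentences:
            mentions.extend(tag_baseline(s, store))
        kept: list[EntityMention] = []
        for span in spans:
            s_start, s_end, label = span
            allowed = EXPRESSION_CATEGORIES.get(label, set())
            inside = [m for m in mentions
                      if m.start >= s_start and m.end <= s_end
                      and m.category in allowed]
            if inside:
                kept.extend(normalise_all(inside, store))
            else:
                flagged.append((si, span))
        kept.sort(key=lambda m: m.start)
        out.append((sent_ann.text, kept))
    return out, flagged


def _runs_to_spans(sent: AnnotatedSentence) -> list[tuple[int, int, str]]:
    spans = []
    current: Optional[tuple[int, int, str]] = None
    for (t_start, t_end), label in zip(sent.token_spans, sent.labels):
        if label in (None, OUTSIDE):
            if current:
                spans.append(current)
                current = None
            continue
        if current and current[2] == label:
            current = (current[0], t_end, label)
        else:
            if current:
                spans.append(current)
            current = (t_start, t_end, label)
    if current:
        spans.append(current)
    return spans


def corpus_stats(corpus: Sequence[tuple[Sentence, list[EntityMention]]]
                 ) -> dict[str, int]:
    """Direct tallies: per-category mention counts, relevant/non-relevant
    sentence counts, token and sentence totals."""
    from .model import Relevance

    stats = {c.value: 0 for c in Category}
    stats.update({"relevant_sentences": 0, "non_relevant_sentences": 0,
                  "tokens": 0, "sentences": 0})
    for sentence, mentions in corpus:
        stats["sentences"] += 1
        stats["tokens"] += len(sentence.tokens)
        if sentence.relevance == Relevance.RELEVANT:
            stats["relevant_sentences"] += 1
        else:
            stats["non_relevant_sentences"] += 1
        for m in mentions:
            stats[m.category.value] += 1
    return stats


@dataclass
class EvalMetrics:
    labels: list[str]
    per_label: dict[str, dict[str, float]]
    macro: dict[str, float] = field(default_factory=dict)
    weighted: dict[str, float] = field(default_factory=dict)
    micro: dict[str, float] = field(default_factory=dict)
    accuracy: Optional[float] = None
    error_rate_percent: Optional[float] = None
    confusion: Optional[list[list[int]]] = None

    def to_text(self) -> str:
        lines = [f"{'label':<22}{'P':>8}{'R':>8}{'F1':>8}{'support':>9}"]
        for label in self.labels:
            m = self.per_label[label]
            lines.append(f"{label:<22}{m['precision']:>8.2f}{m['recall']:>8.2f}"
                         f"{m['f1']:>8.2f}{int(m.get('support', 0)):>9d}")
        if self.micro:
            lines.append(f"{'overall (micro)':<22}{self.micro['precision']:>8.2f}"
                         f"{self.micro['recall']:>8.2f}{self.micro['f1']:>8.2f}")
        if self.accuracy is not None:
            lines.append(f"accuracy: {self.accuracy:.4f}")
        if self.error_rate_percent is not None:
            lines.append(f"error rate: {self.error_rate_percent:.2f}%")
        return "\n".join(lines)

    def to_csv(self) -> str:
        lines = ["label,precision,recall,f1,support"]
        for label in self.labels:
            m = self.per_label[label]
            lines.append(f"{label},{m['precision']:.4f},{m['recall']:.4f},"
                         f"{m['f1']:.4f},{int(m.get('support', 0))}")
        return "\n".join(lines) + "\n"


def _prf(tp: int, fp: int, fn: int) -> dict[str, float]:
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return {"precision": p, "recall": r, "f1": f1, "support": tp + fn}


def evaluate_ner(pred: Sequence[tuple[str, list[EntityMention]]],
                 gold: Sequence[tuple[str, list[EntityMention]]],
                 mode: str = "exact_match") -> EvalMetrics:
    """Exact-match span evaluation: a prediction is a true positive iff
    (start, end, category) all match a gold mention."""
    if mode != "exact_match":
        raise ValueError(f"unsupported mode {mode!r}")
    if len(pred) != len(gold):
        raise ValueError("pred and gold must cover the same documents")
    counts = {c.value: {"tp": 0, "fp": 0, "fn": 0} for c in Category}
    for (p_text, p_mentions), (g_text, g_mentions) in zip(pred, gold):
        if p_text != g_text:
            raise ValueError("pred/gold text mismatch")
        p_set = {(m.start, m.end, m.category.value) for m in p_mentions}
        g_set = {(m.start, m.end, m.category.value) for m in g_mentions}
        for key in p_set & g_set:
            counts[key[2]]["tp"] += 1
        for key in p_set - g_set:
            counts[key[2]]["fp"] += 1
        for key in g_set - p_set:
            counts[key[2]]["fn"] += 1
    per_label = {lab: _prf(**c) for lab, c in counts.items()}
    tp = sum(c["tp"] for c in counts.values())
    fp = sum(c["fp"] for c in counts.values())
    fn = sum(c["fn"] for c in counts.values())
    micro = _prf(tp, fp, fn)
    present = [lab for lab in per_label if per_label[lab]["support"] > 0]
    macro = {k: (sum(per_label[lab][k] for lab in present) / len(present)
                 if present else 0.0)
             for k in ("precision", "recall", "f1")}
    return EvalMetrics(labels=[c.value for c in Category],
                       per_label=per_label, micro=micro, macro=macro)


def evaluate_classifier(pred_labels: Sequence, gold_labels: Sequence
                        ) -> EvalMetrics:
    """Per-class P/R/F1, macro and support-weighted averages, confusion
    matrix, accuracy and half-up-rounded percentage error rate."""
    from sklearn.metrics import confusion_matrix, precision_recall_fscore_support

    if len(pred_labels) != len(gold_labels):
        raise ValueError("pred and gold label lists must have equal length")
    labels = sorted(set(gold_labels) | set(pred_labels), key=str)
    p, r, f1, support = precision_recall_fscore_support(
        gold_labels, pred_labels, labels=labels, zero_division=0)
    per_label = {str(lab): {"precision": float(p[i]), "recall": float(r[i]),
                            "f1": float(f1[i]), "support": int(support[i])}
                 for i, lab in enumerate(labels)}
    total = len(gold_labels)
    errors = sum(1 for a, b in zip(pred_labels, gold_labels) if a != b)
    accuracy = (total - errors) / total if total else 0.0
    mp, mr, mf, _ = precision_recall_fscore_support(
        gold_labels, pred_labels, labels=labels, average="macro",
        zero_division=0)
    wp, wr, wf, _ = precision_recall_fscore_support(
        gold_labels, pred_labels, labels=labels, average="weighted",
        zero_division=0)
    return EvalMetrics(
        labels=[str(lab) for lab in labels],
        per_label=per_label,
        macro={"precision": float(mp), "recall": float(mr), "f1": float(mf)},
        weighted={"precision": float(wp), "recall": float(wr),
                  "f1": float(wf)},
        accuracy=accuracy,
        error_rate_percent=round_half_up(100.0 * errors / total, 2)
        if total else 0.0,
        confusion=confusion_matrix(gold_labels, pred_labels,
                                   labels=labels).tolist(),
    )
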