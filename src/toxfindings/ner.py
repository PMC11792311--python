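"""Named entity recognition over relevant sentences.

The deterministic baseline combines longest-match gazetteer lookup (over
surfaces and lemmas) for the dictionary-backed categories with pattern
rules for doses (number + unit grammar) and groups ("group A",
"high dose group", "12 mg/kg/day dose group").  Overlaps resolve
longest-match-first, then by category priority DOSE > GROUP > STUDY_TEST >
FINDING > SPECIMEN > MANIFESTATION > SEX — dose and group first because
their patterns are the most specific.

Spans are emitted under a BIO scheme; `decode_bio` turns tag sequences
back into mentions, repairing orphan I- tags to B-.

An optional transformer backend mirrors the training protocol used for
the published benchmark model (BioBERT-style encoder, epochs=7,
lr=5.760003080365119e-05, seed=4); it needs the `transformers` extra and
is never a silent fallback.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from importlib import util as _importlib_util
from pathlib import Path

from .model import (Category, ConfigurationError, EntityMention,
                    MissingDependencyError, Sentence, Token, TrainConfig)
from .normalise import TerminologyStore, _CAT_RANK
from .preprocess import preprocess_text

_GAZETTEER_CATEGORIES = [Category.STUDY_TEST, Category.FINDING,
                         Category.SPECIMEN, Category.MANIFESTATION,
                         Category.SEX]

_NUM = re.compile(r"^\d+(?:\.\d+)?$")
_UNIT_HEADS = {"mg", "g", "µg", "ug"}
_GROUP_ADJ = {"high", "low", "mid", "middle", "intermediate", "control",
              "top", "highest", "lowest"}
_GROUP_ID = re.compile(r"^(?:\d+|[A-Za-z]|[IVX]+)$")


def _match_dose(tokens: list[Token], i: int) -> int:
    """Length (in tokens) of a dose expression starting at token i, or 0."""
    if i >= len(tokens) or not _NUM.match(tokens[i].text):
        return 0
    j = i + 1
    if j < len(tokens) and tokens[j].text.lower() in _UNIT_HEADS:
        j += 1
        # optional /kg and /day suffixes
        for suffix in ("kg", "day"):
            if (j + 1 < len(tokens) and tokens[j].text == "/"
                    and tokens[j + 1].text.lower() == suffix):
                j += 2
        return j - i
    if j < len(tokens) and tokens[j].text.lower() == "ppm":
        return j - i + 1
    return 0


def _match_group(tokens: list[Token], i: int) -> int:
    """Length of a group expression starting at token i, or 0."""
    low = tokens[i].text.lower()
    # "group 1" / "group A"
    if low == "group" and i + 1 < len(tokens) and _GROUP_ID.match(tokens[i + 1].text):
        return 2
    # "high dose group" / "control group"
    if low in _GROUP_ADJ:
        if (i + 2 < len(tokens) and tokens[i + 1].text.lower() == "dose"
                and tokens[i + 2].text.lower() == "group"):
            return 3
        if low == "control" and i + 1 < len(tokens) \
                and tokens[i + 1].text.lower() == "group":
            return 2
    # "<dose> dose group"
    n = _match_dose(tokens, i)
    if n and i + n + 1 < len(tokens) \
            and tokens[i + n].text.lower() == "dose" \
            and tokens[i + n + 1].text.lower() == "group":
        return n + 2
    return 0


def _mention(sentence: Sentence, tokens: list[Token], i: int, n: int,
             category: Category) -> EntityMention:
    start = tokens[i].start
    end = tokens[i + n - 1].end
    return EntityMention(category=category, start=start, end=end,
                         text=sentence.text[start - sentence.start:
                                            end - sentence.start])


def tag_baseline(sentence: Sentence,
                 store: TerminologyStore) -> list[EntityMention]:
    """Tag one tokenised sentence with the gazetteer + pattern baseline."""
    if len(store) == 0:
        raise ConfigurationError("terminology store is empty")
    tokens = sentence.tokens
    candidates: list[EntityMention] = []

    # Pattern rules.
    for i in range(len(tokens)):
        n = _match_dose(tokens, i)
        if n:
            candidates.append(_mention(sentence, tokens, i, n, Category.DOSE))
        n = _match_group(tokens, i)
        if n:
            candidates.append(_mention(sentence, tokens, i, n, Category.GROUP))

    # Gazetteer: longest window first, on surfaces then lemmas.
    keys: dict[Category, set[str]] = {}
    max_len = 1
    for cat in _GAZETTEER_CATEGORIES:
        surf = set(store.surfaces(cat)) | set(store.lemma_surfaces(cat))
        keys[cat] = surf
        for k in surf:
            max_len = max(max_len, len(k.split()))
    for i in range(len(tokens)):
        for n in range(min(max_len, len(tokens) - i), 0, -1):
            window = tokens[i:i + n]
            surface = " ".join(t.text.lower() for t in window)
            lemmas = " ".join(t.lemma for t in window)
            for cat in _GAZETTEER_CATEGORIES:
                if surface in keys[cat] or lemmas in keys[cat]:
                    candidates.append(_mention(sentence, tokens, i, n, cat))

    # Longest-match-first, category priority on ties, greedy non-overlap.
    order = sorted(candidates, key=lambda m: (-(m.end - m.start),
                                              _CAT_RANK[m.category], m.start))
    chosen: list[EntityMention] = []
    for m in order:
        if all(m.end <= c.start or m.start >= c.end for c in chosen):
            chosen.append(m)
    chosen.sort(key=lambda m: m.start)
    return chosen


@dataclass
class TagSequence:
    tokens: list[Token]
    tags: list[str]

    def __post_init__(self) -> None:
        if len(self.tokens) != len(self.tags):
            raise ValueError("tokens and tags must align")


def encode_bio(sentence: Sentence, mentions: list[EntityMention]) -> TagSequence:
    """BIO tags for a sentence's (non-overlapping) mentions."""
    tags = ["O"] * len(sentence.tokens)
    for m in mentions:
        inside = [idx for idx, t in enumerate(sentence.tokens)
                  if t.start >= m.start and t.end <= m.end]
        for pos, idx in enumerate(inside):
            tags[idx] = ("B-" if pos == 0 else "I-") + m.category.value
    return TagSequence(tokens=list(sentence.tokens), tags=tags)


def decode_bio(seq: TagSequence, text: str | None = None,
               text_offset: int = 0) -> list[EntityMention]:
    """Decode maximal B..I runs into mentions.

    An orphan I-X (after O, sequence start, or a different category) is
    repaired to B-X.  Mention text is sliced from ``text`` when given,
    otherwise joined from token texts.
    """
    mentions: list[EntityMention] = []
    current: tuple[Category, int, int] | None = None  # (cat, i0, i1)

    def _flush() -> None:
        nonlocal current
        if current is None:
            return
        cat, i0, i1 = current
        start = seq.tokens[i0].start
        end = seq.tokens[i1].end
        if text is not None:
            mtext = text[start - text_offset:end - text_offset]
        else:
            mtext = " ".join(t.text for t in seq.tokens[i0:i1 + 1])
        mentions.append(EntityMention(category=cat, start=start, end=end,
                                      text=mtext))
        current = None

    for i, tag in enumerate(seq.tags):
        if tag == "O":
            _flush()
            continue
        prefix, label = tag.split("-", 1)
        cat = Category(label)
        if prefix == "I" and current is not None and current[0] == cat:
            current = (cat, current[1], i)
        else:  # B-, or orphan I- repaired to B-
            _flush()
            current = (cat, i, i)
    _flush()
    return mentions


def write_conll(sentences: list[Sentence],
                mentions_per_sentence: list[list[EntityMention]],
                path: str | Path) -> None:
    """token TAB tag lines, blank line between sentences."""
    lines = []
    for sent, mentions in zip(sentences, mentions_per_sentence):
        seq = encode_bio(sent, mentions)
        for tok, tag in zip(seq.tokens, seq.tags):
            lines.append(f"{tok.text}\t{tag}")
        lines.append("")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_conll(path: str | Path) -> list[tuple[list[str], list[str]]]:
    """Sentences as (token texts, BIO tags) pairs."""
    out: list[tuple[list[str], list[str]]] = []
    toks: list[str] = []
    tags: list[str] = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            if toks:
                out.append((toks, tags))
                toks, tags = [], []
            continue
        tok, tag = line.split("\t")
        toks.append(tok)
        tags.append(tag)
    if toks:
        out.append((toks, tags))
    return out


def write_standoff(docs: list[tuple[str, list[EntityMention]]],
                   path: str | Path) -> None:
    """JSON-lines standoff: {"text", "entities": [{start,end,category}]}."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for text, mentions in docs:
            fh.write(json.dumps({
                "text": text,
                "entities": [{"start": m.start, "end": m.end,
                              "category": m.category.value}
                             for m in mentions],
            }, ensure_ascii=False) + "\n")


def read_standoff(path: str | Path) -> list[tuple[str, list[EntityMention]]]:
    docs = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        d = json.loads(line)
        mentions = [EntityMention(category=Category(e["category"]),
                                  start=e["start"], end=e["end"],
                                  text=d["text"][e["start"]:e["end"]])
                    for e in d["entities"]]
        docs.append((d["text"], mentions))
    return docs


def tag_text(text: str, store: TerminologyStore) -> list[EntityMention]:
    """Convenience: preprocess raw text and tag every sentence."""
    mentions: list[EntityMention] = []
    for sent in preprocess_text(text):
        mentions.extend(tag_baseline(sent, store))
    return mentions


def finetune_ner_transformer(corpus, config: TrainConfig | None = None):
    """Benchmark-only transformer backend for NER.

    Fine-tunes a biomedical encoder on a BIO-tagged corpus with the
    optimised defaults (epochs=7, lr=5.760003080365119e-05, seed=4).
    Requires the ``transformers`` extra; raises rather than falling back.
    """
    config = (config or TrainConfig.ner_defaults()).validated()
    for mod in ("transformers", "torch"):
        if _importlib_util.find_spec(mod) is None:
            raise MissingDependencyError(
                f"NER fine-tuning requires {mod!r}; install the "
                "'transformers' extra")
    from .transformer_backend import finetune_token_classifier
    return finetune_token_classifier(corpus, config)
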