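"""Section extraction and standard linguistic preprocessing.

Study reports arrive as plain text; the narrative sections that record
findings (Summary, Results, Discussion, Conclusion) are located by soft
heading matching, then split into sentences and tokens with the surface
features (POS, lemma, shape, length) the downstream rules consume.

The preprocessor is a deterministic rule-based component: an
abbreviation-aware sentence splitter, a regex tokeniser that keeps
hyphenated compounds ("treatment-related") and ratio tokens ("M:E")
intact while splitting slashes ("mg", "/", "kg"), and a suffix-rule
lemmatiser with an exception table ("decreased basophils" lemmatises to
"decrease basophil").
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass

from .model import Relevance, Sentence, Token

log = logging.getLogger(__name__)

DEFAULT_SECTION_TITLES = ["Summary", "Results", "Conclusion", "Discussion"]


@dataclass
class SectionText:
    name: str
    text: str
    start: int
    end: int


_NUMBERING = re.compile(r"^(?:[0-9]+[.)]?|[IVXLC]+[.)])(?:[0-9.]*)\s+")


def _heading_key(line: str) -> str | None:
    """Canonical form of a line if it looks like a section heading, else None."""
    stripped = line.strip()
    if not stripped or len(stripped) > 60 or stripped.endswith("."):
        return None
    body = _NUMBERING.sub("", stripped).rstrip(":").strip()
    if not body or not body[0].isalpha() or len(body.split()) > 6:
        return None
    # Headings start upper-cased (or are all-caps) and never end with a
    # sentence-final period; compound titles keep lowercase continuations
    # ("Discussion and conclusions").
    if not (body[0].isupper() or body.isupper()):
        return None
    return body.lower()


def extract_sections(document_text: str,
                     target_titles: list[str] | None = None) -> list[SectionText]:
    """Locate target sections by soft title matching.

    Matching is case-insensitive, tolerates leading numbering
    ("3. DISCUSSION"), trailing colons, and compound titles containing the
    target ("Discussion and conclusions").  A section runs from its heading
    line to the next heading-like line (matched or not) or end of document.
    Returns an empty list, with a warning, when nothing matches; the caller
    may fall back to whole-document processing.
    """
    if not document_text:
        raise ValueError("document_text must be non-empty")
    titles = target_titles or DEFAULT_SECTION_TITLES
    if not titles:
        raise ValueError("target_titles must be non-empty")
    targets = {t.lower(): t for t in titles}

    # (char offset of line start, heading key or None, line)
    headings: list[tuple[int, str]] = []
    pos = 0
    for line in document_text.splitlines(keepends=True):
        key = _heading_key(line)
        if key is not None:
            headings.append((pos, key))
        pos += len(line)
    headings.append((len(document_text), ""))  # sentinel: end of document

    def _match(key: str) -> str | None:
        if key in targets:
            return targets[key]
        key_words = key.split()
        for t_low, t_orig in targets.items():
            t_words = t_low.split()
            for i in range(len(key_words) - len(t_words) + 1):
                if key_words[i:i + len(t_words)] == t_words:
                    return t_orig
        return None

    sections: list[SectionText] = []
    for i, (offset, key) in enumerate(headings[:-1]):
        name = _match(key)
        if name is None:
            continue
        body_start = document_text.find("\n", offset)
        body_start = offset if body_start == -1 else body_start + 1
        body_end = headings[i + 1][0]
        sections.append(SectionText(name=name,
                                    text=document_text[body_start:body_end],
                                    start=body_start, end=body_end))
    if not sections:
        log.warning("no section title matched %s; caller may process the "
                    "entire report", titles)
    return sections


# Abbreviations that never terminate a sentence (lower-case, no final dot).
ABBREVIATIONS = {
    "i.e", "e.g", "approx", "vs", "etc", "no", "fig", "figs", "dr", "al",
    "cf", "ca", "resp", "spp", "wk", "hr", "min", "max", "sec", "inc", "ltd",
}

_SENT_END = re.compile(r"[.!?]+")


def _is_boundary(text: str, end: int) -> bool:
    """True if the terminator ending at ``end`` closes a sentence."""
    nxt = end
    while nxt < len(text) and text[nxt] in " \t":
        nxt += 1
    if nxt < len(text) and text[nxt] not in "\n\r" and not (
            text[nxt].isupper() or text[nxt].isdigit() or text[nxt] in "\"'("):
        return False
    # Word immediately before the terminator.
    i = end - 1
    while i > 0 and text[i - 1] in ".!?":
        i -= 1
    j = i
    while j > 0 and (text[j - 1].isalnum() or text[j - 1] in ".'"):
        j -= 1
    word = text[j:i].lower().rstrip(".")
    if word in ABBREVIATIONS:
        return False
    if len(word) == 1 and word.isalpha():  # initials such as "J."
        return False
    return True


def split_sentences(text: str, offset: int = 0, start_id: int = 0) -> list[Sentence]:
    """Divide text into sentences with document-global offsets.

    The splitter never breaks inside dose expressions (the slash of
    "mg/kg" carries no terminator) and not after common abbreviations
    ("i.e.", "e.g.", "approx.").  Joining the sentence spans with the
    original gap characters reconstructs the input.
    """
    sentences: list[Sentence] = []
    if not text:
        return sentences
    boundaries: list[int] = []
    for m in _SENT_END.finditer(text):
        if _is_boundary(text, m.end()):
            boundaries.append(m.end())
    if not boundaries or boundaries[-1] != len(text):
        boundaries.append(len(text))
    prev = 0
    sid = start_id
    for b in boundaries:
        raw = text[prev:b]
        lead = len(raw) - len(raw.lstrip())
        chunk = raw.strip()
        if chunk:
            s_start = prev + lead
            sentences.append(Sentence(id=sid, text=chunk,
                                      start=offset + s_start,
                                      end=offset + s_start + len(chunk)))
            sid += 1
        prev = b
    return sentences


# Numbers (incl. decimals), words with internal hyphen/colon/apostrophe,
# then any single non-space character (slashes, commas, ...).
_TOKEN = re.compile(r"\d+(?:\.\d+)?|[A-Za-zµ]+(?:[-:'][A-Za-z]+)*|\S")

_LEMMA_EXC = {
    "was": "be", "were": "be", "is": "be", "are": "be", "been": "be",
    "has": "have", "had": "have", "does": "do", "did": "do",
    "faeces": "faeces", "feces": "feces", "species": "species",
    "mice": "mouse", "testes": "testis", "foci": "focus",
    "occurred": "occur", "seen": "see", "observed": "observe",
    "this": "this", "his": "his", "its": "its", "less": "less",
    "lungs": "lung", "analyses": "analysis",
}


def lemma_of(word: str) -> str:
    """Dictionary lemma via an exception table plus regular suffix rules."""
    w = word.lower()
    if w in _LEMMA_EXC:
        return _LEMMA_EXC[w]
    if not w.isalpha():
        return w
    if w.endswith("ies") and len(w) > 4:
        return w[:-3] + "y"
    if w.endswith("sses"):
        return w[:-2]
    if w.endswith("s") and not w.endswith(("ss", "us", "is")):
        return w[:-1]
    if w.endswith("ied") and len(w) > 4:
        return w[:-3] + "y"
    if w.endswith("ed") and len(w) > 3:
        stem = w[:-1]
        return stem if stem.endswith("e") else w[:-2]
    return w


def shape_of(word: str) -> str:
    """Case/digit pattern of a token ("30" -> "dd", "Kg" -> "Xx")."""
    out = []
    for ch in word:
        if ch.isdigit():
            out.append("d")
        elif ch.isalpha():
            out.append("X" if ch.isupper() else "x")
        else:
            out.append(ch)
    # Collapse runs longer than 4 to keep shapes compact.
    collapsed: list[str] = []
    for ch in out:
        if len(collapsed) >= 4 and all(c == ch for c in collapsed[-4:]):
            continue
        collapsed.append(ch)
    return "".join(collapsed)


_ADP = {"in", "at", "of", "on", "for", "with", "to", "by", "from", "after",
        "during", "under", "between"}
_DET = {"the", "a", "an", "this", "these", "those", "that"}
_CONJ = {"and", "or", "but", "nor"}
_VERB_LEMMAS = {"be", "have", "do", "observe", "note", "show", "see", "occur",
                "detect", "record", "report", "consider", "find", "reveal",
                "increase", "decrease", "remain", "appear", "attribute"}


def _pos_of(tok_text: str, lemma: str) -> str:
    if not tok_text[0].isalnum():
        return "PUNCT"
    if tok_text[0].isdigit():
        return "NUM"
    low = tok_text.lower()
    if low in _CONJ:
        return "CCONJ"
    if low in _ADP:
        return "ADP"
    if low in _DET:
        return "DET"
    if lemma in _VERB_LEMMAS:
        return "VERB"
    return "NOUN"


def tokenize_and_annotate(sentence: Sentence) -> Sentence:
    """Populate sentence.tokens with offsets, POS, lemma and shape."""
    tokens: list[Token] = []
    for m in _TOKEN.finditer(sentence.text):
        text = m.group()
        lem = lemma_of(text)
        tokens.append(Token(text=text,
                            start=sentence.start + m.start(),
                            end=sentence.start + m.end(),
                            pos=_pos_of(text, lem),
                            lemma=lem,
                            shape=shape_of(text)))
    sentence.tokens = tokens
    return sentence


def preprocess_text(text: str, offset: int = 0, start_id: int = 0) -> list[Sentence]:
    """Split into sentences and annotate tokens in one pass."""
    sentences = split_sentences(text, offset=offset, start_id=start_id)
    for s in sentences:
        tokenize_and_annotate(s)
    return sentences


def sentence_to_json(sentence: Sentence) -> str:
    """One-sentence JSON line with tokens and features."""
    return json.dumps({
        "id": sentence.id,
        "text": sentence.text,
        "start": sentence.start,
        "end": sentence.end,
        "relevance": sentence.relevance.value,
        "relevance_score": sentence.relevance_score,
        "tokens": [
            {"text": t.text, "start": t.start, "end": t.end, "pos": t.pos,
             "lemma": t.lemma, "shape": t.shape, "length": t.length}
            for t in sentence.tokens
        ],
    }, ensure_ascii=False)


def sentence_from_json(line: str) -> Sentence:
    d = json.loads(line)
    s = Sentence(id=d["id"], text=d["text"], start=d["start"], end=d["end"],
                 relevance=Relevance(d.get("relevance", "UNSET")),
                 relevance_score=d.get("relevance_score"))
    s.tokens = [Token(text=t["text"], start=t["start"], end=t["end"],
                      pos=t["pos"], lemma=t["lemma"], shape=t["shape"])
                for t in d.get("tokens", [])]
    return s
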