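"""Entity normalisation against controlled terminology.

Recognised mentions are linked to preferred terms from a layered set of
lexicons: SEND controlled terminology first, then SEND synonym extensions,
then eTOX-style and UMLS-style resources, then internal tables for the
simple categories (manifestation, sex).  Only terms resolved through the
SEND core list count as *controlled*; anything else keeps its preferred
term but is flagged non-controlled, mirroring how reports routinely use
vocabulary outside the standard.

The full CDISC SEND, eTOX and UMLS resources are licensed and not
redistributable; the packaged TSVs are compact stand-ins with identical
structure (the extensions file is synthetic), and drop-in replacements
load through the same interface.

Dose and group mentions are handled by lexical rules rather than
dictionaries: the dose parser extracts a numeric magnitude and a canonical
unit ("30 mg/kg", "20 mg/kg/day", "100 ppm").
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

from .model import (SOURCE_PRIORITY, Category, ConfigurationError,
                    EntityMention, NormRecord, Sentence, Source, UNASSIGNED)
from .preprocess import lemma_of

log = logging.getLogger(__name__)

_TSV_COLUMNS = ["surface", "preferred_term", "code", "category", "source",
                "domain_code"]


@dataclass(frozen=True)
class TerminologyEntry:
    surface: str  # lower-cased match key
    preferred_term: str
    code: str
    category: Category
    source: Source
    domain_code: str = UNASSIGNED

    @property
    def priority(self) -> int:
        return SOURCE_PRIORITY[self.source]


def _norm_key(surface: str) -> str:
    return " ".join(surface.lower().split())


def _lemma_key(surface: str) -> str:
    return " ".join(lemma_of(w) for w in surface.lower().split())


class TerminologyStore:
    """Surface -> preferred-term index over all loaded lexicons.

    Lookup is by exact lower-cased surface first, then by lemma sequence;
    among several matching sources the strongest (lowest priority value)
    wins.  Within a category the gazetteer consumes surfaces longest-first.
    """

    def __init__(self) -> None:
        self._by_category: dict[Category, dict[str, list[TerminologyEntry]]] = {
            c: {} for c in Category}
        self._by_lemma: dict[Category, dict[str, list[TerminologyEntry]]] = {
            c: {} for c in Category}
        self._by_preferred: dict[Category, dict[str, TerminologyEntry]] = {
            c: {} for c in Category}
        self.stoplist: set[str] = set()

    def add(self, entry: TerminologyEntry) -> None:
        surf = self._by_category[entry.category].setdefault(entry.surface, [])
        for existing in surf:
            if existing.source == entry.source:
                raise ConfigurationError(
                    f"duplicate entry {entry.surface!r}/{entry.category.value}"
                    f"/{entry.source.value}")
        surf.append(entry)
        lem = _lemma_key(entry.surface)
        self._by_lemma[entry.category].setdefault(lem, []).append(entry)
        pref = self._by_preferred[entry.category]
        if (entry.preferred_term not in pref
                or entry.priority < pref[entry.preferred_term].priority):
            pref[entry.preferred_term] = entry

    def __len__(self) -> int:
        return sum(len(v) for d in self._by_category.values() for v in d.values())

    def lookup(self, category: Category, surface: str) -> Optional[TerminologyEntry]:
        """Best entry for a surface: exact match first, then lemma match."""
        key = _norm_key(surface)
        hits = self._by_category[category].get(key)
        if not hits:
            hits = self._by_lemma[category].get(_lemma_key(surface))
        if not hits:
            return None
        return min(hits, key=lambda e: e.priority)

    def entry_for_term(self, category: Category,
                       preferred_term: str) -> Optional[TerminologyEntry]:
        return self._by_preferred[category].get(preferred_term)

    def surfaces(self, category: Category) -> list[str]:
        return list(self._by_category[category])

    def lemma_surfaces(self, category: Category) -> list[str]:
        return list(self._by_lemma[category])

    def entries(self, category: Category | None = None) -> Iterable[TerminologyEntry]:
        cats = [category] if category else list(Category)
        for c in cats:
            for hits in self._by_category[c].values():
                yield from hits

    def self_check(self) -> list[str]:
        """Every preferred term must map back to at least one surface."""
        problems = []
        for c in Category:
            reachable = {e.preferred_term for hits in
                         self._by_category[c].values() for e in hits}
            for term in self._by_preferred[c]:
                if term not in reachable:
                    problems.append(f"{c.value}: {term}")
        return problems


def load_terminology(paths: list[str | Path],
                     stoplist_path: str | Path | None = None) -> TerminologyStore:
    """Build a store from TSV lexicon files.

    Each file needs the header ``surface preferred_term code category
    source domain_code``; unknown category or source values raise a load
    error naming the file and line.
    """
    if not paths:
        raise ConfigurationError("at least one terminology file is required")
    store = TerminologyStore()
    for path in paths:
        path = Path(path)
        with path.open(encoding="utf-8") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            missing = set(_TSV_COLUMNS) - set(reader.fieldnames or [])
            if missing:
                raise ConfigurationError(
                    f"{path}: missing columns {sorted(missing)}")
            for lineno, row in enumerate(reader, start=2):
                try:
                    category = Category(row["category"])
                except ValueError:
                    raise ConfigurationError(
                        f"{path}:{lineno}: unknown category {row['category']!r}")
                try:
                    source = Source(row["source"])
                except ValueError:
                    raise ConfigurationError(
                        f"{path}:{lineno}: unknown source {row['source']!r}")
                store.add(TerminologyEntry(
                    surface=_norm_key(row["surface"]),
                    preferred_term=row["preferred_term"],
                    code=row["code"],
                    category=category,
                    source=source,
                    domain_code=row["domain_code"] or UNASSIGNED))
    if stoplist_path is not None:
        store.stoplist = load_stoplist(stoplist_path)
    return store


def load_stoplist(path: str | Path) -> set[str]:
    out = set()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line.lower())
    return out


_DATA = resources.files("toxfindings.data")
_DEFAULT_FILES = ["terminology_send_mini.tsv",
                  "terminology_extensions_synthetic.tsv",
                  "terminology_internal.tsv"]


def load_default_store() -> TerminologyStore:
    """Load the packaged mini-lexicons and stoplist."""
    with resources.as_file(_DATA / _DEFAULT_FILES[0]) as first:
        data_dir = first.parent
        return load_terminology([data_dir / f for f in _DEFAULT_FILES],
                                stoplist_path=data_dir / "stoplist.txt")


_DICTIONARY_CATEGORIES = {Category.STUDY_TEST, Category.FINDING,
                          Category.SPECIMEN, Category.MANIFESTATION,
                          Category.SEX}


def normalise_mention(m: EntityMention, store: TerminologyStore) -> EntityMention:
    """Attach a NormRecord to a dictionary-backed mention.

    Never changes the span; with no match the mention is kept without a
    norm (recall-first: the expert decides downstream).
    """
    if m.category not in _DICTIONARY_CATEGORIES:
        return m
    entry = store.lookup(m.category, m.text)
    if entry is None:
        return replace(m, norm=None) if m.norm else m
    return replace(m, norm=NormRecord(preferred_term=entry.preferred_term,
                                      code=entry.code, source=entry.source,
                                      domain_code=entry.domain_code))


#: number then unit; unit grammar: (µg|ug|mg|g)/kg with optional /day, bare
#: mg, or ppm.  Extensible via the ``units`` argument of parse_dose.
_DOSE_RE = re.compile(
    r"(?P<value>\d+(?:\.\d+)?)\s*"
    r"(?P<unit>(?:[µu]g|mg|g)\s*/\s*kg(?:\s*/\s*day)?|mg|ppm)",
    re.IGNORECASE)


def parse_dose_text(text: str) -> tuple[Optional[float], Optional[str]]:
    m = _DOSE_RE.search(text)
    if not m:
        return None, None
    unit = re.sub(r"\s*/\s*", "/", m.group("unit").lower()).replace("ug", "µg")
    return float(m.group("value")), unit


def parse_dose(m: EntityMention) -> EntityMention:
    """Lexical-rule mapping for dose mentions: numeric magnitude + unit.

    Strings such as "12 mg/kg/day dose group" parse the leading magnitude.
    Unparseable doses keep no norm and log a warning.
    """
    value, unit = parse_dose_text(m.text)
    if value is None:
        log.warning("unparseable dose expression: %r", m.text)
        return replace(m, norm=None)
    return replace(m, norm=NormRecord(preferred_term=f"{value:g} {unit}",
                                      source=Source.LEXICAL_RULE,
                                      domain_code=UNASSIGNED,
                                      value=value, unit=unit))


_CATEGORY_PRIORITY = [Category.DOSE, Category.GROUP, Category.STUDY_TEST,
                      Category.FINDING, Category.SPECIMEN,
                      Category.MANIFESTATION, Category.SEX]
_CAT_RANK = {c: i for i, c in enumerate(_CATEGORY_PRIORITY)}

_GAP_OK = re.compile(r"^[\s\-]+$")


def postprocess(mentions: list[EntityMention], sentence: Sentence,
                store: TerminologyStore) -> list[EntityMention]:
    """False-positive removal, merging and overlap priority for one sentence.

    Stoplisted surfaces are dropped; adjacent same-category mentions
    separated only by whitespace or hyphen are merged (and renormalised);
    remaining overlaps resolve longest-match-first, then by category
    priority DOSE > GROUP > STUDY_TEST > FINDING > SPECIMEN >
    MANIFESTATION > SEX.  Output sorted by start offset.
    """
    kept = [m for m in mentions if _norm_key(m.text) not in store.stoplist]
    kept.sort(key=lambda m: (m.start, m.end))

    merged: list[EntityMention] = []
    for m in kept:
        if merged:
            prev = merged[-1]
            gap = sentence.text[prev.end - sentence.start:
                                m.start - sentence.start]
            if (prev.category == m.category and prev.end <= m.start
                    and (gap == "" or _GAP_OK.match(gap))):
                combined = EntityMention(
                    category=m.category, start=prev.start, end=m.end,
                    text=sentence.text[prev.start - sentence.start:
                                       m.end - sentence.start])
                merged[-1] = normalise_mention(combined, store)
                continue
        merged.append(m)

    # Longest-match-first overlap resolution with category priority ties.
    order = sorted(merged, key=lambda m: (-(m.end - m.start),
                                          _CAT_RANK[m.category], m.start))
    chosen: list[EntityMention] = []
    for m in order:
        if all(m.end <= c.start or m.start >= c.end for c in chosen):
            chosen.append(m)
    chosen.sort(key=lambda m: m.start)
    return chosen


def normalise_all(mentions: list[EntityMention],
                  store: TerminologyStore) -> list[EntityMention]:
    """Normalise every mention: dictionaries for term categories, lexical
    rules for dose, dose sub-parse for group expressions that embed one."""
    out = []
    for m in mentions:
        if m.category == Category.DOSE:
            out.append(parse_dose(m))
        elif m.category == Category.GROUP:
            value, unit = parse_dose_text(m.text)
            if value is not None:
                out.append(replace(m, norm=NormRecord(
                    preferred_term=m.text, source=Source.LEXICAL_RULE,
                    domain_code=UNASSIGNED, value=value, unit=unit)))
            else:
                out.append(replace(m, norm=NormRecord(
                    preferred_term=m.text, source=Source.LEXICAL_RULE,
                    domain_code=UNASSIGNED)))
        else:
            out.append(normalise_mention(m, store))
    return out
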