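"""Assembly of entity mentions into abnormal observations.

Every study-test and every finding mention anchors one observation; the
remaining entities attach by deterministic positional rules chosen to
handle the characteristic structures of toxicology prose:

1. a MANIFESTATION applies forward to every following anchor until the
   next manifestation or the sentence end — this is what shares one
   "decrease" across a coordinated list of study tests;
2. SEX, DOSE and GROUP apply backward: a mention binds every anchor since
   the previous mention of the same category (or the sentence start), so
   "... in males and females at the 30 mg/kg dose, and X in males at the
   10 mg/kg dose" distributes correctly across both clauses;
3. a SPECIMEN binds the nearest anchor by token distance (ties go to the
   preceding anchor);
4. sex/dose/group still missing afterwards are inherited from the nearest
   same-category mention of the immediately preceding sentence — lookback
   is exactly one sentence deep, never further;
5. a study-test anchor that ends up without a manifestation yields no
   observation (a warning is logged): a study test alone describes no
   abnormality.

Treatment-relatedness is detected from trigger phrases ("treatment-
related", "compound-related effect", "attributable to treatment", ...),
negated when a cue such as "not"/"no"/"without" appears within the three
preceding tokens.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

from .model import (Category, ConfigurationError, EntityMention, Observation,
                    Sentence, Source, UNASSIGNED)
from .normalise import TerminologyStore

log = logging.getLogger(__name__)


@dataclass
class SentenceContext:
    current: Sentence
    mentions: list[EntityMention]
    previous: Optional[Sentence] = None
    previous_mentions: list[EntityMention] = field(default_factory=list)


def _term(m: EntityMention) -> str:
    return m.norm.preferred_term if m.norm else m.text


def _noncontrolled(m: EntityMention) -> bool:
    return (m.norm is not None and not m.norm.is_controlled
            and m.category in (Category.STUDY_TEST, Category.FINDING,
                               Category.SPECIMEN))


def _token_index(sentence: Sentence, offset: int) -> int:
    for i, t in enumerate(sentence.tokens):
        if t.end > offset:
            return i
    return len(sentence.tokens)


@dataclass
class _Slot:
    sex: Optional[EntityMention] = None
    dose: Optional[EntityMention] = None
    group: Optional[EntityMention] = None
    specimen: Optional[EntityMention] = None
    manifestation: Optional[EntityMention] = None


def build_observations(ctx: SentenceContext, section: str = "",
                       section_index: int = 1,
                       start_number: int = 1) -> list[Observation]:
    """Deterministic left-to-right observation assembly for one sentence.

    Mentions are consumed in offset order regardless of input order.
    Observation ids follow the "section_index.running_number" convention.
    """
    mentions = sorted(ctx.mentions, key=lambda m: (m.start, m.end))
    anchors = [m for m in mentions
               if m.category in (Category.STUDY_TEST, Category.FINDING)]
    if not anchors:
        return []
    slots = {id(a): _Slot() for a in anchors}

    # (1)+(2) manifestation: forward sharing, else nearest following.
    current_manif: Optional[EntityMention] = None
    for m in mentions:
        if m.category == Category.MANIFESTATION:
            current_manif = m
        elif m.category in (Category.STUDY_TEST, Category.FINDING):
            if current_manif is not None:
                slots[id(m)].manifestation = current_manif
    for a in anchors:
        if slots[id(a)].manifestation is None:
            following = [m for m in mentions
                         if m.category == Category.MANIFESTATION
                         and m.start >= a.end]
            if following:
                slots[id(a)].manifestation = following[0]

    # (3) sex/dose/group backward binding between same-category mentions.
    for cat, attr in ((Category.SEX, "sex"), (Category.DOSE, "dose"),
                      (Category.GROUP, "group")):
        window_start = -1
        for m in mentions:
            if m.category != cat:
                continue
            for a in anchors:
                if window_start < a.start < m.start:
                    setattr(slots[id(a)], attr, m)
            window_start = m.start

    # (4) specimen: nearest anchor by token distance, tie -> preceding.
    for m in mentions:
        if m.category != Category.SPECIMEN:
            continue
        s_tok = _token_index(ctx.current, m.start)
        best = None
        best_key = None
        for a in anchors:
            a_tok = _token_index(ctx.current, a.start)
            dist = abs(a_tok - s_tok)
            precedes = 0 if a.start < m.start else 1
            key = (dist, precedes, a.start)
            if best_key is None or key < best_key:
                best, best_key = a, key
        if best is not None:
            slots[id(best)].specimen = m

    # (5) one-sentence lookback for still-absent sex/dose/group.
    lookback: dict[str, Optional[EntityMention]] = {}
    for cat, attr in ((Category.SEX, "sex"), (Category.DOSE, "dose"),
                      (Category.GROUP, "group")):
        prev = [m for m in ctx.previous_mentions if m.category == cat]
        lookback[attr] = prev[-1] if prev else None  # nearest = last

    observations: list[Observation] = []
    number = start_number
    for a in anchors:
        slot = slots[id(a)]
        if a.category == Category.STUDY_TEST and slot.manifestation is None:
            log.warning("study-test anchor %r has no manifestation; "
                        "no observation emitted", a.text)
            continue
        evidence = [a]
        sentence_ids = [ctx.current.id]
        obs = Observation(
            obs_id=f"{section_index}.{number}",
            section=section,
            evidence_text=ctx.current.text,
        )
        if a.category == Category.STUDY_TEST:
            obs.study_test = _term(a)
        else:
            obs.finding = _term(a)
        if _noncontrolled(a):
            obs.noncontrolled_flags.append(
                "study_test" if a.category == Category.STUDY_TEST else "finding")
        if slot.manifestation is not None:
            obs.manifestation = _term(slot.manifestation)
            evidence.append(slot.manifestation)
        if slot.specimen is not None:
            obs.specimen = _term(slot.specimen)
            evidence.append(slot.specimen)
            if _noncontrolled(slot.specimen):
                obs.noncontrolled_flags.append("specimen")
        for attr in ("sex", "dose", "group"):
            m = getattr(slot, attr)
            inherited = False
            if m is None and lookback[attr] is not None:
                m = lookback[attr]
                inherited = True
            if m is None:
                continue
            if attr == "sex":
                obs.sex = _term(m)
            elif attr == "group":
                obs.group = _term(m)
            else:
                if m.norm is not None and m.norm.value is not None:
                    obs.dose_value = m.norm.value
                    obs.dose_unit = m.norm.unit
            # group expressions that embed a dose also contribute it
            if attr == "group" and m.norm is not None \
                    and m.norm.value is not None and obs.dose_value is None:
                obs.dose_value = m.norm.value
                obs.dose_unit = m.norm.unit
            evidence.append(m)
            if inherited and ctx.previous is not None \
                    and ctx.previous.id not in sentence_ids:
                sentence_ids.append(ctx.previous.id)
        obs.sentence_ids = sorted(sentence_ids)
        obs.evidence_mentions = evidence
        observations.append(obs)
        number += 1
    return observations


NEGATION_CUES = {"not", "no", "without", "unrelated", "un-related"}


def load_triggers(path: str | Path | None = None) -> list[str]:
    """Trigger lexicon: one phrase per line, '#' comments."""
    if path is None:
        ref = resources.files("toxfindings.data") / "triggers.txt"
        text = ref.read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    triggers = [line.strip() for line in text.splitlines()
                if line.strip() and not line.lstrip().startswith("#")]
    return triggers


def detect_treatment_related(sentence: Sentence,
                             triggers: list[str]) -> bool:
    """True iff a trigger phrase occurs and is not negated.

    Matching is case-insensitive; a match is suppressed when a negation
    cue (not/no/without/unrelated) occurs within the three tokens before
    the trigger.
    """
    if not triggers:
        raise ConfigurationError("trigger list must not be empty")
    text_low = sentence.text.lower()
    tokens = sentence.tokens
    for trig in triggers:
        start = 0
        t_low = trig.lower()
        while True:
            pos = text_low.find(t_low, start)
            if pos == -1:
                break
            start = pos + 1
            before = pos - 1
            if before >= 0 and (text_low[before].isalnum()
                                or text_low[before] == "-"):
                continue  # mid-word match
            trig_tok = _token_index(sentence, sentence.start + pos)
            window = tokens[max(0, trig_tok - 3):trig_tok]
            if any(t.text.lower() in NEGATION_CUES for t in window):
                continue
            return True
    return False


def assign_domain(obs: Observation, store: TerminologyStore) -> Observation:
    """Copy the study domain code (LB, BW, CL, MI, ...) from the anchor's
    terminology entry; UNASSIGNED when the anchor is unnormalised."""
    if obs.study_test is not None:
        entry = store.entry_for_term(Category.STUDY_TEST, obs.study_test)
    elif obs.finding is not None:
        entry = store.entry_for_term(Category.FINDING, obs.finding)
    else:
        entry = None
    obs.domain_code = entry.domain_code if entry else UNASSIGNED
    return obs
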