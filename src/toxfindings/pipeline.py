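"""End-to-end extraction pipeline.

Stage order: section extraction -> preprocessing -> sentence relevance ->
entity recognition -> normalisation -> relation extraction (with
one-sentence lookback and treatment-relatedness triggers) -> SR-domain
mapping.  Entity recognition runs only on sentences classified relevant.
With a fixed configuration the run is bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from .model import Observation, Relevance, Sentence
from .ner import tag_baseline
from .normalise import (TerminologyStore, load_default_store, normalise_all,
                        postprocess)
from .preprocess import (DEFAULT_SECTION_TITLES, SectionText,
                         extract_sections, preprocess_text)
from .relate import (SentenceContext, assign_domain, build_observations,
                     detect_treatment_related, load_triggers)
from .relevance import RelevanceModel, classify, lexicon_model
from .sr_export import SRDomainRecord, SRTemplate, map_to_sr

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    observations: list[Observation]
    records: list[SRDomainRecord]
    sections: list[SectionText]
    sentences: list[Sentence] = field(default_factory=list)


def run_pipeline(document_text: str,
                 store: Optional[TerminologyStore] = None,
                 triggers: Optional[list[str]] = None,
                 relevance_model: Optional[RelevanceModel] = None,
                 section_titles: Optional[list[str]] = None,
                 whole_document: bool = False,
                 template: Optional[SRTemplate] = None) -> PipelineResult:
    """Run the full extraction chain over one report's text.

    When no section title matches (or ``whole_document`` is set) the whole
    text is processed as a single section.
    """
    store = store if store is not None else load_default_store()
    triggers = triggers if triggers is not None else load_triggers()
    model = relevance_model if relevance_model is not None \
        else lexicon_model(store)
    template = template or SRTemplate.default()

    if whole_document or not document_text:
        sections = [SectionText(name="DOCUMENT", text=document_text,
                                start=0, end=len(document_text))]
    else:
        sections = extract_sections(document_text,
                                    section_titles or DEFAULT_SECTION_TITLES)
        if not sections:
            log.warning("falling back to whole-document processing")
            sections = [SectionText(name="DOCUMENT", text=document_text,
                                    start=0, end=len(document_text))]

    observations: list[Observation] = []
    all_sentences: list[Sentence] = []
    for s_idx, sec in enumerate(sections, start=1):
        sentences = preprocess_text(sec.text, offset=sec.start, start_id=0)
        all_sentences.extend(sentences)
        mentions_per: list[list] = []
        for sent in sentences:
            label, _ = classify(model, sent)
            if label == Relevance.RELEVANT:
                mentions = tag_baseline(sent, store)
                mentions = postprocess(mentions, sent, store)
                mentions = normalise_all(mentions, store)
            else:
                mentions = []
            mentions_per.append(mentions)

        number = 1
        prev_sent: Optional[Sentence] = None
        prev_mentions: list = []
        per_sentence_obs: list[list[Observation]] = []
        for sent, mentions in zip(sentences, mentions_per):
            ctx = SentenceContext(current=sent, mentions=mentions,
                                  previous=prev_sent,
                                  previous_mentions=prev_mentions)
            obs = build_observations(ctx, section=sec.name,
                                     section_index=s_idx,
                                     start_number=number)
            number += len(obs)
            if detect_treatment_related(sent, triggers):
                if obs:
                    for o in obs:
                        o.treatment_related = True
                elif per_sentence_obs and per_sentence_obs[-1]:
                    # anchorless trigger sentence: flag the previous
                    # sentence's observations
                    for o in per_sentence_obs[-1]:
                        o.treatment_related = True
            per_sentence_obs.append(obs)
            prev_sent, prev_mentions = sent, mentions
        for obs_list in per_sentence_obs:
            for o in obs_list:
                assign_domain(o, store)
                observations.append(o)

    records = [map_to_sr(o, template) for o in observations]
    return PipelineResult(observations=observations, records=records,
                          sections=sections, sentences=all_sentences)
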