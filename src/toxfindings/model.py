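"""Shared data model for treatment-related finding extraction.

A treatment-related observation in a toxicology study report is anchored
either by a *study test* (a measured endpoint such as body weight or
platelet count) together with an abnormal *manifestation* (increase,
decrease, alteration), or by an adverse *finding* (necrosis, ataxia, ...)
in domains where no study test is defined.  The observation is further
characterised by the specimen, the sex and group of the affected animals,
and the administered dose.

All character offsets are 0-based, half-open, and document-global: for any
span, ``document_text[start:end]`` must equal the span text.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Optional


class Category(str, enum.Enum):
    """The seven entity categories of the extraction model."""

    STUDY_TEST = "STUDY_TEST"
    MANIFESTATION = "MANIFESTATION"
    FINDING = "FINDING"
    SPECIMEN = "SPECIMEN"
    DOSE = "DOSE"
    SEX = "SEX"
    GROUP = "GROUP"


class Source(str, enum.Enum):
    """Provenance of a normalisation entry; order encodes priority."""

    SEND_CORE = "SEND_CORE"
    SEND_EXTENSION = "SEND_EXTENSION"
    ETOX = "ETOX"
    UMLS_LIKE = "UMLS_LIKE"
    INTERNAL = "INTERNAL"
    LEXICAL_RULE = "LEXICAL_RULE"


#: Lower value = stronger source when several lexicons match one surface.
SOURCE_PRIORITY = {
    Source.SEND_CORE: 0,
    Source.SEND_EXTENSION: 1,
    Source.ETOX: 2,
    Source.UMLS_LIKE: 3,
    Source.INTERNAL: 4,
    Source.LEXICAL_RULE: 5,
}

UNASSIGNED = "UNASSIGNED"


class Relevance(str, enum.Enum):
    RELEVANT = "RELEVANT"
    NON_RELEVANT = "NON_RELEVANT"
    UNSET = "UNSET"


@dataclass
class Token:
    text: str
    start: int
    end: int
    pos: str = ""
    lemma: str = ""
    shape: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Sentence:
    id: int
    text: str
    start: int
    end: int
    tokens: list[Token] = field(default_factory=list)
    relevance: Relevance = Relevance.UNSET
    relevance_score: Optional[float] = None


@dataclass
class NormRecord:
    preferred_term: str
    code: str = ""
    source: Source = Source.INTERNAL
    domain_code: str = UNASSIGNED
    value: Optional[float] = None
    unit: Optional[str] = None

    @property
    def is_controlled(self) -> bool:
        return self.source == Source.SEND_CORE


@dataclass
class EntityMention:
    category: Category
    start: int
    end: int
    text: str
    norm: Optional[NormRecord] = None


@dataclass
class Observation:
    """One abnormal observation assembled from entity mentions.

    Exactly one of ``study_test`` / ``finding`` anchors the observation,
    and a study-test anchor always carries a manifestation.  Fields
    inherited by one-sentence lookback cite the previous sentence in
    ``sentence_ids``.
    """

    obs_id: str = ""
    section: str = ""
    domain_code: str = UNASSIGNED
    study_test: Optional[str] = None
    manifestation: Optional[str] = None
    finding: Optional[str] = None
    specimen: Optional[str] = None
    sex: Optional[str] = None
    group: Optional[str] = None
    dose_value: Optional[float] = None
    dose_unit: Optional[str] = None
    treatment_related: bool = False
    sentence_ids: list[int] = field(default_factory=list)
    evidence_text: str = ""
    noncontrolled_flags: list[str] = field(default_factory=list)
    validated: bool = False
    # Contributing mentions; excluded from equality so that CSV round trips
    # (which cannot carry mention objects) compare field-by-field.
    evidence_mentions: list[EntityMention] = field(default_factory=list, compare=False)


VALID_SEX = {"Male", "Female", "Both"}


def validate_observation(obs: Observation) -> list[str]:
    """Check the observation invariants; violations are data, not exceptions.

    Returns an empty list iff the observation is well-formed; otherwise each
    entry names the field and the rule broken.
    """
    violations: list[str] = []
    has_test = obs.study_test is not None
    has_finding = obs.finding is not None
    if has_test == has_finding:
        violations.append(
            "anchor rule: exactly one of study_test or finding must be set"
        )
    if has_test and obs.manifestation is None:
        violations.append("manifestation required: study-test anchors need one")
    if obs.sex is not None and obs.sex not in VALID_SEX:
        violations.append(f"sex: {obs.sex!r} not in {sorted(VALID_SEX)}")
    if (obs.dose_value is None) != (obs.dose_unit is None):
        violations.append("dose: value and unit must be present together")
    if not obs.sentence_ids:
        violations.append("evidence: at least one sentence id required")
    return violations


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters for the optional transformer fine-tuning backends.

    The two named constructors carry the optimised settings found for each
    task during model development (50 search trials for the sentence
    classifier, 100 for NER).
    """

    epochs: int = 3
    learning_rate: float = 1.1848183151867784e-05
    seed: int = 1
    weight_decay: float = 0.01
    early_stopping: bool = True
    trials: int = 50

    @classmethod
    def classifier_defaults(cls) -> "TrainConfig":
        return cls(epochs=3, learning_rate=1.1848183151867784e-05, seed=1,
                   weight_decay=0.01, early_stopping=True, trials=50)

    @classmethod
    def ner_defaults(cls) -> "TrainConfig":
        return cls(epochs=7, learning_rate=5.760003080365119e-05, seed=4,
                   weight_decay=0.01, early_stopping=True, trials=100)

    def validated(self) -> "TrainConfig":
        if self.epochs <= 0:
            raise ValueError("epochs must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be non-negative")
        return self


class ConfigurationError(ValueError):
    """Raised for invalid pipeline or resource configuration."""


class MissingDependencyError(ImportError):
    """Raised when an optional backend's dependencies are not installed."""


__all__ = [
    "Category", "Source", "SOURCE_PRIORITY", "UNASSIGNED", "Relevance",
    "Token", "Sentence", "NormRecord", "EntityMention", "Observation",
    "validate_observation", "TrainConfig", "ConfigurationError",
    "MissingDependencyError", "replace",
]
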