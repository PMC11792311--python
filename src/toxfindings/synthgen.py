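"""Seeded generator of toxicology-style report text with gold annotations.

Every structure the extraction pipeline must handle is emulated with
complete construction-time gold: relevance labels, entity spans, and fully
normalised observations.  Relevant sentences instantiate the two anchor
patterns (study test + manifestation; finding [+ specimen]), optionally
with coordinated study-test lists sharing one manifestation/sex/dose,
sex/dose/group stated only in the preceding sentence, treatment-related
trigger phrases (half of them negated), and non-controlled vocabulary.
Non-relevant sentences are study boilerplate (dates, husbandry, methods).

Template phrasing and vocabulary are drawn from the packaged mini-lexicons
so that, at noise_rate=0, a fully covered baseline pipeline can recover
the gold exactly; the noise perturbation is a length-preserving typo in a
non-entity word.  Identical configurations produce byte-identical corpora.
"""

from __future__ import annotations

import copy
import json
import random
from dataclasses import dataclass, field, asdict

from .model import Category, EntityMention, Observation, Relevance

# (surface, preferred term, domain code)
STUDY_TESTS = [
    ("body weight gain", "Weight Gain", "BW"),
    ("food consumption", "Food Consumption", "FW"),
    ("water consumption", "Water Consumption", "FW"),
    ("hemoglobin", "Hemoglobin", "LB"),
    ("hematocrit", "Hematocrit", "LB"),
    ("albumin", "Albumin", "LB"),
    ("glucose", "Glucose", "LB"),
    ("cholesterol", "Cholesterol", "LB"),
    ("alkaline phosphatase", "Alkaline Phosphatase", "LB"),
    ("creatinine", "Creatinine", "LB"),
    ("prothrombin time", "Prothrombin Time", "LB"),
    ("reticulocyte count", "Reticulocyte Count", "LB"),
    ("platelet count", "Platelet Count", "LB"),
    ("leukocyte count", "Leukocyte Count", "LB"),
    ("lymphocyte count", "Lymphocyte Count", "LB"),
    ("total protein", "Protein", "LB"),
    ("urine volume", "Urine Volume", "UR"),
]

MANIFESTATIONS = [
    ("decrease", "Decrease"),
    ("increase", "Increase"),
    ("reduction", "Decrease"),
    ("elevation", "Increase"),
]

FINDINGS = [
    ("necrosis", "Necrosis", "MI"),
    ("hypertrophy", "Hypertrophy", "MI"),
    ("atrophy", "Atrophy", "MI"),
    ("degeneration", "Degeneration", "MI"),
    ("inflammation", "Inflammation", "MI"),
    ("fibrosis", "Fibrosis", "MI"),
    ("mineralization", "Mineralization", "MI"),
    ("hyperplasia", "Hyperplasia", "MI"),
    ("vomitus", "Vomitus", "CL"),
    ("ataxia", "Ataxia", "CL"),
    ("salivation", "Salivation", "CL"),
    ("tremors", "Tremor", "CL"),
    ("lethargy", "Lethargy", "CL"),
    ("piloerection", "Piloerection", "CL"),
    ("diarrhoea", "Diarrhea", "CL"),
    ("hypoactivity", "Hypoactivity", "CL"),
]

#: vocabulary resolved only through non-SEND (eTOX/UMLS-style) lexicons
NONCONTROLLED_FINDINGS = [
    ("histopathologic lesions", "lesions", "MI"),
    ("erosions", "Erosion", "MI"),
    ("ulceration", "Ulceration", "MI"),
    ("oedema", "Edema", "MI"),
    ("hunched posture", "hunched posture", "CL"),
]

SPECIMENS = [
    ("liver", "Liver"),
    ("kidneys", "Kidney"),
    ("spleen", "Spleen"),
    ("thymus", "Thymus"),
    ("lungs", "Lung"),
    ("stomach", "Stomach"),
    ("adrenal glands", "Adrenal Gland"),
    ("bone marrow", "Bone Marrow"),
    ("heart", "Heart"),
]

SEXES = [
    ("males", "Male"),
    ("females", "Female"),
    ("males and females", "Both"),
    ("both sexes", "Both"),
]

DOSE_VALUES = [5, 10, 15, 20, 25, 30, 50, 100, 150, 200]
DOSE_UNITS = ["mg/kg", "mg/kg/day"]

GROUPS = ["group 1", "group 2", "group 3", "group A", "group B",
          "high dose group", "low dose group"]

TRIGGER_SUFFIXES = [", and was considered treatment-related",
                    ", and was attributable to treatment"]
NEGATED_TRIGGER_SUFFIXES = [", but was not treatment-related",
                            ", and was considered not related to treatment"]

BOILERPLATE = [
    "The study was conducted in {year}.",
    "All animals were dosed by oral gavage for four weeks.",
    "Samples were collected prior to necropsy.",
    "The test article was administered once daily.",
    "Clinical pathology parameters were evaluated during week {week}.",
    "Animals were housed under standard laboratory conditions.",
    "The protocol was approved by the institutional committee.",
    "Ophthalmoscopy was performed before the start of dosing.",
    "The in-life phase was completed as planned.",
    "Stability of the formulation was confirmed analytically.",
    "Terminal procedures were performed according to the protocol.",
    "The study director reviewed all raw records.",
]


@dataclass
class GenConfig:
    n_sentences: int = 200
    relevant_fraction: float = 0.43  # mirrors the gold corpus class balance
    coordination_rate: float = 0.2
    lookback_rate: float = 0.15
    trigger_rate: float = 0.2
    noncontrolled_rate: float = 0.1
    noise_rate: float = 0.0
    seed: int = 0

    def validate(self) -> "GenConfig":
        for name in ("relevant_fraction", "coordination_rate",
                     "lookback_rate", "trigger_rate", "noncontrolled_rate",
                     "noise_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_sentences < 0:
            raise ValueError("n_sentences must be non-negative")
        return self


@dataclass
class GoldSentence:
    text: str
    relevance: Relevance
    entities: list[EntityMention] = field(default_factory=list)
    observations: list[Observation] = field(default_factory=list)
    kind: str = "simple"


@dataclass
class GoldCorpus:
    config: GenConfig
    sentences: list[GoldSentence]

    def labelled(self) -> list[tuple[str, Relevance]]:
        return [(s.text, s.relevance) for s in self.sentences]

    def standoff(self) -> list[tuple[str, list[EntityMention]]]:
        return [(s.text, s.entities) for s in self.sentences]

    def to_jsonl(self) -> str:
        lines = []
        for s in self.sentences:
            lines.append(json.dumps({
                "text": s.text,
                "relevance": s.relevance.value,
                "kind": s.kind,
                "entities": [{"start": m.start, "end": m.end,
                              "category": m.category.value}
                             for m in s.entities],
            }, ensure_ascii=False))
        return "\n".join(lines) + "\n"


class _Builder:
    """Assemble one sentence while recording entity offsets exactly."""

    def __init__(self) -> None:
        self.parts: list[str] = []
        self.entities: list[EntityMention] = []
        self.pos = 0

    def lit(self, s: str) -> "_Builder":
        self.parts.append(s)
        self.pos += len(s)
        return self

    def ent(self, s: str, category: Category) -> "_Builder":
        self.entities.append(EntityMention(category=category, start=self.pos,
                                           end=self.pos + len(s), text=s))
        return self.lit(s)

    def text(self) -> str:
        return "".join(self.parts)


def _obs(**kwargs) -> Observation:
    kwargs.setdefault("sentence_ids", [0])
    return Observation(**kwargs)


def _maybe_trigger(rng: random.Random, cfg: GenConfig, b: _Builder,
                   observations: list[Observation]) -> None:
    if rng.random() >= cfg.trigger_rate:
        b.lit(".")
        return
    if rng.random() < 0.5:
        b.lit(rng.choice(NEGATED_TRIGGER_SUFFIXES) + ".")
    else:
        b.lit(rng.choice(TRIGGER_SUFFIXES) + ".")
        for o in observations:
            o.treatment_related = True


def _apply_noise(rng: random.Random, cfg: GenConfig, b: _Builder) -> str:
    text = b.text()
    if cfg.noise_rate <= 0 or rng.random() >= cfg.noise_rate:
        return text
    # Length-preserving typo in a character not covered by any entity.
    covered = set()
    for m in b.entities:
        covered.update(range(m.start, m.end))
    positions = [i for i in range(len(text) - 1)
                 if i not in covered and i + 1 not in covered
                 and text[i].isalpha() and text[i + 1].isalpha()
                 and text[i] != text[i + 1]]
    if not positions:
        return text
    i = rng.choice(positions)
    return text[:i] + text[i + 1] + text[i] + text[i + 2:]


def _dose(rng: random.Random) -> tuple[str, float, str]:
    value = rng.choice(DOSE_VALUES)
    unit = rng.choice(DOSE_UNITS)
    return f"{value} {unit}", float(value), unit


def _simple_test_sentence(rng: random.Random, cfg: GenConfig) -> GoldSentence:
    surface, preferred, domain = rng.choice(STUDY_TESTS)
    manif_s, manif_p = rng.choice(MANIFESTATIONS)
    dose_s, dose_v, dose_u = _dose(rng)
    b = _Builder()
    b.lit("A ").ent(manif_s, Category.MANIFESTATION)
    b.lit(" in ").ent(surface, Category.STUDY_TEST)
    if rng.random() < 0.25:
        group = rng.choice(GROUPS)
        b.lit(" was noted in ").ent(group, Category.GROUP)
        obs = _obs(domain_code=domain, study_test=preferred,
                   manifestation=manif_p, group=group,
                   dose_value=dose_v, dose_unit=dose_u)
    else:
        sex_s, sex_p = rng.choice(SEXES)
        b.lit(" was observed in ").ent(sex_s, Category.SEX)
        obs = _obs(domain_code=domain, study_test=preferred,
                   manifestation=manif_p, sex=sex_p,
                   dose_value=dose_v, dose_unit=dose_u)
    b.lit(" at the ").ent(dose_s, Category.DOSE).lit(" dose")
    observations = [obs]
    _maybe_trigger(rng, cfg, b, observations)
    text = _apply_noise(rng, cfg, b)
    for o in observations:
        o.evidence_text = text
    return GoldSentence(text=text, relevance=Relevance.RELEVANT,
                        entities=b.entities, observations=observations)


def _finding_sentence(rng: random.Random, cfg: GenConfig) -> GoldSentence:
    noncontrolled = rng.random() < cfg.noncontrolled_rate
    pool = NONCONTROLLED_FINDINGS if noncontrolled else FINDINGS
    surface, preferred, domain = rng.choice(pool)
    sex_s, sex_p = rng.choice(SEXES)
    dose_s, dose_v, dose_u = _dose(rng)
    b = _Builder()
    shown = surface[0].upper() + surface[1:]
    b.ent(shown, Category.FINDING)
    verb = " were" if surface.endswith("s") else " was"
    obs = _obs(domain_code=domain, finding=preferred, sex=sex_p,
               dose_value=dose_v, dose_unit=dose_u,
               noncontrolled_flags=["finding"] if noncontrolled else [])
    if rng.random() < 0.6:
        spec_s, spec_p = rng.choice(SPECIMENS)
        b.lit(verb + " observed in the ").ent(spec_s, Category.SPECIMEN)
        b.lit(" of ").ent(sex_s, Category.SEX)
        obs.specimen = spec_p
    else:
        b.lit(verb + " noted in ").ent(sex_s, Category.SEX)
    b.lit(" at the ").ent(dose_s, Category.DOSE).lit(" dose")
    observations = [obs]
    _maybe_trigger(rng, cfg, b, observations)
    text = _apply_noise(rng, cfg, b)
    for o in observations:
        o.evidence_text = text
    return GoldSentence(text=text, relevance=Relevance.RELEVANT,
                        entities=b.entities, observations=observations,
                        kind="finding")


def _coordination_sentence(rng: random.Random, cfg: GenConfig) -> GoldSentence:
    n_tests = rng.choice([2, 3])
    tests = rng.sample(STUDY_TESTS, n_tests)
    manif_s, manif_p = rng.choice(MANIFESTATIONS)
    sex_s, sex_p = rng.choice(SEXES)
    dose_s, dose_v, dose_u = _dose(rng)
    b = _Builder()
    b.lit("There was a ").ent(manif_s, Category.MANIFESTATION).lit(" in ")
    for i, (surface, _, _) in enumerate(tests):
        if i > 0:
            b.lit(" and " if i == n_tests - 1 else ", ")
        b.ent(surface, Category.STUDY_TEST)
    b.lit(" in ").ent(sex_s, Category.SEX)
    b.lit(" at the ").ent(dose_s, Category.DOSE).lit(" dose")
    observations = [
        _obs(domain_code=domain, study_test=preferred, manifestation=manif_p,
             sex=sex_p, dose_value=dose_v, dose_unit=dose_u)
        for (_, preferred, domain) in tests
    ]
    _maybe_trigger(rng, cfg, b, observations)
    text = _apply_noise(rng, cfg, b)
    for o in observations:
        o.evidence_text = text
    return GoldSentence(text=text, relevance=Relevance.RELEVANT,
                        entities=b.entities, observations=observations,
                        kind="coordination")


def _lookback_pair(rng: random.Random, cfg: GenConfig) -> list[GoldSentence]:
    head = _simple_test_sentence(rng, cfg)
    surface, preferred, domain = rng.choice(STUDY_TESTS)
    manif_s, manif_p = rng.choice(MANIFESTATIONS)
    b = _Builder()
    b.lit("A ").ent(manif_s, Category.MANIFESTATION)
    b.lit(" in ").ent(surface, Category.STUDY_TEST).lit(" was also noted")
    obs = _obs(domain_code=domain, study_test=preferred,
               manifestation=manif_p)
    observations = [obs]
    _maybe_trigger(rng, cfg, b, observations)
    text = _apply_noise(rng, cfg, b)
    obs.evidence_text = text
    tail = GoldSentence(text=text, relevance=Relevance.RELEVANT,
                        entities=b.entities, observations=observations,
                        kind="lookback_tail")
    head.kind = "lookback_head"
    return [head, tail]


def _boilerplate(rng: random.Random) -> GoldSentence:
    template = rng.choice(BOILERPLATE)
    text = template.format(year=rng.randint(1990, 2017),
                           week=rng.randint(1, 13))
    return GoldSentence(text=text, relevance=Relevance.NON_RELEVANT,
                        kind="boilerplate")


def _blocks(cfg: GenConfig, rng: random.Random) -> list[list[GoldSentence]]:
    n_rel = int(round(cfg.n_sentences * cfg.relevant_fraction))
    n_non = cfg.n_sentences - n_rel
    blocks: list[list[GoldSentence]] = []
    remaining = n_rel
    while remaining > 0:
        if remaining >= 2 and rng.random() < cfg.lookback_rate:
            block = _lookback_pair(rng, cfg)
        elif rng.random() < cfg.coordination_rate:
            block = [_coordination_sentence(rng, cfg)]
        elif rng.random() < 0.5:
            block = [_simple_test_sentence(rng, cfg)]
        else:
            block = [_finding_sentence(rng, cfg)]
        blocks.append(block)
        remaining -= len(block)
    blocks.extend([_boilerplate(rng)] for _ in range(n_non))
    rng.shuffle(blocks)
    return blocks


def generate_corpus(config: GenConfig | None = None) -> GoldCorpus:
    """Generate a flat gold corpus of independent sentences."""
    cfg = (config or GenConfig()).validate()
    rng = random.Random(cfg.seed)
    sentences = [s for block in _blocks(cfg, rng) for s in block]
    return GoldCorpus(config=cfg, sentences=sentences)


SECTION_HEADINGS = [("SUMMARY", "Summary"),
                    ("2. Results:", "Results"),
                    ("Discussion and conclusions", "Discussion")]


@dataclass
class GoldReport:
    text: str
    observations: list[Observation]
    corpus: GoldCorpus
    sections: list[str]


def _inherit(obs: Observation, previous: GoldSentence | None,
             prev_id: int) -> None:
    """One-sentence lookback on gold: fill absent sex/dose/group from the
    previous sentence's entities (mirrors the extraction contract)."""
    if previous is None or previous.relevance != Relevance.RELEVANT:
        return
    by_cat: dict[Category, EntityMention] = {}
    for m in previous.entities:  # last mention of each category wins
        by_cat[m.category] = m
    inherited = False
    if obs.sex is None and Category.SEX in by_cat:
        donors = [o.sex for o in previous.observations if o.sex is not None]
        if donors:
            obs.sex = donors[-1]
            inherited = True
    if obs.dose_value is None and Category.DOSE in by_cat:
        donors = [(o.dose_value, o.dose_unit) for o in previous.observations
                  if o.dose_value is not None]
        if donors:
            obs.dose_value, obs.dose_unit = donors[-1]
            inherited = True
    if obs.group is None and Category.GROUP in by_cat:
        donors = [o.group for o in previous.observations
                  if o.group is not None]
        if donors:
            obs.group = donors[-1]
            inherited = True
    if inherited and prev_id not in obs.sentence_ids:
        obs.sentence_ids.append(prev_id)


def generate_report(config: GenConfig | None = None) -> GoldReport:
    """Assemble a report with Summary / Results / Discussion-and-conclusions
    sections (heading variants exercise the soft matcher) plus the gold
    observations in the observations-CSV schema."""
    cfg = (config or GenConfig()).validate()
    rng = random.Random(cfg.seed)
    blocks = [copy.deepcopy(b) for b in _blocks(cfg, rng)]
    n_sections = len(SECTION_HEADINGS)
    per_section = max(1, (len(blocks) + n_sections - 1) // n_sections)
    chunks = [blocks[i * per_section:(i + 1) * per_section]
              for i in range(n_sections)]

    parts: list[str] = []
    observations: list[Observation] = []
    all_sentences: list[GoldSentence] = []
    section_names: list[str] = []
    for s_idx, ((heading, name), chunk) in enumerate(
            zip(SECTION_HEADINGS, chunks), start=1):
        parts.append(heading + "\n")
        section_names.append(name)
        sentence_id = 0
        number = 1
        previous: GoldSentence | None = None
        section_sentences: list[str] = []
        for block in chunk:
            for sent in block:
                section_sentences.append(sent.text)
                for obs in sent.observations:
                    obs.obs_id = f"{s_idx}.{number}"
                    obs.section = name
                    obs.sentence_ids = [sentence_id]
                    _inherit(obs, previous, sentence_id - 1)
                    obs.sentence_ids.sort()
                    observations.append(obs)
                    number += 1
                previous = sent
                sentence_id += 1
                all_sentences.append(sent)
        parts.append(" ".join(section_sentences) + "\n\n")
    text = "".join(parts)
    return GoldReport(text=text, observations=observations,
                      corpus=GoldCorpus(config=cfg, sentences=all_sentences),
                      sections=section_names)
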