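# toxfindings

Extraction of **treatment-related findings** from preclinical toxicology
study reports.

Toxicology studies record the effects of a test compound on animals as
free-text narrative.  A *treatment-related finding* — an effect
attributable to compound administration, as opposed to spontaneous or
background incidence — is described either by a **study test** (a measured
endpoint such as body weight or platelet count) together with an abnormal
**manifestation** (increase, decrease, alteration), or by an adverse
**finding** (necrosis, ataxia, ...) in study domains without defined
tests.  The observation is further characterised by the **specimen**,
the **sex** and **group** of the affected animals, and the administered
**dose**.  `toxfindings` turns report text into structured observation
records for toxicologists and data engineers who need to mine legacy study
reports.

## What the pipeline does

1. **Section extraction** — soft title matching (case-insensitive,
   numbering- and colon-tolerant, compound titles such as "Discussion and
   conclusions") locates the narrative sections that record findings.
2. **Preprocessing** — abbreviation-aware sentence splitting, tokenisation,
   POS/lemma/shape features.
3. **Sentence relevance** — binary classification into toxicologically
   relevant / non-relevant.  The default backend is a deterministic
   cue-lexicon scorer; a seeded logistic-regression baseline and an
   optional transformer fine-tuning adapter are included.  Classification
   is recall-first: ties go to relevant.
4. **Entity recognition** — a gazetteer + pattern baseline tags the seven
   entity categories (study test, manifestation, finding, specimen, dose,
   sex, group) under a BIO scheme; dose and group are pattern rules
   (`30 mg/kg`, `group A`, `12 mg/kg/day dose group`).
5. **Normalisation** — layered terminologies (SEND core, SEND synonym
   extensions, eTOX-style, UMLS-style, internal tables) map surfaces to
   preferred terms; only SEND-core hits count as *controlled*.
6. **Relation extraction** — deterministic positional rules assemble
   mentions into observations: manifestations share forward across
   coordinated study-test lists, sex/dose/group attach backward per
   clause, specimens bind the nearest anchor, and sex/dose/group missing
   from a sentence are inherited from the immediately preceding sentence
   (one-sentence lookback).  Trigger phrases ("treatment-related",
   "attributable to treatment", ...) set the treatment-related flag unless
   negated within three tokens.
7. **SR-domain export** — observations are projected onto a configurable
   SR-domain template and written as two CSV files.

The corpus toolkit adds Krippendorff's alpha (nominal, token-level units)
for inter-annotator agreement, majority-vote harmonisation,
expression-to-entity standardisation, corpus statistics, exact-match NER
evaluation and classifier metrics.  A seeded synthetic-report generator
produces report text with complete gold annotations, so every stage is
testable without any proprietary data.

## Worked example

```python
from toxfindings.pipeline import run_pipeline

text = """Discussion and conclusions
A decrease in body weight gain was observed in females at the 30 mg/kg dose. \
There was a decrease in total white blood cell, absolute lymphocyte and \
platelet counts in males and females at the 30 mg/kg dose, and a decrease \
in platelet count only for males at the 10 mg/kg dose.
"""
result = run_pipeline(text)
for o in result.observations:
    print(o.obs_id, o.domain_code, o.study_test, o.manifestation, o.sex,
          f"{o.dose_value:g} {o.dose_unit}")
```

prints

```
1.1 BW Weight Gain Decrease Female 30 mg/kg
1.2 LB Leukocyte Count Decrease Both 30 mg/kg
1.3 LB Lymphocyte Count Decrease Both 30 mg/kg
1.4 LB Platelet Count Decrease Both 30 mg/kg
1.5 LB Platelet Count Decrease Male 10 mg/kg
```

Observation 1.1 anchors on the study test *Weight Gain* (normalised from
"body weight gain", SEND body-weight domain BW) with manifestation
*Decrease* in females at 30 mg/kg.  The coordinated laboratory sentence
yields three observations sharing one manifestation, sex and dose, plus a
fourth, male-only platelet observation at 10 mg/kg — the characteristic
coordination and clause structure of toxicology prose.

The same pipeline is available from the shell:

```bash
toxfindings extract --input report.txt --out out/
toxfindings split --n 2933 --ratios 0.70 0.15 0.15   # prints: 2053 440 440
toxfindings synth --n 100 --seed 7 --out synth/       # gold-annotated report
toxfindings iaa annotatorA.conll annotatorB.conll
```

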