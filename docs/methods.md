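# Methods

## Data model

An observation is anchored by exactly one of a study test or a finding
(anchor XOR); a study-test anchor always carries a manifestation, because
a measured endpoint alone describes no abnormality.  Optional fields are
specimen, sex (normalised to {Male, Female, Both}), group, dose
(magnitude + unit), and a treatment-related flag.  Character offsets are
0-based, half-open and document-global everywhere, so any span re-slices
the source text; this single convention is what makes the round-trip and
evidence-slicing invariants checkable.  Observation ids are
`section_index.running_number` (1.1, 1.2, ...).  All observations default
to not-validated; validation is a human act.

## Preprocessing

The preprocessor is deliberately rule-based and dependency-free, because
every downstream stage needs bit-reproducible token offsets:

* Sentence splitting breaks at `.!?` followed by whitespace and an
  upper-case/digit opener, suppressed after a known abbreviation set
  (i.e., e.g., approx., vs., fig., ...) and after single-letter initials.
  Slashes carry no terminator, so dose expressions (`mg/kg/day`) can never
  be split internally.
* Tokenisation keeps hyphen/colon compounds intact (`treatment-related`,
  `M:E`) and splits slashes (`mg`, `/`, `kg`); the dose grammar in the
  recogniser reassembles units, which keeps the tokeniser trivial while
  dose rules own unit syntax.
* Lemmatisation is an exception table plus regular suffix rules (plural
  `-s/-ies`, past `-ed`), sufficient for lexicon matching ("decreased
  basophils" → "decrease basophil"); it is not a general-purpose
  lemmatiser.
* The POS tagger is a coarse closed-class lookup (PUNCT/NUM/ADP/DET/
  CCONJ/VERB/NOUN); relation extraction only consumes broad distinctions.

Section extraction treats any short line that starts upper-cased, has no
sentence-final period and at most six words as a heading candidate; a
candidate matches a target title when the title's word sequence occurs in
it (case-insensitive, after stripping leading numbering and trailing
colons).  A section runs to the next heading-like line, matched or not.
When nothing matches, the caller falls back to whole-document processing.

## Sentence relevance

A sentence is relevant iff it contains an abnormal observation.  Two
deterministic backends:

* **Cue-lexicon scorer** (pipeline default): relevant iff the sentence
  contains any manifestation or finding lemma from the terminology store.
  It needs no training data and is exact on text whose vocabulary the
  store covers.
* **Linear baseline**: logistic regression (scikit-learn) over lemma
  counts, seeded; the same corpus and seed give a byte-identical
  serialised model (JSON with sorted keys).

The decision threshold is 0.5 with ties classified relevant.  The
recall-first stance is deliberate and global to the chain: a missed
observation is unrecoverable downstream, while a false alarm is removed
during expert validation.

The split protocol is frozen: `train = floor(n*r_train)`, then
`val = floor(remainder * r_val/(r_val+r_test))`, `test = remainder - val`,
membership by a seeded uniform shuffle.  This rounding contract
reproduces 2053/440/440 from a 2933-sentence corpus at 70/15/15.

The transformer adapters (sequence and token classification) carry the
optimised settings found during model development — classifier epochs=3,
lr=1.1848183151867784e-05, seed=1; NER epochs=7, lr=5.760003080365119e-05,
seed=4; weight decay 0.01 with early stopping on validation loss — and
require the optional `transformers` extra.  They raise a dependency error
rather than falling back, so a configured transformer run can never
silently become a baseline run.  The hyperparameter search helper samples
lr log-uniformly in [1e-6, 1e-4], epochs in [2, 10] and seeds in [1, 10];
the ranges used for the published models are unpublished, so no fidelity
to them is claimed.

## Entity recognition and normalisation

The baseline tagger combines gazetteer lookup (exact lower-cased surface,
then lemma sequence) for study test / finding / specimen / manifestation /
sex with pattern rules for dose (number + unit grammar over
{µg|mg|g}/kg[/day], mg, ppm) and group ("group" + identifier,
adjective + "dose group", dose expression + "dose group").  Overlap
resolution is longest-match-first with category priority
DOSE > GROUP > STUDY_TEST > FINDING > SPECIMEN > MANIFESTATION > SEX on
ties — dose and group first because their patterns are the most specific.
A group expression that embeds a dose ("12 mg/kg/day dose group") wins by
length and its norm carries the parsed magnitude.

BIO is used as the tagging scheme (standard for span NER and required by
the exact-match metric); orphan `I-` tags decode by repair to `B-`.

Normalisation never changes a span and is idempotent.  Sources are
prioritised SEND core < SEND synonym extension < eTOX-style < UMLS-style <
internal; only SEND-core hits are *controlled*, anything else keeps its
preferred term with a non-controlled flag that the observation record
propagates.  Unmatched mentions are kept without a norm (recall-first).
Post-processing drops stoplisted surfaces and merges same-category
mentions separated only by whitespace/hyphen, then re-resolves overlaps.

The packaged lexicons are compact stand-ins (~160 entries): the SEND mini
file covers common laboratory, body-weight, clinical-sign and microscopic
vocabulary; the extensions file is an explicitly synthetic stand-in for
licensed eTOX/UMLS resources, with the same TSV schema, so full drop-in
terminologies load through the identical interface.  Passing tests with
these files demonstrates mechanism, not coverage of real report
vocabulary.

## Relation extraction

Assembly is deterministic and positional (the attachment scheme is this
package's own realisation; it reproduces the characteristic coordination,
clause and lookback structures of toxicology prose):

1. every study-test and finding mention anchors one observation;
2. a manifestation applies forward to all following anchors until the
   next manifestation — this shares one "decrease" across a coordinated
   test list; an anchor with no preceding manifestation takes the nearest
   following one;
3. sex/dose/group apply backward, each mention binding the anchors since
   the previous same-category mention — this separates per-clause
   modifiers ("... in males and females at 30 mg/kg ..., and X in males
   at 10 mg/kg");
4. specimen binds the nearest anchor by token distance, ties to the
   preceding anchor;
5. sex/dose/group still missing are inherited from the nearest
   same-category mention of the immediately preceding sentence; lookback
   depth is exactly one sentence, never further;
6. a study-test anchor without manifestation yields no observation and a
   logged warning.

Treatment-relatedness triggers match case-insensitively at word
boundaries; a negation cue (not, no, without, unrelated) within the three
preceding tokens suppresses the match.  The window of three is a design
choice documented here: wide enough for "was not considered
treatment-related", narrow enough not to cross clause boundaries in
practice.  An anchorless trigger sentence flags the immediately preceding
sentence's observations.

## Agreement and evaluation

Krippendorff's alpha uses the nominal distance over the coincidence
matrix; units with fewer than two codings are excluded, and zero expected
disagreement yields a flagged undefined result instead of an exception.
The agreement unit is the token-level category label — the strictest
span-compatible choice; whether the original corpus computation used
token, character or expression units is unknown, so coefficients need not
be numerically identical to previously reported ones.  Reported
coefficients round half-up to two decimals; group averages are arithmetic
means of per-group alphas.

NER evaluation is exact match: a prediction counts only when start, end
and category all equal a gold mention; per-category and micro-averaged
P/R/F1 are reported.  Classifier evaluation reports per-class P/R/F1,
macro and support-weighted averages, the confusion matrix, accuracy and a
half-up-rounded percentage error rate.

## Synthetic data

The generator emulates, with construction-time gold: both anchor
patterns; coordinated study-test lists (2-3 tests sharing one
manifestation/sex/dose); sex/dose/group stated only in the preceding
sentence; trigger phrases, half of them negated; non-controlled
vocabulary; and non-relevant boilerplate (dates, husbandry, methods).
Defaults: 200 sentences, relevant fraction 0.43 (the class balance of the
reference gold corpus), coordination 0.2, lookback 0.15, trigger 0.2,
non-controlled 0.1, noise 0.  The noise perturbation is a
length-preserving typo in a non-entity word, so gold offsets stay valid
while surface matching degrades.  Reports are assembled into three
sections whose headings exercise the soft matcher (upper-case, numbered
with colon, compound).

Gold lookback inheritance is applied during report assembly with the same
one-sentence rule the extractor uses, so gold remains a fair field-level
oracle when blocks land adjacent to each other.

What passing against this gold shows: that every mechanism — splitting,
tagging, normalisation, attachment, lookback, triggers, export — is
internally consistent and exact under full lexicon coverage and clean
prose.  What it does not show: robustness to real report vocabulary,
OCR noise, tables, or writing styles outside the templates; published
benchmark figures on the released expert-annotated corpus require
transformer fine-tuning and are out of scope for the default suite.

## Numerical and size choices

All randomness flows through explicit seeds (numpy generators and
`random.Random`); identical configuration means byte-identical output,
including CSV files (frozen dialect: comma, double-quote, LF).  Test and
acceptance runs use corpora of 60-200 sentences and 100-instance oracle
comparisons — sizes at which every behaviour under test is already fully
exercised.  Decimal half-up rounding (not banker's) is used wherever a
two-decimal coefficient or percentage is reported.

## Known limitations

* Gazetteer recall is bounded by the loaded terminology; there is no
  fuzzy or embedding-based linking.
* Attachment rules are positional, not syntactic; unusual argument orders
  (modifiers preceding all anchors) can detach sex/dose/group within the
  sentence.
* PDF handling (layout, OCR, TEI) is out of scope; input is plain text.
* Nested and discontinuous entities are not represented.
* The full 26-field commercial SR-domain template is licensed; only the
  configurable mechanism and an 11-field default are provided.
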