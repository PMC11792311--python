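"""Sentence-level relevance classification.

A sentence is *toxicologically relevant* iff it contains an abnormal
observation.  Two deterministic baselines are provided:

* a cue-lexicon scorer built from the terminology store (a sentence is
  relevant when it mentions a manifestation or finding cue) — the
  pipeline's default, requiring no training data; and
* a seeded linear model (logistic regression over lemma counts) trained
  on a labelled corpus.

Classification is recall-first: the threshold is 0.5 and exact ties go to
RELEVANT, since missed observations are costlier than false alarms — the
expert validates downstream.

The transformer backend used for the published benchmark (BiomedBERT-style
encoder; epochs=3, lr=1.1848183151867784e-05, seed=1, weight_decay=0.01,
early stopping on validation loss) is available behind the
``transformers`` extra and never substitutes silently.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import util as _importlib_util
from typing import Sequence

import numpy as np

from .model import (Category, ConfigurationError, MissingDependencyError,
                    Relevance, Sentence, TrainConfig)
from .normalise import TerminologyStore
from .preprocess import lemma_of

MODEL_FORMAT_VERSION = 1


@dataclass
class SplitResult:
    train_ids: list[int]
    val_ids: list[int]
    test_ids: list[int]
    seed: int

    @property
    def sizes(self) -> tuple[int, int, int]:
        return len(self.train_ids), len(self.val_ids), len(self.test_ids)


def split_corpus(n: int, ratios: tuple[float, float, float],
                 seed: int) -> SplitResult:
    """Seeded train/validation/test partition of ``range(n)``.

    The rounding contract is fixed: ``train = floor(n*r_train)``, then the
    remainder is split as ``val = floor(remainder * r_val/(r_val+r_test))``
    and ``test = remainder - val``.  With the standard 70/15/15 ratios a
    2933-sentence corpus yields 2053/440/440.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if any(r < 0 for r in ratios):
        raise ConfigurationError("ratios must be non-negative")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ConfigurationError(f"ratios must sum to 1, got {sum(ratios)}")
    r_train, r_val, r_test = ratios
    n_train = math.floor(n * r_train)
    remainder = n - n_train
    if r_val + r_test > 0:
        n_val = math.floor(remainder * r_val / (r_val + r_test))
    else:
        n_val = 0
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n).tolist()
    return SplitResult(train_ids=perm[:n_train],
                       val_ids=perm[n_train:n_train + n_val],
                       test_ids=perm[n_train + n_val:],
                       seed=seed)


class TrainingError(ValueError):
    pass


@dataclass
class RelevanceModel:
    """Serialisable relevance scorer.

    ``kind`` is "lexicon" (cue lemmas, untrained) or "linear" (vocabulary
    plus logistic-regression weights).  The score is always the
    relevant-class probability in [0, 1].
    """

    kind: str
    cue_lemmas: frozenset[str] = frozenset()
    vocabulary: dict[str, int] = field(default_factory=dict)
    coef: list[float] = field(default_factory=list)
    intercept: float = 0.0
    seed: int = 0

    def score(self, sentence: Sentence | str) -> float:
        lemmas = _sentence_lemmas(sentence)
        if self.kind == "lexicon":
            return 1.0 if any(l in self.cue_lemmas for l in lemmas) else 0.0
        z = self.intercept
        for l in lemmas:
            idx = self.vocabulary.get(l)
            if idx is not None:
                z += self.coef[idx]
        return 1.0 / (1.0 + math.exp(-z))

    def to_json(self) -> str:
        return json.dumps({
            "format_version": MODEL_FORMAT_VERSION,
            "kind": self.kind,
            "cue_lemmas": sorted(self.cue_lemmas),
            "vocabulary": self.vocabulary,
            "coef": self.coef,
            "intercept": self.intercept,
            "seed": self.seed,
        }, sort_keys=True)

    @classmethod
    def from_json(cls, payload: str) -> "RelevanceModel":
        d = json.loads(payload)
        if d.get("format_version") != MODEL_FORMAT_VERSION:
            raise ConfigurationError(
                f"unsupported model format {d.get('format_version')!r}")
        return cls(kind=d["kind"], cue_lemmas=frozenset(d["cue_lemmas"]),
                   vocabulary=d["vocabulary"], coef=d["coef"],
                   intercept=d["intercept"], seed=d["seed"])


def _sentence_lemmas(sentence: Sentence | str) -> list[str]:
    if isinstance(sentence, str):
        return [lemma_of(w) for w in sentence.split()]
    if sentence.tokens:
        return [t.lemma for t in sentence.tokens]
    return [lemma_of(w) for w in sentence.text.split()]


def lexicon_model(store: TerminologyStore) -> RelevanceModel:
    """Cue-lexicon scorer: manifestation and finding lemmas signal relevance."""
    cues: set[str] = set()
    for cat in (Category.MANIFESTATION, Category.FINDING):
        for key in store.lemma_surfaces(cat):
            cues.update(key.split())
    return RelevanceModel(kind="lexicon", cue_lemmas=frozenset(cues))


def train_baseline(corpus: Sequence[tuple[Sentence | str, Relevance]],
                   seed: int = 0) -> RelevanceModel:
    """Fit the seeded linear baseline on a labelled sentence corpus.

    Deterministic: the same corpus and seed give a byte-identical
    serialised model.  A single-class corpus raises a TrainingError
    naming the missing label.
    """
    from sklearn.linear_model import LogisticRegression

    labels = {lab for _, lab in corpus}
    for required in (Relevance.RELEVANT, Relevance.NON_RELEVANT):
        if required not in labels:
            raise TrainingError(f"corpus lacks {required.value} examples")

    docs = [_sentence_lemmas(s) for s, _ in corpus]
    vocab = {l: i for i, l in enumerate(sorted({l for d in docs for l in d}))}
    X = np.zeros((len(docs), len(vocab)))
    for i, d in enumerate(docs):
        for l in d:
            X[i, vocab[l]] += 1.0
    y = np.array([1 if lab == Relevance.RELEVANT else 0 for _, lab in corpus])
    clf = LogisticRegression(max_iter=1000, random_state=seed)
    clf.fit(X, y)
    return RelevanceModel(kind="linear", vocabulary=vocab,
                          coef=[float(c) for c in clf.coef_[0]],
                          intercept=float(clf.intercept_[0]), seed=seed)


def classify(model: RelevanceModel,
             sentence: Sentence | str) -> tuple[Relevance, float]:
    """Label a sentence; score >= 0.5 (ties included) means RELEVANT."""
    score = model.score(sentence)
    label = Relevance.RELEVANT if score >= 0.5 else Relevance.NON_RELEVANT
    if isinstance(sentence, Sentence):
        sentence.relevance = label
        sentence.relevance_score = score
    return label, score


def sample_search_space(trials: int, seed: int,
                        lr_range: tuple[float, float] = (1e-6, 1e-4),
                        epoch_range: tuple[int, int] = (2, 10),
                        seed_range: tuple[int, int] = (1, 10)) -> list[TrainConfig]:
    """Seeded random hyperparameter candidates (log-uniform learning rate).

    The published models were selected from searches of this shape (50
    trials for the classifier, 100 for NER); the original search ranges are
    unpublished, so no fidelity to them is claimed.
    """
    rng = np.random.default_rng(seed)
    configs = []
    for _ in range(trials):
        lr = float(np.exp(rng.uniform(np.log(lr_range[0]), np.log(lr_range[1]))))
        configs.append(TrainConfig(
            epochs=int(rng.integers(epoch_range[0], epoch_range[1] + 1)),
            learning_rate=lr,
            seed=int(rng.integers(seed_range[0], seed_range[1] + 1))))
    return configs


def finetune_transformer(corpus, config: TrainConfig | None = None):
    """Benchmark-only transformer backend for sentence classification.

    Requires the ``transformers`` extra and a locally available biomedical
    encoder; raises MissingDependencyError otherwise — never a silent
    fallback to the baseline.
    """
    config = (config or TrainConfig.classifier_defaults()).validated()
    for mod in ("transformers", "torch"):
        if _importlib_util.find_spec(mod) is None:
            raise MissingDependencyError(
                f"fine-tuning requires {mod!r}; install the 'transformers' "
                "extra")
    from .transformer_backend import finetune_sequence_classifier
    return finetune_sequence_classifier(corpus, config)


def read_labelled_jsonl(path) -> list[tuple[str, Relevance]]:
    """Labelled-corpus JSON-lines: {"text": ..., "label": "relevant"|"no_relevant"}."""
    from pathlib import Path

    out = []
    mapping = {"relevant": Relevance.RELEVANT,
               "no_relevant": Relevance.NON_RELEVANT}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        d = json.loads(line)
        out.append((d["text"], mapping[d["label"]]))
    return out


def write_labelled_jsonl(corpus: Sequence[tuple[str, Relevance]], path) -> None:
    from pathlib import Path

    mapping = {Relevance.RELEVANT: "relevant",
               Relevance.NON_RELEVANT: "no_relevant"}
    with Path(path).open("w", encoding="utf-8") as fh:
        for text, label in corpus:
            fh.write(json.dumps({"text": text, "label": mapping[label]},
                                ensure_ascii=False) + "\n")
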