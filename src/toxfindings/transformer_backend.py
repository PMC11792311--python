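"""Optional transformer fine-tuning backends (benchmark scale).

Imported lazily, only when `transformers` and `torch` are installed; the
callers in `relevance` and `ner` guard the import and raise a clear
dependency error otherwise.  These routines exist so that the published
benchmark protocol can be re-run against the released gold corpus on a
machine with the extras installed; the default test suite never exercises
them.
"""

from __future__ import annotations

from .model import TrainConfig

CLASSIFIER_ENCODER = "microsoft/BiomedNLP-BiomedBERT-base-uncased-abstract-fulltext"
NER_ENCODER = "dmis-lab/biobert-v1.1"


def _common_args(config: TrainConfig, output_dir: str):
    from transformers import TrainingArguments

    return TrainingArguments(
        output_dir=output_dir,
        num_train_epochs=config.epochs,
        learning_rate=config.learning_rate,
        weight_decay=config.weight_decay,
        seed=config.seed,
        load_best_model_at_end=config.early_stopping,
        eval_strategy="epoch",
        save_strategy="epoch",
        metric_for_best_model="eval_loss",
    )


def finetune_sequence_classifier(corpus, config: TrainConfig,
                                 encoder: str = CLASSIFIER_ENCODER,
                                 output_dir: str = "scratch/cls"):
    """Fine-tune a binary relevance classifier; returns the HF Trainer."""
    from transformers import (AutoModelForSequenceClassification,
                              AutoTokenizer, Trainer)

    tokenizer = AutoTokenizer.from_pretrained(encoder)
    model = AutoModelForSequenceClassification.from_pretrained(
        encoder, num_labels=2)

    def encode(split):
        return [
            {**tokenizer(text, truncation=True), "label": label}
            for text, label in split
        ]

    trainer = Trainer(model=model, args=_common_args(config, output_dir),
                      train_dataset=encode(corpus["train"]),
                      eval_dataset=encode(corpus["validation"]),
                      processing_class=tokenizer)
    trainer.train()
    return trainer


def finetune_token_classifier(corpus, config: TrainConfig,
                              encoder: str = NER_ENCODER,
                              output_dir: str = "scratch/ner"):
    """Fine-tune a BIO token classifier; returns the HF Trainer."""
    from transformers import (AutoModelForTokenClassification, AutoTokenizer,
                              DataCollatorForTokenClassification, Trainer)

    labels = corpus["labels"]  # BIO label list, index = class id
    tokenizer = AutoTokenizer.from_pretrained(encoder)
    model = AutoModelForTokenClassification.from_pretrained(
        encoder, num_labels=len(labels))

    def encode(split):
        out = []
        for tokens, tags in split:
            enc = tokenizer(tokens, is_split_into_words=True, truncation=True)
            word_ids = enc.word_ids()
            enc["labels"] = [
                -100 if w is None else labels.index(tags[w]) for w in word_ids
            ]
            out.append(dict(enc))
        return out

    trainer = Trainer(model=model, args=_common_args(config, output_dir),
                      train_dataset=encode(corpus["train"]),
                      eval_dataset=encode(corpus["validation"]),
                      data_collator=DataCollatorForTokenClassification(tokenizer),
                      processing_class=tokenizer)
    trainer.train()
    return trainer
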