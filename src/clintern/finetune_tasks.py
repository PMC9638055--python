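"""Temporal fine-tuning datasets, token metrics, and the trainer contract.

Two dataset builders feed temporal fine-tuning of an encoder:

* binary — one example per sentence, labeled 1 iff a gold annotation
  overlaps the sentence span;
* Seq2Seq token labeling — BIO (B-/I- per type + O, 9 labels) or Ttype
  (type-only + O, 5 labels) over whitespace tokens.

Token metrics exclude the O label (it dominates the counts) and weight the
remaining labels by gold support.

Fine-tuning itself is a contract: ``fit(dataset, base_provider, epochs,
seed) -> FineTuneResult`` whose result carries a derived embedding provider
and a fitted task head.  The reference trainers here are lightweight
scikit-learn models meant for tiny-scale smoke runs; sequential fine-tuning
(binary then Seq2Seq) is expressed by chaining the returned providers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol

import numpy as np
from sklearn.feature_extraction.text import CountVectorizer
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import make_pipeline

from clintern.corpus_io import Document, TimexAnnotation, segment
from clintern.embedding_features import MockEmbeddingProvider

__all__ = [
    "LabelScheme", "BIO", "TTYPE",
    "make_binary_dataset", "make_token_dataset", "token_metrics",
    "FineTuneResult", "fit_binary", "fit_seq2seq", "fit_sequential",
    "write_sentence_dataset", "write_token_dataset",
]

_TYPES = ("DATE", "TIME", "DURATION", "FREQUENCY")


@dataclass(frozen=True)
class LabelScheme:
    name: str
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.name == "BIO" and len(self.labels) != 9:
            raise ValueError("BIO scheme must have exactly 9 labels")
        if self.name == "Ttype" and len(self.labels) != 5:
            raise ValueError("Ttype scheme must have exactly 5 labels")


BIO = LabelScheme(
    "BIO",
    tuple(f"{p}-{t.lower()}" for t in _TYPES for p in ("B", "I")) + ("O",),
)
TTYPE = LabelScheme("Ttype", tuple(t.lower() for t in _TYPES) + ("O",))


# ---------------------------------------------------------------------------
# Dataset construction

def make_binary_dataset(corpus: list[Document]) -> list[tuple[str, int]]:
    """Sentence texts labeled 1 iff >=1 gold annotation overlaps the sentence."""
    out: list[tuple[str, int]] = []
    for doc in corpus:
        for sent in segment(doc.text):
            hit = any(a.overlaps(sent.start, sent.end) for a in doc.annotations)
            out.append((doc.text[sent.start:sent.end], int(hit)))
    return out


def _owner(token_span: tuple[int, int],
           annotations: list[TimexAnnotation]) -> TimexAnnotation | None:
    """Annotation owning a token; overlapping gold resolved longest-first."""
    s, e = token_span
    hits = [a for a in annotations if a.start < e and s < a.end]
    if not hits:
        return None
    if len(hits) > 1:
        warnings.warn(
            f"token ({s},{e}) overlaps {len(hits)} gold annotations; "
            "longest wins", stacklevel=2)
        hits.sort(key=lambda a: (-(a.end - a.start), a.start))
    return hits[0]


def make_token_dataset(
    corpus: list[Document], scheme: LabelScheme,
) -> list[tuple[list[str], list[str]]]:
    """Per-sentence (tokens, labels) pairs under the BIO or Ttype scheme."""
    if scheme.name not in ("BIO", "Ttype"):
        raise ValueError(f"unknown scheme {scheme.name!r}")
    out = []
    for doc in corpus:
        for sent in segment(doc.text):
            tokens = [doc.text[s:e] for s, e in sent.tokens]
            labels = []
            prev: TimexAnnotation | None = None
            for span in sent.tokens:
                ann = _owner(span, doc.annotations)
                if ann is None:
                    labels.append("O")
                elif scheme.name == "Ttype":
                    labels.append(ann.ttype.value.lower())
                else:
                    tag = "I" if ann is prev else "B"
                    labels.append(f"{tag}-{ann.ttype.value.lower()}")
                prev = ann
            out.append((tokens, labels))
    return out


# ---------------------------------------------------------------------------
# Token metrics (O excluded, gold-support weighting)

def token_metrics(
    gold_labels: list[str], predicted_labels: list[str], scheme: LabelScheme,
) -> dict:
    """Per-label and support-weighted P/R/F1 over non-O labels."""
    if len(gold_labels) != len(predicted_labels):
        raise ValueError(
            f"length mismatch: {len(gold_labels)} gold vs "
            f"{len(predicted_labels)} predicted labels")
    labels = [l for l in scheme.labels if l != "O"]
    per_label: dict[str, dict[str, float]] = {}
    supports: dict[str, int] = {}
    for lab in labels:
        tp = sum(1 for g, p in zip(gold_labels, predicted_labels)
                 if g == lab and p == lab)
        fp = sum(1 for g, p in zip(gold_labels, predicted_labels)
                 if g != lab and p == lab)
        fn = sum(1 for g, p in zip(gold_labels, predicted_labels)
                 if g == lab and p != lab)
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        per_label[lab] = {"precision": prec, "recall": rec, "f1": f1}
        supports[lab] = tp + fn
    total = sum(supports.values())
    weighted = {}
    for metric in ("precision", "recall", "f1"):
        weighted[metric] = (
            sum(per_label[l][metric] * supports[l] for l in labels) / total
            if total else 0.0)
    return {"per_label": per_label, "support": supports, "weighted": weighted}


# ---------------------------------------------------------------------------
# Trainer contract and reference implementations

class TaskHead(Protocol):
    def predict(self, X): ...


@dataclass
class FineTuneResult:
    """Outcome of one fine-tuning step.

    ``provider`` is the (derived) embedding provider to use downstream;
    ``head`` is the fitted task model; ``task`` names the step for chained
    provenance.
    """

    provider: object
    head: object
    task: str
    metadata: dict = field(default_factory=dict)


def _derive_provider(base_provider, task: str, seed: int):
    """Fine-tuning alters the encoder; the mock analogue derives a new seed."""
    if isinstance(base_provider, MockEmbeddingProvider):
        derived = (base_provider.seed * 1_000_003 + hash(task) % 9973 + seed) % (2**31)
        return MockEmbeddingProvider(
            seed=derived,
            hidden_size=base_provider.hidden_size,
            n_layers=base_provider.n_layers,
        )
    return base_provider


def fit_binary(dataset: list[tuple[str, int]], base_provider,
               epochs: int = 1, seed: int = 0) -> FineTuneResult:
    """Binary temporal sentence classification (bag-of-words reference head)."""
    texts = [t for t, _ in dataset]
    y = np.array([l for _, l in dataset])
    head = make_pipeline(
        CountVectorizer(lowercase=True),
        LogisticRegression(max_iter=200 * max(1, epochs), random_state=seed),
    )
    head.fit(texts, y)
    return FineTuneResult(
        provider=_derive_provider(base_provider, "binary", seed),
        head=head, task="binary",
        metadata={"n_examples": len(dataset), "epochs": epochs, "seed": seed},
    )


class _MajorityTokenTagger:
    """Most-frequent label per token surface; unseen tokens -> O."""

    def __init__(self) -> None:
        self.table: dict[str, str] = {}

    def fit(self, sequences: list[tuple[list[str], list[str]]]) -> None:
        counts: dict[str, dict[str, int]] = {}
        for tokens, labels in sequences:
            for tok, lab in zip(tokens, labels):
                counts.setdefault(tok.lower(), {}).setdefault(lab, 0)
                counts[tok.lower()][lab] += 1
        self.table = {
            tok: max(sorted(labs), key=lambda l: labs[l])
            for tok, labs in counts.items()
        }

    def predict(self, tokens: list[str]) -> list[str]:
        return [self.table.get(t.lower(), "O") for t in tokens]


def fit_seq2seq(dataset: list[tuple[list[str], list[str]]], base_provider,
                scheme: LabelScheme, epochs: int = 1, seed: int = 0) -> FineTuneResult:
    """Seq2Seq token labeling (majority-per-surface reference head)."""
    head = _MajorityTokenTagger()
    head.fit(dataset)
    return FineTuneResult(
        provider=_derive_provider(base_provider, f"seq2seq-{scheme.name}", seed),
        head=head, task=f"seq2seq-{scheme.name}",
        metadata={"n_sequences": len(dataset), "epochs": epochs, "seed": seed},
    )


def fit_sequential(binary_dataset, token_dataset, base_provider,
                   scheme: LabelScheme, epochs: int = 1, seed: int = 0) -> FineTuneResult:
    """Binary then Seq2Seq fine-tuning, chained through the derived provider."""
    step1 = fit_binary(binary_dataset, base_provider, epochs=epochs, seed=seed)
    step2 = fit_seq2seq(token_dataset, step1.provider, scheme,
                        epochs=epochs, seed=seed)
    step2.task = f"binary->{step2.task}"
    return step2


# ---------------------------------------------------------------------------
# Writers

def write_sentence_dataset(dataset: list[tuple[str, int]], path: str | Path) -> None:
    lines = [f"{text.replace(chr(9), ' ')}\t{label}" for text, label in dataset]
    Path(path).write_text("\n".join(lines) + "\n")


def write_token_dataset(dataset: list[tuple[list[str], list[str]]],
                        path: str | Path) -> None:
    """CoNLL-style: one token<TAB>label per line, blank line between sentences."""
    blocks = []
    for tokens, labels in dataset:
        blocks.append("\n".join(f"{t}\t{l}" for t, l in zip(tokens, labels)))
    Path(path).write_text("\n\n".join(blocks) + "\n")
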