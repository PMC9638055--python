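"""End-to-end wiring: recognize → featurize → disambiguate → convert → score.

These helpers connect the module surfaces into the three evaluation phases:

1. gold spans — disambiguate the relative gold phrases directly (no
   recognition), scoring type classification alone;
2. system spans — run recognition + conversion, restrict output to spans
   overlapping the relative gold subset, and score type classification;
3. end-to-end — score the complete system output span-wise against the
   full gold standard, with an optional FREQUENCY-removed re-scoring.
"""

from __future__ import annotations

from clintern.corpus_io import Document, TimexAnnotation, TimexType, segment, sentence_containing
from clintern.embedding_features import FeatureVariant, PhraseFeature, featurize_phrase
from clintern.evaluation import (
    class_metrics, confusion_from_pairs, match_pairs, canonical_value,
)
from clintern.gold_filters import filter_dd, restrict_to_gold_overlap
from clintern.recognizer import EntityKind, RecognizerConfig, recognize
from clintern.timeml_converter import ConversionConfig, convert_entities
from clintern.ttd_classifier import TTDModel, train_ttd

__all__ = [
    "annotate_document", "featurize_gold_spans", "train_ttd_from_corpus",
    "run_phase_gold_timex", "run_phase_system_timex", "run_phase_end2end",
]

_AMBIGUOUS = (EntityKind.Period, EntityKind.CalendarInterval)


def _feature_for_span(doc: Document, span: tuple[int, int], provider,
                      variant: FeatureVariant, sentences) -> PhraseFeature:
    sent = sentence_containing(sentences, *span)
    if sent is None:
        raise ValueError(f"span {span} lies outside every sentence of {doc.doc_id}")
    return featurize_phrase(doc.text, sent, span, provider, variant)


def annotate_document(
    doc: Document,
    recognizer_cfg: RecognizerConfig | None = None,
    conversion_cfg: ConversionConfig | None = None,
    provider=None,
    variant: FeatureVariant = FeatureVariant.PhraseOnly,
) -> list[TimexAnnotation]:
    """Full recognition + conversion for one note.

    When the conversion config carries a disambiguation model, every
    Period/Calendar-Interval entity is featurized from its sentence context
    and routed through the model.
    """
    conversion_cfg = conversion_cfg or ConversionConfig()
    entities = recognize(doc.text, recognizer_cfg)
    features: dict[int, PhraseFeature] = {}
    if conversion_cfg.ttd_model is not None:
        if provider is None:
            raise ValueError("an embedding provider is required with a TTD model")
        sentences = segment(doc.text)
        for i, ent in enumerate(entities):
            if ent.kind in _AMBIGUOUS:
                features[i] = _feature_for_span(
                    doc, (ent.start, ent.end), provider, variant, sentences)
    return convert_entities(entities, doc, conversion_cfg, features)


def featurize_gold_spans(
    docs: list[Document], provider,
    variant: FeatureVariant = FeatureVariant.PhraseOnly,
) -> tuple[list[PhraseFeature], list[str]]:
    """(features, type labels) for every gold annotation span in the corpus."""
    features, labels = [], []
    for doc in docs:
        sentences = segment(doc.text)
        for ann in doc.annotations:
            features.append(_feature_for_span(
                doc, (ann.start, ann.end), provider, variant, sentences))
            labels.append(ann.ttype.value)
    return features, labels


def train_ttd_from_corpus(
    docs: list[Document], provider,
    variant: FeatureVariant = FeatureVariant.PhraseOnly,
    hyperparams: dict | None = None,
) -> TTDModel:
    """Train the disambiguator on the DATE+DURATION gold spans of ``docs``."""
    dd = filter_dd(docs)
    features, labels = featurize_gold_spans(dd, provider, variant)
    keep = [i for i, l in enumerate(labels) if l in ("DATE", "DURATION")]
    model = train_ttd([features[i] for i in keep], [labels[i] for i in keep],
                      hyperparams)
    model.metadata["provider_id"] = getattr(provider, "provider_id", str(provider))
    model.metadata["variant"] = variant.value
    return model


# ---------------------------------------------------------------------------
# Evaluation phases

def run_phase_gold_timex(
    reliv_docs: list[Document], model: TTDModel, provider,
    variant: FeatureVariant = FeatureVariant.PhraseOnly,
) -> dict:
    """Phase 1: classify the relative gold spans directly."""
    pairs = []
    for doc in reliv_docs:
        sentences = segment(doc.text)
        predicted = []
        for ann in doc.annotations:
            feat = _feature_for_span(doc, (ann.start, ann.end), provider,
                                     variant, sentences)
            predicted.append(TimexAnnotation(
                ann_id=ann.ann_id, start=ann.start, end=ann.end,
                text=ann.text, ttype=TimexType(model.predict_label(feat))))
        pairs.append((doc.annotations, predicted))
    cm = confusion_from_pairs(pairs)
    return {"confusion": cm, "metrics": class_metrics(cm)}


def run_phase_system_timex(
    docs: list[Document], reliv_docs: list[Document],
    model: TTDModel | None, provider,
    variant: FeatureVariant = FeatureVariant.PhraseOnly,
    recognizer_cfg: RecognizerConfig | None = None,
) -> dict:
    """Phase 2: recognizer spans, restricted to the relative gold subset."""
    conv = ConversionConfig(ttd_model=model)
    pairs = []
    for doc, reliv in zip(docs, reliv_docs):
        system = annotate_document(doc, recognizer_cfg, conv, provider, variant)
        restricted = restrict_to_gold_overlap(system, reliv.annotations)
        pairs.append((reliv.annotations, restricted))
    cm = confusion_from_pairs(pairs)
    return {"confusion": cm, "metrics": class_metrics(cm)}


def _value_accuracy(matched) -> float:
    comparable = [(g, s) for g, s in matched if g.value]
    if not comparable:
        return 0.0
    ok = sum(1 for g, s in comparable
             if canonical_value(g.value) == canonical_value(s.value))
    return ok / len(comparable)


def run_phase_end2end(
    docs: list[Document],
    model: TTDModel | None, provider,
    variant: FeatureVariant = FeatureVariant.PhraseOnly,
    recognizer_cfg: RecognizerConfig | None = None,
    remove_frequency: bool = False,
    system_sets: dict[str, list[TimexAnnotation]] | None = None,
) -> dict:
    """Phase 3: span P/R/F1 plus type accuracy on the complete output.

    ``system_sets`` substitutes precomputed system output (e.g. a fabricated
    run) for the recognizer; otherwise the pipeline runs end to end.
    With ``remove_frequency`` both gold and system FREQUENCY annotations
    are dropped before scoring.
    """
    conv = ConversionConfig(ttd_model=model)
    tp = fp = fn = 0
    type_ok = type_total = 0
    matched_all = []
    for doc in docs:
        if system_sets is not None:
            system = system_sets.get(doc.doc_id, [])
        else:
            system = annotate_document(doc, recognizer_cfg, conv, provider, variant)
        gold = doc.annotations
        if remove_frequency:
            gold = [a for a in gold if a.ttype is not TimexType.FREQUENCY]
            system = [a for a in system if a.ttype is not TimexType.FREQUENCY]
        match = match_pairs(gold, system)
        tp += len(match.matched)
        fp += len(match.added)
        fn += len(match.missed)
        type_total += len(match.matched)
        type_ok += sum(1 for g, s in match.matched if g.ttype == s.ttype)
        matched_all.extend(match.matched)
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return {
        "precision": p, "recall": r, "f1": f1,
        "type_accuracy": type_ok / type_total if type_total else 0.0,
        "value_accuracy": _value_accuracy(matched_all),
        "n_matched": type_total,
    }
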