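"""DATE-vs-DURATION temporal type disambiguation with an SVM.

A relative temporal phrase ("a week ago", "the past 2 weeks") must be typed
as a DATE (a point in time) or a DURATION (a span) before it can be
normalized.  The classifier is a support vector machine over fixed-length
phrase feature vectors; DATE is the positive class (+1), DURATION the
negative class (−1).  Training data may include explicit phrases (the
filtered DATE+DURATION corpus) while evaluation is restricted to the
relative/implicit/vague subset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.svm import SVC

from clintern.embedding_features import FeatureVariant, PhraseFeature

__all__ = ["TTDModel", "train_ttd", "predict_type", "save_model", "load_model",
           "encode_label", "decode_label"]

POSITIVE, NEGATIVE = "DATE", "DURATION"


def encode_label(label: str) -> int:
    if label == POSITIVE:
        return 1
    if label == NEGATIVE:
        return -1
    raise ValueError(f"label must be DATE or DURATION, got {label!r}")


def decode_label(code: int) -> str:
    return POSITIVE if code > 0 else NEGATIVE


@dataclass
class TTDModel:
    svm: SVC
    variant: FeatureVariant
    dim: int
    metadata: dict = field(default_factory=dict)

    def _check(self, feature: PhraseFeature) -> None:
        if feature.dim != self.dim:
            raise ValueError(
                f"feature dim {feature.dim} does not match model dim {self.dim}")
        if feature.variant != self.variant:
            raise ValueError(
                f"feature variant {feature.variant} does not match model "
                f"variant {self.variant}")

    def predict_label(self, feature: PhraseFeature) -> str:
        self._check(feature)
        code = int(self.svm.predict(feature.vector.reshape(1, -1))[0])
        return decode_label(code)


def train_ttd(
    features: list[PhraseFeature],
    labels: list[str],
    hyperparams: dict | None = None,
) -> TTDModel:
    """Train the disambiguation SVM (linear kernel, C=1 by default).

    Requires at least one example of each class and uniform feature
    variant/dimension across the training set.
    """
    if len(features) != len(labels):
        raise ValueError("features and labels must align")
    if not features:
        raise ValueError("empty training set")
    dims = {f.dim for f in features}
    variants = {f.variant for f in features}
    if len(dims) > 1 or len(variants) > 1:
        raise ValueError(f"mixed feature dims {dims} / variants {variants}")
    y = np.array([encode_label(l) for l in labels])
    if len(set(y)) < 2:
        raise ValueError("training set must contain both DATE and DURATION")

    params = {"kernel": "linear", "C": 1.0}
    params.update(hyperparams or {})
    svm = SVC(**params)
    X = np.stack([f.vector for f in features])
    svm.fit(X, y)
    return TTDModel(
        svm=svm,
        variant=variants.pop(),
        dim=dims.pop(),
        metadata={"n_train": len(features), "hyperparams": params},
    )


def predict_type(model: TTDModel, feature: PhraseFeature) -> str:
    """'DATE' (+1 side of the decision function) or 'DURATION' (−1 side)."""
    return model.predict_label(feature)


# ---------------------------------------------------------------------------
# Serialization: versioned binary + JSON metadata sidecar

def save_model(model: TTDModel, path: str | Path) -> None:
    path = Path(path)
    joblib.dump({"svm": model.svm, "variant": model.variant.value,
                 "dim": model.dim, "format_version": 1}, path)
    sidecar = {"variant": model.variant.value, "dim": model.dim,
               "metadata": model.metadata, "format_version": 1}
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2, default=str))


def load_model(path: str | Path) -> TTDModel:
    path = Path(path)
    blob = joblib.load(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    metadata = {}
    if sidecar_path.exists():
        metadata = json.loads(sidecar_path.read_text()).get("metadata", {})
    return TTDModel(svm=blob["svm"], variant=FeatureVariant(blob["variant"]),
                    dim=blob["dim"], metadata=metadata)
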