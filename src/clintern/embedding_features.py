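"""Phrase feature vectors from per-subword, per-layer contextual embeddings.

An encoder provider returns, per sentence, a tensor of shape
``(layers L, subwords S, hidden H)`` plus a map from subword index to
whitespace-token index.  Feature construction is provider-agnostic:

* token resolution — each whitespace token is represented by the
  concatenation of the last 4 hidden layers of its LAST subword (length
  ``4·H``; 3,072 at H=768), ordered shallowest-of-the-last-four first;
* Phrase-Only — the elementwise mean of the phrase's token vectors
  (``4·H``);
* Phrase+Context — mean of up to 3 tokens before ∥ phrase mean ∥ mean of
  up to 3 tokens after (``12·H``; 9,216 at H=768).  A side with zero
  available tokens (phrase at the sentence edge, or phrase = whole
  sentence) is replaced by a duplicate of the phrase vector.

A deterministic mock provider stands in for a transformer encoder: vectors
are seeded hashes of (subword surface, token position, layer), so identical
inputs and seed give identical batches.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "FeatureVariant", "PhraseFeature", "SubwordEmbeddingBatch",
    "MockEmbeddingProvider", "mock_embed",
    "resolve_tokens", "phrase_only", "phrase_context", "featurize_phrase",
]

CONTEXT_WINDOW = 3  # whitespace tokens on each side
N_LAYERS_POOLED = 4


class FeatureVariant(str, Enum):
    PhraseOnly = "PhraseOnly"
    PhraseContext = "PhraseContext"


@dataclass(frozen=True)
class PhraseFeature:
    vector: np.ndarray
    variant: FeatureVariant

    @property
    def dim(self) -> int:
        return int(self.vector.shape[0])


@dataclass
class SubwordEmbeddingBatch:
    """One sentence's subwords, their token ownership, and the layer tensor."""

    subwords: list[str]
    subword_to_token: list[int]     # len == len(subwords)
    tensor: np.ndarray              # (L, S, H)

    def __post_init__(self) -> None:
        L, S, H = self.tensor.shape
        if S != len(self.subwords) or S != len(self.subword_to_token):
            raise ValueError("subword bookkeeping does not match tensor shape")
        if L < N_LAYERS_POOLED:
            raise ValueError(f"provider must expose >= {N_LAYERS_POOLED} layers, got {L}")

    @property
    def n_tokens(self) -> int:
        return max(self.subword_to_token) + 1 if self.subword_to_token else 0

    @property
    def hidden_size(self) -> int:
        return int(self.tensor.shape[2])


def resolve_tokens(batch: SubwordEmbeddingBatch) -> np.ndarray:
    """Per-token vectors of length 4·H: last subword, last 4 layers concatenated."""
    L, _, H = batch.tensor.shape
    n_tokens = batch.n_tokens
    last_subword = [-1] * n_tokens
    for si, ti in enumerate(batch.subword_to_token):
        last_subword[ti] = si
    if any(si < 0 for si in last_subword):
        missing = [ti for ti, si in enumerate(last_subword) if si < 0]
        raise ValueError(f"tokens {missing} own no subwords")
    out = np.empty((n_tokens, N_LAYERS_POOLED * H), dtype=batch.tensor.dtype)
    for ti, si in enumerate(last_subword):
        out[ti] = np.concatenate(
            [batch.tensor[layer, si] for layer in range(L - N_LAYERS_POOLED, L)])
    return out


def _check_phrase(phrase_token_indices) -> list[int]:
    idx = list(phrase_token_indices)
    if not idx:
        raise ValueError("phrase must contain at least one token")
    if idx != list(range(idx[0], idx[0] + len(idx))):
        raise ValueError("phrase token indices must be contiguous")
    return idx


def phrase_only(token_vectors: np.ndarray, phrase_token_indices) -> PhraseFeature:
    """Mean over the phrase's token vectors (dim 4·H)."""
    idx = _check_phrase(phrase_token_indices)
    vec = token_vectors[idx].mean(axis=0)
    return PhraseFeature(vector=vec, variant=FeatureVariant.PhraseOnly)


def phrase_context(
    token_vectors: np.ndarray,
    phrase_token_indices,
    sentence_token_count: int | None = None,
) -> PhraseFeature:
    """[before-window mean ∥ phrase mean ∥ after-window mean] (dim 12·H)."""
    idx = _check_phrase(phrase_token_indices)
    n = sentence_token_count if sentence_token_count is not None else len(token_vectors)
    phrase_vec = token_vectors[idx].mean(axis=0)

    before_idx = list(range(max(0, idx[0] - CONTEXT_WINDOW), idx[0]))
    after_idx = list(range(idx[-1] + 1, min(n, idx[-1] + 1 + CONTEXT_WINDOW)))
    before = token_vectors[before_idx].mean(axis=0) if before_idx else phrase_vec
    after = token_vectors[after_idx].mean(axis=0) if after_idx else phrase_vec

    vec = np.concatenate([before, phrase_vec, after])
    return PhraseFeature(vector=vec, variant=FeatureVariant.PhraseContext)


# ---------------------------------------------------------------------------
# Deterministic mock provider

def _hash_vector(parts: tuple, hidden: int) -> np.ndarray:
    key = "|".join(str(p) for p in parts).encode("utf-8")
    rng = np.random.RandomState(zlib.crc32(key) & 0x7FFFFFFF)
    return rng.standard_normal(hidden).astype(np.float64)


def _split_subwords(token: str, max_len: int = 6) -> list[str]:
    if len(token) > max_len:
        half = len(token) // 2
        return [token[:half], token[half:]]
    return [token]


class MockEmbeddingProvider:
    """Seeded stand-in encoder with the same batch contract as a transformer.

    Each subword's layer vector is a seeded hash of (subword surface, token
    position, layer), so outputs are reproducible and input-sensitive.
    Tokens longer than 6 characters split into two subwords.
    """

    def __init__(self, seed: int = 0, hidden_size: int = 768, n_layers: int = 12):
        self.seed = seed
        self.hidden_size = hidden_size
        self.n_layers = n_layers

    @property
    def provider_id(self) -> str:
        return f"mock(seed={self.seed},H={self.hidden_size},L={self.n_layers})"

    def embed(self, sentences: list[list[str]]) -> list[SubwordEmbeddingBatch]:
        return [self._embed_one(tokens) for tokens in sentences]

    def _embed_one(self, tokens: list[str]) -> SubwordEmbeddingBatch:
        subwords: list[str] = []
        owner: list[int] = []
        for ti, tok in enumerate(tokens):
            for piece in _split_subwords(tok):
                subwords.append(piece)
                owner.append(ti)
        tensor = np.empty((self.n_layers, len(subwords), self.hidden_size))
        for si, piece in enumerate(subwords):
            for layer in range(self.n_layers):
                tensor[layer, si] = _hash_vector(
                    (self.seed, piece, owner[si], layer), self.hidden_size)
        return SubwordEmbeddingBatch(subwords=subwords, subword_to_token=owner,
                                     tensor=tensor)


def mock_embed(sentence_tokens: list[str], seed: int = 0,
               hidden_size: int = 768, n_layers: int = 12) -> SubwordEmbeddingBatch:
    """One-sentence convenience wrapper around :class:`MockEmbeddingProvider`."""
    return MockEmbeddingProvider(seed, hidden_size, n_layers).embed([sentence_tokens])[0]


# ---------------------------------------------------------------------------
# Span-level featurization against a document

def featurize_phrase(
    text: str,
    sentence,
    span: tuple[int, int],
    provider,
    variant: FeatureVariant = FeatureVariant.PhraseOnly,
) -> PhraseFeature:
    """Build the feature for the phrase at ``span`` inside ``sentence``.

    A phrase token is any sentence token overlapping the span.  The window
    never crosses the sentence boundary.
    """
    start, end = span
    tokens = [text[s:e] for s, e in sentence.tokens]
    idx = [i for i, (s, e) in enumerate(sentence.tokens) if s < end and start < e]
    if not idx:
        raise ValueError(f"span ({start},{end}) overlaps no token of its sentence")
    batch = provider.embed([tokens])[0]
    vectors = resolve_tokens(batch)
    if variant is FeatureVariant.PhraseOnly:
        return phrase_only(vectors, idx)
    return phrase_context(vectors, idx, sentence_token_count=len(tokens))
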