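"""Token-feature providers and token‖radical feature concatenation.

The tagger is agnostic to where per-character token vectors come from: any
object satisfying :class:`EmbeddingProvider` can feed it.  Two providers are
shipped:

``TrainableLookupProvider``
    A character-lookup embedding table with an UNK row, trained jointly
    with the tagger.  This is the default and is self-contained.

``ContextualAdapter``
    A thin shim around any external system that maps a character sequence
    to per-character context-dependent vectors of a declared width (e.g. a
    pretrained transformer encoder served elsewhere).  Integration is
    configuration — you hand it a callable — not code.
"""

from __future__ import annotations

from typing import Callable, Protocol, Sequence, runtime_checkable

import numpy as np

from .corpus_io import ModelSequence

UNK = "[UNK]"


@runtime_checkable
class EmbeddingProvider(Protocol):
    """Contract: deterministic per-character vectors of fixed width."""

    dim: int
    kind: str

    def embed(self, seq: ModelSequence) -> np.ndarray:
        """Vectors for the mask-true positions only, shape (n_real, dim)."""
        ...


class TrainableLookupProvider:
    """Context-free trainable character embeddings with an UNK row.

    Row 0 is the UNK row; the vocabulary is built from a training corpus
    with :meth:`fit_vocab`.  Rows are initialized uniformly on
    [-0.5/dim, +0.5/dim] from ``seed`` so two providers with identical
    (vocabulary, dim, seed) produce identical vectors.
    """

    kind = "trainable_lookup"

    def __init__(self, dim: int = 64, seed: int = 0):
        if dim < 1:
            raise ValueError("dim must be positive")
        self.dim = dim
        self.seed = seed
        self.vocab: dict[str, int] = {UNK: 0}
        self.weights = self._init_rows(1)

    def _init_rows(self, n: int) -> np.ndarray:
        rng = np.random.default_rng(self.seed)
        scale = 0.5 / self.dim
        return rng.uniform(-scale, scale, size=(n, self.dim))

    def fit_vocab(self, texts: Sequence[str]) -> "TrainableLookupProvider":
        chars = sorted({ch for text in texts for ch in text})
        self.vocab = {UNK: 0}
        for ch in chars:
            self.vocab[ch] = len(self.vocab)
        self.weights = self._init_rows(len(self.vocab))
        return self

    def row_of(self, ch: str) -> int:
        return self.vocab.get(ch, 0)

    def rows(self, seq: ModelSequence) -> np.ndarray:
        return np.asarray(
            [self.row_of(ch) for ch in seq.real_chars()], dtype=np.intp
        )

    def embed(self, seq: ModelSequence) -> np.ndarray:
        rows = self.rows(seq)
        if rows.size == 0:
            return np.zeros((0, self.dim))
        return self.weights[rows]


class ContextualAdapter:
    """Adapter for an external contextual encoder.

    ``backend`` maps a character string to an (n, dim) array.  Without a
    backend the adapter cannot run and says so explicitly.
    """

    kind = "contextual_adapter"

    def __init__(self, dim: int, backend: Callable[[str], np.ndarray] | None = None):
        self.dim = dim
        self.backend = backend

    def embed(self, seq: ModelSequence) -> np.ndarray:
        if self.backend is None:
            raise RuntimeError(
                "contextual_adapter has no backend configured; supply a "
                "callable producing per-character vectors, or use the "
                "trainable_lookup provider"
            )
        chars = seq.real_chars()
        out = np.asarray(self.backend("".join(chars)), dtype=float)
        if out.shape != (len(chars), self.dim):
            raise ValueError(
                f"backend returned shape {out.shape}, expected "
                f"({len(chars)}, {self.dim})"
            )
        return out


def embed_tokens(seq: ModelSequence, provider: EmbeddingProvider) -> np.ndarray:
    """Token-feature vectors for the real characters of a model sequence."""
    out = provider.embed(seq)
    n_real = sum(seq.token_mask)
    if out.shape != (n_real, provider.dim):
        raise ValueError(
            f"provider returned shape {out.shape}, expected ({n_real}, {provider.dim})"
        )
    return out


def concat_features(token_vecs: np.ndarray, radical_vecs: np.ndarray) -> np.ndarray:
    """Per-position [token ‖ radical] concatenation, token part first."""
    token_vecs = np.asarray(token_vecs, dtype=float)
    radical_vecs = np.asarray(radical_vecs, dtype=float)
    if token_vecs.shape[0] != radical_vecs.shape[0]:
        raise ValueError(
            f"length mismatch: {token_vecs.shape[0]} token vectors vs "
            f"{radical_vecs.shape[0]} radical vectors"
        )
    if token_vecs.shape[0] == 0:
        return np.zeros((0, token_vecs.shape[1] + radical_vecs.shape[1]))
    return np.concatenate([token_vecs, radical_vecs], axis=1)
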