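"""The radical-augmented Bi-LSTM-CRF sequence tagger.

Architecture, per character position: a token-feature vector (from a
pluggable :class:`~radner.embeddings.EmbeddingProvider`) is concatenated
with a trainable 20-dimensional embedding of the character's Kangxi
radical; the concatenated features run through a bidirectional LSTM (128
hidden units per direction by default); an affine projection of the
concatenated directional states yields per-tag emission scores; a
linear-chain CRF on top supplies the training objective (path negative
log-likelihood) and Viterbi decoding.

Exposed as a scikit-learn-style estimator: ``fit`` takes annotated
documents, ``predict`` takes raw texts and returns documents with predicted
entity spans in whole-narrative offsets, and ``score`` is held-out strict
micro-F1.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass

import numpy as np
from sklearn.base import BaseEstimator

from . import crf
from .corpus_io import (
    TAGS,
    TAG_TO_INDEX,
    AnnotatedDocument,
    split_long,
    spans_to_tags,
    tags_to_spans,
    to_model_sequence,
)
from .embeddings import EmbeddingProvider, TrainableLookupProvider, concat_features
from .nn import Adam, BiLSTM, glorot
from .radicals import (
    N_RADICALS,
    RadicalEmbeddingTable,
    RadicalIndex,
    build_radical_index,
)

logger = logging.getLogger(__name__)

CHECKPOINT_FORMAT = "radner-checkpoint-v1"


@dataclass
class TrainConfig:
    """Published training settings (defaults) for the tagger.

    batch_size 16, Bi-LSTM hidden width 128 per direction, radical
    embedding width 20, Adam at 5e-5, maximum model-sequence length 512.
    Epoch count, dropout and gradient clipping are implementation defaults.
    The 5e-5 rate suits fine-tuning a pretrained contextual provider; the
    from-scratch lookup-embedding configuration trains with the
    conventional Adam rate 1e-3 (see the synthetic pipeline).
    """

    batch_size: int = 16
    lstm_hidden: int = 128
    radical_dim: int = 20
    learning_rate: float = 5e-5
    max_len: int = 512
    epochs: int = 20
    embedding_dim: int = 64
    dropout: float = 0.1
    grad_clip: float = 5.0
    mask_illegal: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("batch_size", "lstm_hidden", "radical_dim", "max_len",
                     "epochs", "embedding_dim"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


def _illegal_transition_mask() -> tuple[np.ndarray, np.ndarray]:
    """(-inf) masks forbidding O/B-T'/I-T' -> I-T and a path starting at I-T."""
    K = len(TAGS)
    trans = np.zeros((K, K))
    start = np.zeros(K)
    for j, tj in enumerate(TAGS):
        if not tj.startswith("I-"):
            continue
        etype = tj[2:]
        start[j] = -np.inf
        for i, ti in enumerate(TAGS):
            if ti not in (f"B-{etype}", f"I-{etype}"):
                trans[i, j] = -np.inf
    return trans, start


class RadicalBiLstmCrfTagger(BaseEstimator):
    """Radical-augmented Bi-LSTM-CRF character tagger (Reason/Drug/ADR).

    Parameters mirror :class:`TrainConfig`; ``provider`` defaults to a
    trainable character-lookup table and ``radical_index`` to the packaged
    Kangxi table.  All randomness (initialization, shuffling, dropout)
    derives from ``seed``.

    Fitted attributes
    -----------------
    params_ : dict of parameter arrays (embeddings, LSTM, projection, CRF)
    provider_ : the fitted embedding provider
    history_ : per-epoch mean training loss
    n_tags_ : size of the BIO label alphabet (7)
    """

    def __init__(
        self,
        embedding_dim: int = 64,
        radical_dim: int = 20,
        lstm_hidden: int = 128,
        batch_size: int = 16,
        learning_rate: float = 5e-5,
        epochs: int = 20,
        max_len: int = 512,
        dropout: float = 0.1,
        grad_clip: float = 5.0,
        mask_illegal: bool = False,
        seed: int = 0,
        provider: EmbeddingProvider | None = None,
        radical_index: RadicalIndex | None = None,
        warm_start: bool = False,
        verbose: int = 0,
    ):
        self.embedding_dim = embedding_dim
        self.radical_dim = radical_dim
        self.lstm_hidden = lstm_hidden
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.max_len = max_len
        self.dropout = dropout
        self.grad_clip = grad_clip
        self.mask_illegal = mask_illegal
        self.seed = seed
        self.provider = provider
        self.radical_index = radical_index
        self.warm_start = warm_start
        self.verbose = verbose

    # -- internals ---------------------------------------------------------

    def _crf_params(self) -> crf.CRFParameters:
        trans = self.params_["crf.trans"]
        start = self.params_["crf.start"]
        if self.mask_illegal:
            mt, ms = _illegal_transition_mask()
            trans = trans + mt
            start = start + ms
        return crf.CRFParameters(trans, start, self.params_["crf.end"])

    def _init_state(self, docs: list[AnnotatedDocument]) -> None:
        rng = np.random.default_rng(self.seed)
        self.n_tags_ = len(TAGS)
        provider = self.provider
        if provider is None:
            provider = TrainableLookupProvider(self.embedding_dim, seed=self.seed)
        if isinstance(provider, TrainableLookupProvider) and len(provider.vocab) <= 1:
            provider.fit_vocab([d.text for d in docs])
        self.provider_ = provider
        self.radical_index_ = (
            self.radical_index if self.radical_index is not None else build_radical_index()
        )
        rad_table = RadicalEmbeddingTable(self.radical_dim, seed=self.seed)
        d_in = self.provider_.dim + self.radical_dim
        self._bilstm = BiLSTM(d_in, self.lstm_hidden, rng)
        K = self.n_tags_
        self.params_ = {
            "emb.rad": rad_table.vectors,
            "lstm.fwd.Wx": self._bilstm.fwd.Wx,
            "lstm.fwd.Wh": self._bilstm.fwd.Wh,
            "lstm.fwd.b": self._bilstm.fwd.b,
            "lstm.bwd.Wx": self._bilstm.bwd.Wx,
            "lstm.bwd.Wh": self._bilstm.bwd.Wh,
            "lstm.bwd.b": self._bilstm.bwd.b,
            "proj.W": glorot(rng, (2 * self.lstm_hidden, K)),
            "proj.b": np.zeros(K),
            "crf.trans": np.zeros((K, K)),
            "crf.start": np.zeros(K),
            "crf.end": np.zeros(K),
        }
        if isinstance(self.provider_, TrainableLookupProvider):
            self.params_["emb.char"] = self.provider_.weights
        self.history_ = []
        self._epochs_done = 0

    def _rebind(self) -> None:
        """Point the BiLSTM/provider views at params_ after load/clone."""
        d_in = self.provider_.dim + self.radical_dim
        self._bilstm = BiLSTM(d_in, self.lstm_hidden, np.random.default_rng(0))
        self._bilstm.fwd.Wx = self.params_["lstm.fwd.Wx"]
        self._bilstm.fwd.Wh = self.params_["lstm.fwd.Wh"]
        self._bilstm.fwd.b = self.params_["lstm.fwd.b"]
        self._bilstm.bwd.Wx = self.params_["lstm.bwd.Wx"]
        self._bilstm.bwd.Wh = self.params_["lstm.bwd.Wh"]
        self._bilstm.bwd.b = self.params_["lstm.bwd.b"]
        if isinstance(self.provider_, TrainableLookupProvider):
            self.provider_.weights = self.params_["emb.char"]

    def _features(self, seq) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(features, char rows, radical ids) for a model sequence."""
        chars = seq.real_chars()
        rid = np.asarray([self.radical_index_.lookup(c) for c in chars], dtype=np.intp)
        tok = self.provider_.embed(seq)
        rad = self.params_["emb.rad"][rid]
        x = concat_features(tok, rad)
        if isinstance(self.provider_, TrainableLookupProvider):
            rows = self.provider_.rows(seq)
        else:
            rows = np.full(len(chars), -1, dtype=np.intp)
        return x, rows, rid

    def _sequence_grads(
        self, seq, gold_idx: np.ndarray, rng: np.random.Generator, train: bool
    ) -> tuple[float, dict[str, np.ndarray]]:
        x, rows, rid = self._features(seq)
        hs, cache = self._bilstm.forward(x)
        if train and self.dropout > 0:
            keep = 1.0 - self.dropout
            mask = (rng.random(hs.shape) < keep) / keep
            hs_d = hs * mask
        else:
            mask = None
            hs_d = hs
        W, b = self.params_["proj.W"], self.params_["proj.b"]
        emissions = hs_d @ W + b
        loss, d_e, d_trans, d_start, d_end = crf.nll_and_grads(
            emissions, self._crf_params(), gold_idx
        )
        grads = {
            "crf.trans": d_trans,
            "crf.start": d_start,
            "crf.end": d_end,
            "proj.W": hs_d.T @ d_e,
            "proj.b": d_e.sum(axis=0),
        }
        d_hs = d_e @ W.T
        if mask is not None:
            d_hs = d_hs * mask
        dxs, lstm_grads = self._bilstm.backward(d_hs, cache)
        for direction in ("fwd", "bwd"):
            for name, g in lstm_grads[direction].items():
                grads[f"lstm.{direction}.{name}"] = g
        d_tok = dxs[:, : self.provider_.dim]
        d_rad = dxs[:, self.provider_.dim :]
        g_rad = np.zeros_like(self.params_["emb.rad"])
        np.add.at(g_rad, rid, d_rad)
        grads["emb.rad"] = g_rad
        if "emb.char" in self.params_:
            g_char = np.zeros_like(self.params_["emb.char"])
            np.add.at(g_char, rows, d_tok)
            grads["emb.char"] = g_char
        return loss, grads

    def _prepare(self, docs: list[AnnotatedDocument]):
        """Split to max content length and attach gold tag indices."""
        out = []
        for doc in docs:
            for frag in split_long(doc, self.max_len - 2):
                if len(frag.text) == 0:
                    continue
                seq = to_model_sequence(frag, min(self.max_len, len(frag.text) + 2))
                gold = np.asarray(
                    [TAG_TO_INDEX[t] for t in spans_to_tags(frag)], dtype=np.intp
                )
                out.append((seq, gold))
        return out

    # -- estimator API -----------------------------------------------------

    def fit(self, X: list[AnnotatedDocument], y=None) -> "RadicalBiLstmCrfTagger":
        """Train on annotated documents (labels live inside the documents)."""
        if not X:
            raise ValueError("cannot train on an empty corpus")
        if not (self.warm_start and hasattr(self, "params_")):
            self._init_state(X)
        else:
            self._rebind()
        rng = np.random.default_rng(
            np.random.SeedSequence([self.seed, 1 + self._epochs_done])
        )
        data = self._prepare(X)
        optimizer = Adam(
            self.params_, lr=self.learning_rate, clip_norm=self.grad_clip
        )
        for epoch in range(self.epochs):
            order = rng.permutation(len(data))
            total_loss = 0.0
            for lo in range(0, len(order), self.batch_size):
                batch = order[lo : lo + self.batch_size]
                acc: dict[str, np.ndarray] = {}
                batch_loss = 0.0
                for idx in batch:
                    seq, gold = data[idx]
                    loss, grads = self._sequence_grads(seq, gold, rng, train=True)
                    batch_loss += loss
                    for k, g in grads.items():
                        acc[k] = acc[k] + g if k in acc else g
                if not np.isfinite(batch_loss):
                    raise RuntimeError(
                        f"non-finite training loss at epoch {self._epochs_done + 1}"
                    )
                n = len(batch)
                optimizer.step({k: g / n for k, g in acc.items()})
                total_loss += batch_loss
            self._epochs_done += 1
            mean_loss = total_loss / len(data)
            self.history_.append({"epoch": self._epochs_done, "loss": mean_loss})
            if self.verbose:
                logger.info(
                    "epoch %d: mean NLL per sequence %.4f", self._epochs_done, mean_loss
                )
        return self

    def predict(self, X: list[str]) -> list[AnnotatedDocument]:
        """Tag raw narratives; spans returned in whole-document offsets."""
        if not hasattr(self, "params_"):
            raise RuntimeError("tagger is not fitted")
        self._rebind()
        params = self._crf_params()
        W, b = self.params_["proj.W"], self.params_["proj.b"]
        out = []
        for i, text in enumerate(X):
            doc = AnnotatedDocument(str(i), text)
            spans = []
            for frag in split_long(doc, self.max_len - 2):
                if len(frag.text) == 0:
                    continue
                seq = to_model_sequence(frag, min(self.max_len, len(frag.text) + 2))
                x, _, _ = self._features(seq)
                hs, _ = self._bilstm.forward(x)
                emissions = hs @ W + b
                path = crf.viterbi(emissions, params)
                tags = [TAGS[k] for k in path]
                for sp in tags_to_spans(tags):
                    spans.append(sp.shifted(frag.origin_offset))
            out.append(AnnotatedDocument(str(i), text, tuple(sorted(spans))))
        return out

    def predict_documents(
        self, docs: list[AnnotatedDocument]
    ) -> list[AnnotatedDocument]:
        """Like :meth:`predict` but preserves the input documents' ids."""
        preds = self.predict([d.text for d in docs])
        return [
            AnnotatedDocument(d.doc_id, d.text, p.entities)
            for d, p in zip(docs, preds)
        ]

    def score(self, X: list[AnnotatedDocument], y=None) -> float:
        """Strict-match micro-F1 (fraction in [0, 1]) against gold documents."""
        from .evaluation import strict_match_score

        preds = self.predict_documents(X)
        return strict_match_score(X, preds).micro.f1

    # -- checkpointing -----------------------------------------------------

    def save(self, path: str) -> None:
        """Write a single-archive checkpoint (parameters + config + vocab)."""
        if not hasattr(self, "params_"):
            raise RuntimeError("tagger is not fitted")
        meta = {
            "format": CHECKPOINT_FORMAT,
            "config": {
                k: v
                for k, v in self.get_params().items()
                if k not in ("provider", "radical_index")
            },
            "provider_kind": self.provider_.kind,
            "provider_dim": self.provider_.dim,
            "tags": list(TAGS),
            "epochs_done": self._epochs_done,
            "history": self.history_,
        }
        if isinstance(self.provider_, TrainableLookupProvider):
            meta["vocab"] = sorted(
                self.provider_.vocab, key=self.provider_.vocab.get
            )
        arrays = {k.replace(".", "__"): v for k, v in self.params_.items()}
        np.savez(path, meta=np.frombuffer(
            json.dumps(meta).encode("utf-8"), dtype=np.uint8
        ), **arrays)

    @classmethod
    def load(cls, path: str) -> "RadicalBiLstmCrfTagger":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode("utf-8"))
            if meta.get("format") != CHECKPOINT_FORMAT:
                raise ValueError(f"unrecognized checkpoint format in {path}")
            arrays = {
                k.replace("__", "."): data[k] for k in data.files if k != "meta"
            }
        est = cls(**meta["config"])
        est.n_tags_ = len(meta["tags"])
        est.params_ = arrays
        est.history_ = meta["history"]
        est._epochs_done = meta["epochs_done"]
        if meta["provider_kind"] == "trainable_lookup":
            provider = TrainableLookupProvider(meta["provider_dim"], seed=est.seed)
            provider.vocab = {ch: i for i, ch in enumerate(meta["vocab"])}
            provider.weights = est.params_["emb.char"]
            est.provider_ = provider
        else:
            raise ValueError(
                "only trainable_lookup checkpoints can be reloaded standalone; "
                "reattach the contextual backend and rebuild the estimator"
            )
        est.radical_index_ = build_radical_index()
        est._rebind()
        return est


def train(
    corpus: list[AnnotatedDocument],
    cfg: TrainConfig | None = None,
    provider: EmbeddingProvider | None = None,
    index: RadicalIndex | None = None,
    verbose: int = 0,
) -> RadicalBiLstmCrfTagger:
    """Functional wrapper: fit a tagger on a corpus under a TrainConfig."""
    cfg = cfg or TrainConfig()
    est = RadicalBiLstmCrfTagger(
        embedding_dim=cfg.embedding_dim,
        radical_dim=cfg.radical_dim,
        lstm_hidden=cfg.lstm_hidden,
        batch_size=cfg.batch_size,
        learning_rate=cfg.learning_rate,
        epochs=cfg.epochs,
        max_len=cfg.max_len,
        dropout=cfg.dropout,
        grad_clip=cfg.grad_clip,
        mask_illegal=cfg.mask_illegal,
        seed=cfg.seed,
        provider=provider,
        radical_index=index,
        verbose=verbose,
    )
    return est.fit(corpus)


def predict(texts: list[str], model: RadicalBiLstmCrfTagger) -> list[AnnotatedDocument]:
    """Functional wrapper over :meth:`RadicalBiLstmCrfTagger.predict`."""
    return model.predict(texts)


def config_to_dict(cfg: TrainConfig) -> dict:
    return asdict(cfg)
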