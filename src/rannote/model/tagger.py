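"""BiLSTM-CRF sequence tagger with char-CNN and gated embedding combination.

Architecture, bottom to top: word embedding lookup; a character encoder per
word (CNN over char embeddings with kernel widths 2/3/4 and max-pooling by
default, a char BiLSTM or nothing as ablations); combination of word and
character vectors by a learned elementwise sigmoid gate
``z = sigmoid(U tanh(Wx + Vc + b)); out = z*x + (1-z)*c`` (plain
concatenation as ablation); a bidirectional LSTM; a linear layer with
log-softmax emissions; and a linear-chain CRF decoded by Viterbi.

Training minimizes the mean sentence-level CRF negative log-likelihood by
mini-batch gradient descent with Adadelta updates, global-norm gradient
clipping at 5.0, dropout 0.5 on hidden units, optional batch normalization,
and optional early stopping on development-set entity F.  A single seed
drives initialization, shuffling and dropout masks; runs are deterministic
in single-threaded execution.

The public surface follows the model/results convention:
``BiLstmCrfTagger(sequences, config).fit()`` returns a
:class:`TaggerResults` carrying the fitted parameters, per-epoch history and
prediction/evaluation helpers.
"""

from __future__ import annotations

import dataclasses
import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ..pipeline import (
    EncodedBatch,
    TaggedSequence,
    Vocab,
    encode_batch,
)
from . import crf as crf_mod
from .crf import CrfParams, viterbi_decode
from .layers import (
    BatchNorm,
    BiLstm,
    CharCnn,
    Dense,
    Dropout,
    Embedding,
    Gate,
    Lstm,
    Param,
)

_COMBINERS = ("gate", "concat")
_CHAR_ENCODERS = ("cnn", "lstm", "none")


@dataclass
class TrainConfig:
    """Hyper-parameters of the tagger and its training loop.

    The documented training regime fixes batch size 20, Adadelta updates,
    gradient clipping 5.0 and dropout 0.5; layer sizes are free
    configuration choices with CPU-friendly defaults.  ``combiner`` and
    ``char_encoder`` cover the ablations: ``combiner="concat"`` disables the
    gate ("no attention"), ``char_encoder="none"`` removes character
    features, ``char_encoder="lstm"`` swaps the CNN for a char BiLSTM.
    """

    word_dim: int = 48
    char_dim: int = 24
    char_filters: int | None = None       # per kernel width; default derived
    char_lstm_hidden: int | None = None   # default derived from word_dim
    gate_hidden: int = 32
    lstm_hidden: int = 48
    combiner: str = "gate"
    char_encoder: str = "cnn"
    batch_size: int = 20
    optimizer: str = "adadelta"
    lr: float = 1.0
    adadelta_rho: float = 0.95
    adadelta_eps: float = 1e-6
    gradient_clip: float = 5.0
    dropout: float = 0.5
    batch_norm: bool = False
    max_epochs: int = 50
    early_stopping: bool = False
    patience: int = 5
    scalar_gate: bool = False
    max_word_len: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.combiner not in _COMBINERS:
            raise ValueError(f"combiner must be one of {_COMBINERS}")
        if self.char_encoder not in _CHAR_ENCODERS:
            raise ValueError(f"char_encoder must be one of {_CHAR_ENCODERS}")
        if self.optimizer not in ("adadelta", "sgd"):
            raise ValueError("optimizer must be 'adadelta' or 'sgd'")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.gradient_clip <= 0:
            raise ValueError("gradient_clip must be positive")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be >= 1")
        if self.char_filters is None:
            self.char_filters = (
                self.word_dim // 3 if self.combiner == "gate" else 16
            )
        if self.char_lstm_hidden is None:
            self.char_lstm_hidden = (
                self.word_dim // 2 if self.combiner == "gate" else 16
            )
        if self.combiner == "gate" and self.char_encoder == "cnn":
            if 3 * self.char_filters != self.word_dim:
                raise ValueError(
                    "gate combiner needs char output dim == word_dim; set "
                    "char_filters = word_dim / 3"
                )
        if self.combiner == "gate" and self.char_encoder == "lstm":
            if 2 * self.char_lstm_hidden != self.word_dim:
                raise ValueError(
                    "gate combiner needs char output dim == word_dim; set "
                    "char_lstm_hidden = word_dim / 2"
                )

    @classmethod
    def from_dict(cls, data: dict) -> "TrainConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown TrainConfig keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


class _Network:
    """All layers and parameters of one tagger instance."""

    def __init__(self, config: TrainConfig, vocab: Vocab,
                 rng: np.random.Generator):
        self.config = config
        self.vocab = vocab
        n_tags = len(vocab.tag_to_index)
        self.word_emb = Embedding(len(vocab.word_to_index), config.word_dim,
                                  rng, name="word_emb")
        self.char_emb = None
        self.char_cnn = None
        self.char_fwd = self.char_bwd = None
        char_out = 0
        if config.char_encoder != "none":
            self.char_emb = Embedding(len(vocab.char_to_index), config.char_dim,
                                      rng, name="char_emb")
        if config.char_encoder == "cnn":
            self.char_cnn = CharCnn(config.char_dim, config.char_filters, rng)
            char_out = self.char_cnn.out_dim
        elif config.char_encoder == "lstm":
            self.char_fwd = Lstm(config.char_dim, config.char_lstm_hidden, rng,
                                 name="char_lstm.fwd")
            self.char_bwd = Lstm(config.char_dim, config.char_lstm_hidden, rng,
                                 name="char_lstm.bwd")
            char_out = 2 * config.char_lstm_hidden

        self.gate = None
        if config.char_encoder == "none":
            lstm_in = config.word_dim
        elif config.combiner == "gate":
            self.gate = Gate(config.word_dim, config.gate_hidden, rng,
                             scalar_gate=config.scalar_gate)
            lstm_in = config.word_dim
        else:
            lstm_in = config.word_dim + char_out

        self.bn_char = (
            BatchNorm(char_out, name="bn_char")
            if config.batch_norm and char_out else None
        )
        self.bilstm = BiLstm(lstm_in, config.lstm_hidden, rng)
        self.emit = Dense(2 * config.lstm_hidden, n_tags, rng, name="emit")
        self.bn_emit = BatchNorm(n_tags, name="bn_emit") if config.batch_norm else None
        self.crf = CrfParams(n_tags)
        self.drop_in = Dropout(config.dropout)
        self.drop_out = Dropout(config.dropout)

    # -- parameter plumbing -------------------------------------------------
    def params(self) -> dict[str, Param]:
        out: dict[str, Param] = {}
        for layer in self._layers():
            out.update(layer.params())
        return out

    def _layers(self):
        layers = [self.word_emb]
        for maybe in (self.char_emb, self.char_cnn, self.char_fwd,
                      self.char_bwd, self.gate, self.bn_char, self.bilstm,
                      self.emit, self.bn_emit, self.crf):
            if maybe is not None:
                layers.append(maybe)
        return layers

    def zero_grad(self) -> None:
        for layer in self._layers():
            layer.zero_grad()

    # -- forward / backward for one sentence --------------------------------
    def forward(self, words: np.ndarray, chars: np.ndarray, train: bool,
                rng: np.random.Generator | None):
        """Emission log-probability rows for one sentence.

        ``words``: (n,) indices; ``chars``: (n, C) indices, zero padded.
        Returns (emissions, cache).
        """
        cfg = self.config
        X = self.word_emb.forward(words)
        cache: dict = {"words": words, "chars": chars, "n": len(words)}

        Cvecs = None
        if cfg.char_encoder == "cnn":
            rows, char_caches = [], []
            for j in range(len(words)):
                Cmat = self.char_emb.forward(chars[j])
                vec, cc = self.char_cnn.forward(Cmat)
                rows.append(vec)
                char_caches.append(cc)
            Cvecs = np.vstack(rows)
            cache["char"] = char_caches
        elif cfg.char_encoder == "lstm":
            rows, char_caches = [], []
            for j in range(len(words)):
                length = int(np.count_nonzero(chars[j])) or 1
                Cmat = self.char_emb.forward(chars[j][:length])
                Hf, cf = self.char_fwd.forward(Cmat)
                Hb, cb = self.char_bwd.forward(Cmat[::-1])
                rows.append(np.concatenate([Hf[-1], Hb[-1]]))
                char_caches.append((length, cf, cb))
            Cvecs = np.vstack(rows)
            cache["char"] = char_caches

        if Cvecs is not None and self.bn_char is not None:
            Cvecs, cache["bn_char"] = self.bn_char.forward(Cvecs, train)

        if cfg.char_encoder == "none":
            combined = X
        elif cfg.combiner == "gate":
            combined, cache["gate"] = self.gate.forward(X, Cvecs)
        else:
            combined = np.concatenate([X, Cvecs], axis=1)

        combined, cache["drop_in"] = self.drop_in.forward(combined, train, rng)
        H, cache["bilstm"] = self.bilstm.forward(combined)
        H, cache["drop_out"] = self.drop_out.forward(H, train, rng)
        S, cache["emit"] = self.emit.forward(H)
        if self.bn_emit is not None:
            S, cache["bn_emit"] = self.bn_emit.forward(S, train)
        # log-softmax rows: the softmax layer feeding the CRF
        S = S - S.max(axis=1, keepdims=True)
        logsum = np.log(np.exp(S).sum(axis=1, keepdims=True))
        emissions = S - logsum
        cache["softmax"] = np.exp(emissions)
        return emissions, cache

    def backward(self, d_emissions: np.ndarray, cache: dict) -> None:
        cfg = self.config
        soft = cache["softmax"]
        dS = d_emissions - soft * d_emissions.sum(axis=1, keepdims=True)
        if self.bn_emit is not None:
            dS = self.bn_emit.backward(dS, cache["bn_emit"])
        dH = self.emit.backward(dS, cache["emit"])
        dH = self.drop_out.backward(dH, cache["drop_out"])
        dcombined = self.bilstm.backward(dH, cache["bilstm"])
        dcombined = self.drop_in.backward(dcombined, cache["drop_in"])

        if cfg.char_encoder == "none":
            dX, dC = dcombined, None
        elif cfg.combiner == "gate":
            dX, dC = self.gate.backward(dcombined, cache["gate"])
        else:
            dX = dcombined[:, : cfg.word_dim]
            dC = dcombined[:, cfg.word_dim :]

        if dC is not None and self.bn_char is not None:
            dC = self.bn_char.backward(dC, cache["bn_char"])

        if cfg.char_encoder == "cnn":
            for j, cc in enumerate(cache["char"]):
                dCmat = self.char_cnn.backward(dC[j], cc)
                self.char_emb.backward(cache["chars"][j], dCmat)
        elif cfg.char_encoder == "lstm":
            h = cfg.char_lstm_hidden
            for j, (length, cf, cb) in enumerate(cache["char"]):
                dHf = np.zeros((length, h)); dHf[-1] = dC[j][:h]
                dHb = np.zeros((length, h)); dHb[-1] = dC[j][h:]
                dCmat = self.char_fwd.backward(dHf, cf)
                dCmat = dCmat + self.char_bwd.backward(dHb, cb)[::-1]
                self.char_emb.backward(cache["chars"][j][:length], dCmat)

        self.word_emb.backward(cache["words"], dX)


class Adadelta:
    """Adadelta updates (accumulated squared gradients and updates)."""

    def __init__(self, params: dict[str, Param], rho: float = 0.95,
                 eps: float = 1e-6, lr: float = 1.0):
        self.rho, self.eps, self.lr = rho, eps, lr
        self.eg2 = {k: np.zeros_like(p.value) for k, p in params.items()}
        self.edx2 = {k: np.zeros_like(p.value) for k, p in params.items()}

    def step(self, params: dict[str, Param]) -> None:
        for k, p in params.items():
            g = p.grad
            self.eg2[k] = self.rho * self.eg2[k] + (1 - self.rho) * g * g
            dx = -np.sqrt(self.edx2[k] + self.eps) / np.sqrt(
                self.eg2[k] + self.eps
            ) * g
            self.edx2[k] = self.rho * self.edx2[k] + (1 - self.rho) * dx * dx
            p.value += self.lr * dx


class Sgd:
    def __init__(self, params: dict[str, Param], lr: float = 0.1):
        self.lr = lr

    def step(self, params: dict[str, Param]) -> None:
        for p in params.values():
            p.value -= self.lr * p.grad


def clip_gradients(params: dict[str, Param], max_norm: float) -> float:
    """Scale all gradients so their global L2 norm is at most ``max_norm``."""
    total = 0.0
    for p in params.values():
        total += float((p.grad * p.grad).sum())
    norm = float(np.sqrt(total))
    if norm > max_norm and norm > 0:
        scale = max_norm / norm
        for p in params.values():
            p.grad *= scale
    return norm


class BiLstmCrfTagger:
    """The tagger model, built from gold-tagged training sequences.

    Parameters
    ----------
    sequences
        Training data (tokens + gold BIO tags).
    config
        :class:`TrainConfig`; defaults reproduce the documented regime.
    vocab
        Optional pre-built vocabulary (otherwise built from ``sequences``).
    pretrained_words, pretrained_chars
        Optional symbol -> vector dicts (word2vec text dialect, see
        :mod:`rannote.model.embeddings`); symbols not covered keep their
        uniform random initialization.
    """

    def __init__(self, sequences: Sequence[TaggedSequence],
                 config: TrainConfig | None = None,
                 vocab: Vocab | None = None,
                 pretrained_words: dict | None = None,
                 pretrained_chars: dict | None = None):
        if not sequences and vocab is None:
            raise ValueError("cannot build a tagger from an empty corpus")
        self.sequences = list(sequences)
        self.config = config or TrainConfig()
        self.vocab = vocab or Vocab.from_sequences(self.sequences)
        ss = np.random.SeedSequence(self.config.seed)
        init_ss, train_ss = ss.spawn(2)
        self.net = _Network(self.config, self.vocab,
                            np.random.default_rng(init_ss))
        self._train_rng = np.random.default_rng(train_ss)
        if pretrained_words:
            self.net.word_emb.load_pretrained(
                pretrained_words, self.vocab.word_to_index
            )
        if pretrained_chars and self.net.char_emb is not None:
            self.net.char_emb.load_pretrained(
                pretrained_chars, self.vocab.char_to_index
            )

    # -- encoding ------------------------------------------------------------
    def _encode(self, sequences: Sequence[TaggedSequence]) -> list[tuple]:
        """Per-sentence (words, chars, tags) index arrays via the batch encoder."""
        rows = []
        for batch in encode_batch(sequences, self.vocab, batch_size=1,
                                  max_word_len=self.config.max_word_len):
            m = batch.mask[0]
            rows.append((batch.words[0][m], batch.chars[0][m], batch.tags[0][m]))
        return rows

    # -- core per-sentence computations --------------------------------------
    def emissions(self, words: np.ndarray, chars: np.ndarray) -> np.ndarray:
        """Log-softmax emission rows for an encoded sentence (eval mode)."""
        E, _ = self.net.forward(words, chars, train=False, rng=None)
        return E

    def _sentence_loss_grad(self, words, chars, tags) -> float:
        E, cache = self.net.forward(words, chars, train=True, rng=self._train_rng)
        nll, dE = crf_mod.crf_nll_grad(E, tags, self.net.crf)
        self.net.backward(dE, cache)
        return nll

    def sentence_nll(self, words, chars, tags) -> float:
        E, _ = self.net.forward(words, chars, train=False, rng=None)
        return -crf_mod.crf_log_likelihood(E, tags, self.net.crf)

    # -- fitting --------------------------------------------------------------
    def fit(self, dev: Sequence[TaggedSequence] | None = None,
            verbose: bool = False) -> "TaggerResults":
        cfg = self.config
        if not self.sequences:
            raise ValueError("cannot fit on an empty corpus")
        if cfg.early_stopping and not dev:
            raise ValueError("early stopping requires a development set")
        encoded = self._encode(self.sequences)
        params = self.net.params()
        if cfg.optimizer == "adadelta":
            opt = Adadelta(params, cfg.adadelta_rho, cfg.adadelta_eps, cfg.lr)
        else:
            opt = Sgd(params, cfg.lr)

        history: list[dict] = []
        best_f = -1.0
        best_values: dict[str, np.ndarray] | None = None
        best_epoch = -1
        stall = 0
        for epoch in range(cfg.max_epochs):
            order = self._train_rng.permutation(len(encoded))
            total = 0.0
            for lo in range(0, len(order), cfg.batch_size):
                idx = order[lo : lo + cfg.batch_size]
                self.net.zero_grad()
                for i in idx:
                    words, chars, tags = encoded[i]
                    total += self._sentence_loss_grad(words, chars, tags)
                # mean over the batch, then clip by global norm
                for p in params.values():
                    p.grad /= len(idx)
                clip_gradients(params, cfg.gradient_clip)
                opt.step(params)
            row = {"epoch": epoch, "loss": total / len(encoded)}
            if dev:
                from ..evaluation import conll_evaluate

                pred = self.predict(dev)
                row["dev_f"] = conll_evaluate(list(dev), pred).overall_f
                if row["dev_f"] > best_f:
                    best_f = row["dev_f"]
                    best_epoch = epoch
                    best_values = {k: p.value.copy() for k, p in params.items()}
                    stall = 0
                else:
                    stall += 1
            history.append(row)
            if verbose:  # pragma: no cover - logging only
                print(f"epoch {epoch}: " + " ".join(
                    f"{k}={v:.4f}" for k, v in row.items() if k != "epoch"))
            if cfg.early_stopping and stall > cfg.patience:
                break
        if cfg.early_stopping and best_values is not None:
            for k, p in params.items():
                p.value[...] = best_values[k]
        return TaggerResults(self, pd.DataFrame(history), best_epoch)

    # -- prediction -----------------------------------------------------------
    def predict(self, sequences: Sequence[TaggedSequence]) -> list[TaggedSequence]:
        """Viterbi-decode BIO tags for each sentence (gold tags ignored)."""
        tags_list = self.vocab.tags
        out = []
        for batch in encode_batch(sequences, self.vocab, batch_size=1,
                                  max_word_len=self.config.max_word_len):
            m = batch.mask[0]
            seq = batch.sequences[0]
            if not m.any():
                out.append(TaggedSequence(seq.text, [], [], seq.doc_id, seq.offset))
                continue
            E = self.emissions(batch.words[0][m], batch.chars[0][m])
            path, _ = viterbi_decode(E, self.net.crf)
            out.append(
                TaggedSequence(
                    seq.text, seq.tokens, [tags_list[i] for i in path],
                    seq.doc_id, seq.offset,
                )
            )
        return out


@dataclass
class TaggerResults:
    """Fitted tagger: parameters, training history and helpers."""

    model: BiLstmCrfTagger
    history: pd.DataFrame
    best_epoch: int = -1

    @property
    def final_loss(self) -> float:
        return float(self.history["loss"].iloc[-1])

    def predict(self, sequences: Sequence[TaggedSequence]) -> list[TaggedSequence]:
        return self.model.predict(sequences)

    def evaluate(self, gold: Sequence[TaggedSequence]):
        from ..evaluation import conll_evaluate

        return conll_evaluate(list(gold), self.predict(gold))

    def summary(self) -> str:
        cfg = self.model.config
        n_params = sum(p.value.size for p in self.model.net.params().values())
        lines = [
            "BiLSTM-CRF tagger results",
            "=" * 41,
            f"training sentences     {len(self.model.sequences):>10d}",
            f"vocabulary (words)     {len(self.model.vocab.word_to_index):>10d}",
            f"tags                   {len(self.model.vocab.tag_to_index):>10d}",
            f"parameters             {n_params:>10d}",
            f"combiner / char enc    {cfg.combiner:>6s} / {cfg.char_encoder}",
            f"optimizer              {cfg.optimizer:>10s}",
            f"epochs run             {len(self.history):>10d}",
            f"final train NLL        {self.final_loss:>10.4f}",
        ]
        if "dev_f" in self.history:
            lines.append(
                f"best dev entity F      {self.history['dev_f'].max():>10.2f}"
                f"  (epoch {self.best_epoch})"
            )
        return "\n".join(lines)

    # -- checkpointing --------------------------------------------------------
    def save(self, path: str | Path) -> None:
        save_checkpoint(self.model, path, history=self.history)

    @staticmethod
    def load(path: str | Path) -> "TaggerResults":
        model, history = load_checkpoint(path)
        return TaggerResults(model, history)


def save_checkpoint(model: BiLstmCrfTagger, path: str | Path,
                    history: pd.DataFrame | None = None) -> None:
    """Write a self-describing archive: config, vocab and all tensors."""
    arrays = {f"param/{k}": p.value for k, p in model.net.params().items()}
    for bn_name in ("bn_char", "bn_emit"):
        bn = getattr(model.net, bn_name)
        if bn is not None:
            arrays[f"state/{bn_name}.mean"] = bn.running_mean
            arrays[f"state/{bn_name}.var"] = bn.running_var
    meta = {
        "config": model.config.to_dict(),
        "history": history.to_dict(orient="list") if history is not None else None,
    }
    np.savez(
        path,
        __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        __vocab__=np.frombuffer(model.vocab.to_text().encode(), dtype=np.uint8),
        **arrays,
    )


def load_checkpoint(path: str | Path) -> tuple[BiLstmCrfTagger, pd.DataFrame]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        vocab = Vocab.from_text(bytes(data["__vocab__"]).decode())
        config = TrainConfig.from_dict(meta["config"])
        model = BiLstmCrfTagger([], config=config, vocab=vocab)
        params = model.net.params()
        for key in data.files:
            if key.startswith("param/"):
                name = key[6:]
                if name not in params:
                    raise ValueError(f"checkpoint has unknown parameter {name!r}")
                params[name].value[...] = data[key]
            elif key.startswith("state/"):
                bn_name, stat = key[6:].split(".")
                bn = getattr(model.net, bn_name)
                if stat == "mean":
                    bn.running_mean[...] = data[key]
                else:
                    bn.running_var[...] = data[key]
    history = pd.DataFrame(meta["history"]) if meta["history"] else pd.DataFrame()
    return model, history


@dataclass
class CrossValidationResult:
    """Pooled (micro-averaged) scores over all folds plus per-fold detail."""

    report: "object"           # EvalReport
    fold_losses: list[float] = field(default_factory=list)

    @property
    def micro_f(self) -> float:
        return self.report.overall_f


def cross_validate(documents, config: TrainConfig | None = None, k: int = 10,
                   segmenter=None, seed: int | None = None,
                   ) -> CrossValidationResult:
    """Document-level k-fold cross-validation, scored once over pooled folds.

    Folds are split at document level so no document contributes sentences
    to both training and test.  Every document is predicted exactly once;
    the pooled predictions are scored in a single micro-averaged evaluation.
    """
    from sklearn.model_selection import KFold

    from ..evaluation import conll_evaluate
    from ..pipeline import CharSegmenter, document_to_sequences

    documents = list(documents)
    config = config or TrainConfig()
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(documents) < k:
        raise ValueError(f"{len(documents)} documents cannot fill {k} folds")
    segmenter = segmenter or CharSegmenter()

    doc_seqs = [document_to_sequences(d, segmenter) for d in documents]
    gold_all: list[TaggedSequence] = []
    pred_all: list[TaggedSequence] = []
    fold_losses: list[float] = []
    splitter = KFold(n_splits=k, shuffle=True,
                     random_state=config.seed if seed is None else seed)
    for train_idx, test_idx in splitter.split(documents):
        train_seqs = [s for i in train_idx for s in doc_seqs[i]]
        test_seqs = [s for i in test_idx for s in doc_seqs[i]]
        model = BiLstmCrfTagger(train_seqs, config=config)
        results = model.fit()
        fold_losses.append(results.final_loss)
        gold_all.extend(test_seqs)
        pred_all.extend(results.predict(test_seqs))
    return CrossValidationResult(conll_evaluate(gold_all, pred_all), fold_losses)
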