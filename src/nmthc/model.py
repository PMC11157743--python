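"""The encoder–decoder network and its training loop.

A bidirectional LSTM encoder consumes the reversed, framed source sentence
and hands its final hidden and cell states (the context) directly to the
decoder as initial state. The decoder is a forward LSTM whose state width
equals the concatenated bidirectional encoder state, followed by a dense
softmax layer over the closed vocabulary. Training is teacher-forced with a
categorical cross-entropy that is masked at <UNK> padding positions, Adam
(or RMSProp) with gradient clipping, and early stopping on validation loss.

Everything here — forward pass, backpropagation through time, and the
optimizers — is implemented directly on numpy arrays; the network is small
(|V| = 5^k + 3) and dense matmuls on one-hot rows are all it needs.
"""

from __future__ import annotations

import copy
import csv
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import yaml

from .corpus import CorpusSplit, SentencePair
from .tokenizer import OneHotBatch, Vocabulary, encode_one_hot, pad_batch, prepare_sentence, tokenize

log = logging.getLogger(__name__)


@dataclass
class ModelConfig:
    k: int = 3
    hidden_units: int = 256  # per direction
    bidirectional_encoder: bool = True
    batch_size: int = 64
    learning_rate: float = 0.1
    optimizer: str = "adam"
    max_epochs: int = 200
    patience: int = 5
    #: early-stopping quantity: "loss" (training loss, the default — training
    #: is cut off when the loss stops decreasing) or "val_loss"
    monitor: str = "loss"
    seed: int = 0
    grad_clip: float = 5.0

    def __post_init__(self) -> None:
        if self.hidden_units < 1 or self.batch_size < 1 or self.patience < 1:
            raise ValueError("hidden_units, batch_size and patience must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.optimizer not in ("adam", "rmsprop"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.monitor not in ("loss", "val_loss"):
            raise ValueError(f"unknown early-stopping monitor {self.monitor!r}")

    @property
    def decoder_units(self) -> int:
        return 2 * self.hidden_units if self.bidirectional_encoder else self.hidden_units


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    stopped_epoch: int = 0
    best_epoch: int = 0

    def save_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["epoch", "train_loss", "train_acc", "val_loss", "val_acc"])
            for i in range(len(self.train_loss)):
                w.writerow(
                    [i + 1, self.train_loss[i], self.train_acc[i],
                     self.val_loss[i], self.val_acc[i]]
                )


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=(fan_in, fan_out))


def _init_lstm(rng: np.random.Generator, d_in: int, h: int) -> dict[str, np.ndarray]:
    b = np.zeros(4 * h)
    b[h : 2 * h] = 1.0  # forget-gate bias
    return {"Wx": _glorot(rng, d_in, 4 * h), "Wh": _glorot(rng, h, 4 * h), "b": b}


def _lstm_forward(X, Wx, Wh, b, h0, c0):
    """Run an LSTM over X (B,T,D); returns all hidden/cell states + cache."""
    B, T, _ = X.shape
    H = Wh.shape[0]
    Hs = np.empty((B, T, H))
    Cs = np.empty((B, T, H))
    G = np.empty((B, T, 4 * H))
    pre = X @ Wx + b
    h, c = h0, c0
    for t in range(T):
        a = pre[:, t] + h @ Wh
        i = _sigmoid(a[:, :H])
        f = _sigmoid(a[:, H : 2 * H])
        g = np.tanh(a[:, 2 * H : 3 * H])
        o = _sigmoid(a[:, 3 * H :])
        c = f * c + i * g
        h = o * np.tanh(c)
        G[:, t, :H], G[:, t, H : 2 * H] = i, f
        G[:, t, 2 * H : 3 * H], G[:, t, 3 * H :] = g, o
        Hs[:, t], Cs[:, t] = h, c
    return Hs, Cs, (X, G, Hs, Cs, h0, c0, Wx, Wh)


def _lstm_backward(cache, dHs, dCs):
    """BPTT given upstream gradients on every hidden (dHs) and cell (dCs) state.

    Returns parameter gradients plus the gradients flowing out of the
    initial state (dh0, dc0).
    """
    X, G, Hs, Cs, h0, c0, Wx, Wh = cache
    B, T, _ = X.shape
    H = Wh.shape[0]
    dWx = np.zeros_like(Wx)
    dWh = np.zeros_like(Wh)
    db = np.zeros(4 * H)
    dh_next = np.zeros((B, H))
    dc_next = np.zeros((B, H))
    for t in range(T - 1, -1, -1):
        i = G[:, t, :H]
        f = G[:, t, H : 2 * H]
        g = G[:, t, 2 * H : 3 * H]
        o = G[:, t, 3 * H :]
        c = Cs[:, t]
        c_prev = Cs[:, t - 1] if t > 0 else c0
        h_prev = Hs[:, t - 1] if t > 0 else h0
        tanh_c = np.tanh(c)
        dh = dHs[:, t] + dh_next
        do = dh * tanh_c
        dc = dh * o * (1.0 - tanh_c**2) + dc_next + dCs[:, t]
        da = np.concatenate(
            [
                dc * g * i * (1.0 - i),
                dc * c_prev * f * (1.0 - f),
                dc * i * (1.0 - g * g),
                do * o * (1.0 - o),
            ],
            axis=1,
        )
        dWx += X[:, t].T @ da
        dWh += h_prev.T @ da
        db += da.sum(axis=0)
        dh_next = da @ Wh.T
        dc_next = dc * f
    return dWx, dWh, db, dh_next, dc_next


def _reverse_within_lengths(X: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Reverse each sequence's first ``lengths[i]`` steps; padding stays put."""
    B, T, _ = X.shape
    idx = np.tile(np.arange(T), (B, 1))
    content = idx < lengths[:, None]
    idx = np.where(content, lengths[:, None] - 1 - idx, idx)
    return X[np.arange(B)[:, None], idx]


class Seq2SeqModel:
    """Parameter container with forward/backward passes."""

    def __init__(self, config: ModelConfig, vocab: Vocabulary,
                 params: dict[str, np.ndarray] | None = None):
        if vocab.k != config.k:
            raise ValueError("vocabulary k does not match config k")
        self.config = config
        self.vocab = vocab
        V = len(vocab)
        H = config.hidden_units
        D = config.decoder_units
        if params is not None:
            self.params = params
        else:
            rng = np.random.default_rng(config.seed)
            self.params = {}
            for name, d_in, h in [("enc_f", V, H)] + (
                [("enc_b", V, H)] if config.bidirectional_encoder else []
            ):
                for pname, arr in _init_lstm(rng, d_in, h).items():
                    self.params[f"{name}_{pname}"] = arr
            for pname, arr in _init_lstm(rng, V, D).items():
                self.params[f"dec_{pname}"] = arr
            self.params["out_W"] = _glorot(rng, D, V)
            self.params["out_b"] = np.zeros(V)
        if self.params["out_W"].shape[1] != V:
            raise ValueError("output projection width does not match vocabulary size")

    # -- forward ---------------------------------------------------------
    def encode(self, X: np.ndarray, lengths: np.ndarray):
        """Final encoder states gathered at each sequence's content length."""
        p = self.params
        B = X.shape[0]
        H = self.config.hidden_units
        zeros = np.zeros((B, H))
        rows = np.arange(B)
        Hs_f, Cs_f, cache_f = _lstm_forward(
            X, p["enc_f_Wx"], p["enc_f_Wh"], p["enc_f_b"], zeros, zeros
        )
        hf, cf = Hs_f[rows, lengths - 1], Cs_f[rows, lengths - 1]
        if self.config.bidirectional_encoder:
            Xr = _reverse_within_lengths(X, lengths)
            Hs_b, Cs_b, cache_b = _lstm_forward(
                Xr, p["enc_b_Wx"], p["enc_b_Wh"], p["enc_b_b"], zeros, zeros
            )
            hb, cb = Hs_b[rows, lengths - 1], Cs_b[rows, lengths - 1]
            h0 = np.concatenate([hf, hb], axis=1)
            c0 = np.concatenate([cf, cb], axis=1)
            return h0, c0, (cache_f, cache_b, lengths)
        return hf, cf, (cache_f, None, lengths)

    def forward(self, batch: OneHotBatch):
        """Teacher-forced forward pass; returns logits and caches."""
        h0, c0, enc_cache = self.encode(batch.encoder_input, batch.src_lengths)
        Hs, _, dec_cache = _lstm_forward(
            batch.decoder_input,
            self.params["dec_Wx"],
            self.params["dec_Wh"],
            self.params["dec_b"],
            h0,
            c0,
        )
        logits = Hs @ self.params["out_W"] + self.params["out_b"]
        return logits, (enc_cache, dec_cache, Hs)

    def backward(self, batch: OneHotBatch, logits, caches) -> dict[str, np.ndarray]:
        """Gradients of the masked mean cross-entropy w.r.t. all parameters."""
        enc_cache, dec_cache, Hs = caches
        cache_f, cache_b, lengths = enc_cache
        p = self.params
        B, T, V = logits.shape
        probs = _softmax(logits)
        n = max(batch.loss_mask.sum(), 1.0)
        dlogits = probs
        rows, cols = np.meshgrid(np.arange(B), np.arange(T), indexing="ij")
        dlogits[rows, cols, batch.decoder_labels] -= 1.0
        dlogits *= batch.loss_mask[..., None] / n

        grads = {
            "out_W": np.einsum("btd,btv->dv", Hs, dlogits),
            "out_b": dlogits.sum(axis=(0, 1)),
        }
        dHs_dec = dlogits @ p["out_W"].T
        dCs_dec = np.zeros((B, T, self.config.decoder_units))
        dWx, dWh, db, dh0, dc0 = _lstm_backward(dec_cache, dHs_dec, dCs_dec)
        grads["dec_Wx"], grads["dec_Wh"], grads["dec_b"] = dWx, dWh, db

        H = self.config.hidden_units
        Tsrc = batch.encoder_input.shape[1]
        br = np.arange(B)
        dHs = np.zeros((B, Tsrc, H))
        dCs = np.zeros((B, Tsrc, H))
        dHs[br, lengths - 1] = dh0[:, :H]
        dCs[br, lengths - 1] = dc0[:, :H]
        dWx, dWh, db, _, _ = _lstm_backward(cache_f, dHs, dCs)
        grads["enc_f_Wx"], grads["enc_f_Wh"], grads["enc_f_b"] = dWx, dWh, db
        if self.config.bidirectional_encoder:
            dHs = np.zeros((B, Tsrc, H))
            dCs = np.zeros((B, Tsrc, H))
            dHs[br, lengths - 1] = dh0[:, H:]
            dCs[br, lengths - 1] = dc0[:, H:]
            dWx, dWh, db, _, _ = _lstm_backward(cache_b, dHs, dCs)
            grads["enc_b_Wx"], grads["enc_b_Wh"], grads["enc_b_b"] = dWx, dWh, db
        return grads

    def decoder_step(self, x_ids: np.ndarray, h: np.ndarray, c: np.ndarray):
        """One autoregressive decoder step for a batch of token ids."""
        p = self.params
        V = len(self.vocab)
        X = np.zeros((x_ids.shape[0], 1, V))
        X[np.arange(x_ids.shape[0]), 0, x_ids] = 1.0
        Hs, Cs, _ = _lstm_forward(X, p["dec_Wx"], p["dec_Wh"], p["dec_b"], h, c)
        probs = _softmax(Hs[:, 0] @ p["out_W"] + p["out_b"])
        return probs, Hs[:, 0], Cs[:, 0]


@dataclass
class TrainedModel:
    """Checkpointable bundle of network parameters, vocabulary and config."""

    network: Seq2SeqModel

    @property
    def vocab(self) -> Vocabulary:
        return self.network.vocab

    @property
    def config(self) -> ModelConfig:
        return self.network.config

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        np.savez(out / "weights.npz", **self.network.params)
        self.vocab.save(out / "vocab.json")
        (out / "config.yaml").write_text(yaml.safe_dump(asdict(self.config)))

    @classmethod
    def load(cls, in_dir: str | Path) -> "TrainedModel":
        out = Path(in_dir)
        config = ModelConfig(**yaml.safe_load((out / "config.yaml").read_text()))
        vocab = Vocabulary.load(out / "vocab.json")
        with np.load(out / "weights.npz") as data:
            params = {k: data[k].copy() for k in data.files}
        if params["out_W"].shape[1] != len(vocab):
            raise ValueError("checkpoint output projection does not match vocabulary")
        return cls(network=Seq2SeqModel(config, vocab, params=params))


# ---------------------------------------------------------------------------
# loss / metrics

def masked_loss(predicted_distributions: np.ndarray, label_ids: np.ndarray,
                loss_mask: np.ndarray) -> float:
    """Mean −log p(label) over unmasked positions; 0 if everything is masked."""
    B, T, _ = predicted_distributions.shape
    rows, cols = np.meshgrid(np.arange(B), np.arange(T), indexing="ij")
    p = predicted_distributions[rows, cols, label_ids]
    mask = loss_mask.astype(bool)
    if not mask.any():
        return 0.0
    if np.any(p[mask] <= 0):
        raise FloatingPointError("zero probability assigned to an unmasked label")
    return float(-np.log(p[mask]).mean())


def _masked_loss_acc_from_logits(logits, labels, mask) -> tuple[float, float, float]:
    """(summed nll, n correct, n unmasked) for running averages."""
    probs = _softmax(logits)
    B, T, _ = logits.shape
    rows, cols = np.meshgrid(np.arange(B), np.arange(T), indexing="ij")
    p = probs[rows, cols, labels]
    m = mask.astype(bool)
    nll = float(-np.log(np.maximum(p[m], 1e-300)).sum())
    correct = float((np.argmax(logits, axis=-1) == labels)[m].sum())
    return nll, correct, float(m.sum())


# ---------------------------------------------------------------------------
# data generator

def make_batches(
    pairs: Sequence[SentencePair], vocab: Vocabulary, config: ModelConfig
) -> Iterator[OneHotBatch]:
    """Yield one-hot batches in stable corpus order (sequential partition).

    Each batch is padded to its own maximum sentence length and only one
    batch is materialized at a time.
    """
    if not pairs:
        raise ValueError("empty split: nothing to batch")
    for lo in range(0, len(pairs), config.batch_size):
        chunk = pairs[lo : lo + config.batch_size]
        sources, targets = [], []
        for pair in chunk:
            sources.append(
                prepare_sentence(tokenize(pair.source, config.k), "source", vocab, pair.read_id)
            )
            targets.append(
                prepare_sentence(tokenize(pair.target, config.k), "target", vocab, pair.read_id)
            )
        pad_src = max(s.content_len for s in sources)
        pad_tgt = max(t.content_len for t in targets)
        yield encode_one_hot(
            pad_batch(sources, pad_src, vocab), pad_batch(targets, pad_tgt, vocab), vocab
        )


# ---------------------------------------------------------------------------
# optimizers

class _Adam:
    def __init__(self, params: dict, lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for k in params:
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class _RMSProp:
    def __init__(self, params: dict, lr: float):
        self.lr = lr
        self.rho, self.eps = 0.9, 1e-8
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict, grads: dict) -> None:
        for k in params:
            g = grads[k]
            self.v[k] = self.rho * self.v[k] + (1 - self.rho) * g * g
            params[k] -= self.lr * g / (np.sqrt(self.v[k]) + self.eps)


def _clip_grads(grads: dict, max_norm: float) -> None:
    total = np.sqrt(sum(float((g * g).sum()) for g in grads.values()))
    if total > max_norm > 0:
        scale = max_norm / total
        for g in grads.values():
            g *= scale


# ---------------------------------------------------------------------------
# training

def _split_metrics(model: Seq2SeqModel, pairs, config) -> tuple[float, float]:
    nll = correct = n = 0.0
    for batch in make_batches(pairs, model.vocab, config):
        logits, _ = model.forward(batch)
        b_nll, b_correct, b_n = _masked_loss_acc_from_logits(
            logits, batch.decoder_labels, batch.loss_mask
        )
        nll += b_nll
        correct += b_correct
        n += b_n
    if n == 0:
        warnings.warn("all label positions masked; metrics defined as 0")
        return 0.0, 0.0
    return nll / n, correct / n


def train(
    corpus: CorpusSplit,
    config: ModelConfig,
    initial_model: TrainedModel | None = None,
    learning_rate: float | None = None,
) -> tuple[TrainedModel, TrainHistory]:
    """Teacher-forced training with early stopping on validation loss.

    Training stops when the monitored loss (training loss by default,
    validation loss with ``config.monitor == "val_loss"``) has not improved
    for ``config.patience`` epochs; the best-epoch weights are restored.
    ``initial_model`` warm-starts the parameters (transfer learning);
    ``learning_rate`` overrides the config rate for this run. With an empty
    validation split, training loss is always the monitored quantity.
    """
    if not corpus.train:
        raise ValueError("empty train split")
    vocab = initial_model.vocab if initial_model else Vocabulary(config.k)
    if initial_model is not None:
        params = {k: v.copy() for k, v in initial_model.network.params.items()}
        model = Seq2SeqModel(config, vocab, params=params)
    else:
        model = Seq2SeqModel(config, vocab)
    lr = config.learning_rate if learning_rate is None else learning_rate
    opt = (_Adam if config.optimizer == "adam" else _RMSProp)(model.params, lr)

    history = TrainHistory()
    best_loss = np.inf
    best_params = None
    have_val = bool(corpus.validation)
    monitor_val = config.monitor == "val_loss" and have_val
    if config.monitor == "val_loss" and not have_val:
        log.warning("no validation split; early stopping monitors training loss")

    for epoch in range(1, config.max_epochs + 1):
        nll = correct = n = 0.0
        for batch in make_batches(corpus.train, vocab, config):
            logits, caches = model.forward(batch)
            b_nll, b_correct, b_n = _masked_loss_acc_from_logits(
                logits, batch.decoder_labels, batch.loss_mask
            )
            nll += b_nll
            correct += b_correct
            n += b_n
            grads = model.backward(batch, logits, caches)
            _clip_grads(grads, config.grad_clip)
            opt.step(model.params, grads)
        train_loss = nll / max(n, 1.0)
        history.train_loss.append(train_loss)
        history.train_acc.append(correct / max(n, 1.0))
        if have_val:
            val_loss, val_acc = _split_metrics(model, corpus.validation, config)
        else:
            val_loss, val_acc = train_loss, history.train_acc[-1]
        history.val_loss.append(val_loss)
        history.val_acc.append(val_acc)

        monitored = val_loss if monitor_val else train_loss
        if monitored < best_loss:
            best_loss = monitored
            history.best_epoch = epoch
            best_params = {k: v.copy() for k, v in model.params.items()}
        history.stopped_epoch = epoch
        if epoch - history.best_epoch >= config.patience:
            break

    if best_params is not None:
        model.params = best_params
    return TrainedModel(network=model), history


def evaluate_token_accuracy(
    model: TrainedModel, pairs: Sequence[SentencePair]
) -> float:
    """Fraction of unmasked label positions predicted correctly
    (teacher forcing)."""
    if not pairs:
        raise ValueError("empty split")
    _, acc = _split_metrics(model.network, pairs, model.config)
    return acc
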