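"""k-mer tokenization, the closed vocabulary, and one-hot encoding.

Filled sequences over {A,C,G,T,$} are cut into adjacent, non-overlapping
k-mers (no sliding window — the recurrent model is expected to learn the
context across token boundaries itself). The vocabulary is always the full
5^k k-mer set plus the three specials <s>, </s>, <UNK>, so its size — and
with it the dense output layer — is fixed for a given k, which is what lets
transfer-learning stages share parameters. Tokens are fed to the network as
one-hot rows; no embedding layer is used.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

ALPHABET = "ACGT$"
START = "<s>"
END = "</s>"
PAD = "<UNK>"
SPECIALS = (START, END, PAD)


@dataclass(frozen=True)
class Vocabulary:
    """All 5^k k-mers in lexicographic order, then <s>, </s>, <UNK>."""

    k: int
    tokens: tuple[str, ...] = field(init=False)
    index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        kmers = ["".join(p) for p in itertools.product(sorted(ALPHABET), repeat=self.k)]
        object.__setattr__(self, "tokens", tuple(kmers) + SPECIALS)
        object.__setattr__(
            self, "index", {tok: i for i, tok in enumerate(self.tokens)}
        )

    def __len__(self) -> int:
        return 5**self.k + 3

    @property
    def start_id(self) -> int:
        return self.index[START]

    @property
    def end_id(self) -> int:
        return self.index[END]

    @property
    def pad_id(self) -> int:
        return self.index[PAD]

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"k": self.k, "tokens": list(self.tokens)}))

    @classmethod
    def load(cls, path: str | Path) -> "Vocabulary":
        data = json.loads(Path(path).read_text())
        vocab = cls(k=data["k"])
        if list(vocab.tokens) != data["tokens"]:
            raise ValueError("stored vocabulary order does not match the closed set")
        return vocab


@dataclass
class TokenSequence:
    read_id: str
    token_ids: list[int]
    reversed: bool
    content_len: int  # number of non-<UNK> tokens


@dataclass
class OneHotBatch:
    """One training batch: one-hot inputs, shifted labels, and loss mask."""

    encoder_input: np.ndarray  # B x T_src x |V|
    decoder_input: np.ndarray  # B x T_tgt x |V|
    decoder_labels: np.ndarray  # B x T_tgt (token ids)
    loss_mask: np.ndarray  # B x T_tgt in {0,1}
    src_lengths: np.ndarray  # B, content lengths of the encoder input
    read_ids: list[str]


def tokenize(seq: str, k: int) -> list[str]:
    """Cut into non-overlapping k-mers; a short tail is '$'-padded to k."""
    if k < 1:
        raise ValueError("k must be >= 1")
    bad = set(seq) - set(ALPHABET)
    if bad:
        raise ValueError(f"characters outside {{A,C,G,T,$}}: {sorted(bad)}")
    tokens = [seq[i : i + k] for i in range(0, len(seq), k)]
    if tokens and len(tokens[-1]) < k:
        tokens[-1] = tokens[-1].ljust(k, "$")
    return tokens


def detokenize(tokens: Sequence[str]) -> str:
    """Concatenate k-mers back into a sequence; specials are rejected."""
    for tok in tokens:
        if tok in SPECIALS:
            raise ValueError(f"special token {tok} in detokenize input")
    return "".join(tokens)


def prepare_sentence(
    tokens: Sequence[str], role: str, vocab: Vocabulary, read_id: str = "?"
) -> TokenSequence:
    """Frame with <s>/</s>; reverse the whole source sentence.

    The source is fed to the encoder back-to-front, so its last token is
    <s> — the same token the decoder starts from, putting the sequence ends
    that meet at the encoder→decoder state handoff next to each other.
    """
    if role not in ("source", "target"):
        raise ValueError(f"role must be source or target, got {role!r}")
    framed = [START] + list(tokens) + [END]
    if role == "source":
        framed = framed[::-1]
    ids = [vocab.index[t] for t in framed]
    return TokenSequence(
        read_id=read_id,
        token_ids=ids,
        reversed=(role == "source"),
        content_len=len(ids),
    )


def pad_batch(sentences: Sequence[TokenSequence], pad_to: int, vocab: Vocabulary) -> list[TokenSequence]:
    """Append <UNK> so every sentence reaches ``pad_to`` tokens."""
    out = []
    for s in sentences:
        if s.content_len > pad_to:
            raise ValueError(
                f"{s.read_id}: sentence of {s.content_len} tokens exceeds pad_to={pad_to}"
            )
        out.append(
            TokenSequence(
                read_id=s.read_id,
                token_ids=s.token_ids[: s.content_len]
                + [vocab.pad_id] * (pad_to - s.content_len),
                reversed=s.reversed,
                content_len=s.content_len,
            )
        )
    return out


def _one_hot(ids: np.ndarray, width: int) -> np.ndarray:
    out = np.zeros(ids.shape + (width,), dtype=np.float32)
    np.put_along_axis(out, ids[..., None], 1.0, axis=-1)
    return out


def encode_one_hot(
    sources: Sequence[TokenSequence],
    targets: Sequence[TokenSequence],
    vocab: Vocabulary,
) -> OneHotBatch:
    """Teacher-forcing tensors for one batch.

    decoder_input is the padded target as-is (starts at <s>); the labels are
    the target shifted one step left (so each step predicts the next token,
    ending at </s> then <UNK> padding). The loss mask is zero exactly where
    the label is <UNK>.
    """
    V = len(vocab)
    for seq in itertools.chain(sources, targets):
        for tid in seq.token_ids:
            if not 0 <= tid < V:
                raise ValueError(f"{seq.read_id}: token id {tid} outside vocabulary")
    src_ids = np.array([s.token_ids for s in sources], dtype=np.int64)
    tgt_ids = np.array([t.token_ids for t in targets], dtype=np.int64)
    labels = np.concatenate(
        [tgt_ids[:, 1:], np.full((len(targets), 1), vocab.pad_id, dtype=np.int64)],
        axis=1,
    )
    return OneHotBatch(
        encoder_input=_one_hot(src_ids, V),
        decoder_input=_one_hot(tgt_ids, V),
        decoder_labels=labels,
        loss_mask=(labels != vocab.pad_id).astype(np.float32),
        src_lengths=np.array([s.content_len for s in sources], dtype=np.int64),
        read_ids=[s.read_id for s in sources],
    )


def decode_one_hot(array: np.ndarray, vocab: Vocabulary) -> list[list[str]]:
    """Invert one-hot encoding by argmax over the vocabulary axis."""
    ids = np.argmax(array, axis=-1)
    return [[vocab.tokens[i] for i in row] for row in ids]
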