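"""Correct long reads with a trained model.

Source sentences are built by the same pileup-consensus placeholder filling
used for training (so the '$' slots for insertions exist at inference);
reads without a single alignment fall back to their raw tokenized bases.
Decoding is batched greedy argmax: the decoder starts from the encoder's
final state, feeds each emitted token back in, keeps one independent hidden
state per sequence, and stops at </s> or at a per-read step cap. Stripping
specials and '$' yields the corrected bases. Every input read yields exactly
one output read with the same id — nothing is trimmed or dropped.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .corpus import build_sentence_pair
from .io_formats import AlignmentRecord, SequenceRecord
from .model import TrainedModel
from .tokenizer import (
    PAD,
    END,
    START,
    TokenSequence,
    encode_one_hot,
    pad_batch,
    prepare_sentence,
    tokenize,
)

log = logging.getLogger(__name__)

#: decode-step margin beyond the source token count (the filled pairs are
#: column-aligned, so target length tracks source length closely)
MAX_STEP_MARGIN = 8


@dataclass
class DecodeResult:
    read_id: str
    predicted_tokens: list[str]
    corrected_bases: str
    terminated_by: str  # "end_token" | "max_steps"


def greedy_decode(
    model: TrainedModel,
    sources: Sequence[TokenSequence],
    max_steps: int | Sequence[int],
) -> list[list[str]]:
    """Batched greedy decoding with one independent state per sequence.

    ``sources`` are prepared (reversed, framed) sentences; ``max_steps`` is
    a cap on emitted tokens, scalar or per sequence. Returns the emitted
    tokens per sequence including the terminating </s> when reached.
    """
    B = len(sources)
    caps = np.full(B, max_steps) if np.isscalar(max_steps) else np.asarray(max_steps)
    if np.any(caps < 1):
        raise ValueError("max_steps must be >= 1")
    net = model.network
    vocab = model.vocab
    pad_to = max(s.content_len for s in sources)
    batch = encode_one_hot(
        pad_batch(sources, pad_to, vocab),
        pad_batch(sources, pad_to, vocab),  # decoder side unused
        vocab,
    )
    h, c, _ = net.encode(batch.encoder_input, batch.src_lengths)
    x = np.full(B, vocab.start_id)
    emitted: list[list[str]] = [[] for _ in range(B)]
    done = np.zeros(B, dtype=bool)
    for _ in range(int(caps.max())):
        probs, h, c = net.decoder_step(x, h, c)
        nxt = np.argmax(probs, axis=1)
        for i in range(B):
            if done[i]:
                continue
            emitted[i].append(vocab.tokens[nxt[i]])
            if nxt[i] == vocab.end_id or len(emitted[i]) >= caps[i]:
                done[i] = True
        if done.all():
            break
        x = nxt
    return emitted


def finalize(predicted_tokens: Sequence[str]) -> str:
    """Strip specials, concatenate k-mers, delete every '$' placeholder."""
    bases = "".join(
        tok for tok in predicted_tokens if tok not in (START, END, PAD)
    ).replace("$", "")
    if not bases:
        log.info("decode produced an empty corrected read")
    return bases


def correct_reads(
    model: TrainedModel,
    long_reads: Sequence[SequenceRecord],
    alignments: Sequence[AlignmentRecord],
    batch_size: int | None = None,
    use_consensus_sources: bool = True,
) -> list[DecodeResult]:
    """Correct every read; ids and order are preserved, nothing is dropped."""
    ids = [r.id for r in long_reads]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate read ids in input")
    k = model.config.k
    vocab = model.vocab
    B = batch_size or model.config.batch_size
    by_read: dict[str, list[AlignmentRecord]] = defaultdict(list)
    for aln in alignments:
        by_read[aln.long_read_id].append(aln)

    results: list[DecodeResult] = []
    for lo in range(0, len(long_reads), B):
        chunk = long_reads[lo : lo + B]
        sources = []
        for read in chunk:
            alns = by_read.get(read.id, [])
            if alns and use_consensus_sources:
                source_seq = build_sentence_pair(read, alns).source
            else:
                source_seq = read.bases
            sources.append(
                prepare_sentence(tokenize(source_seq, k), "source", vocab, read.id)
            )
        caps = [s.content_len + MAX_STEP_MARGIN for s in sources]
        for read, src, tokens, cap in zip(
            chunk, sources, greedy_decode(model, sources, caps), caps
        ):
            results.append(
                DecodeResult(
                    read_id=read.id,
                    predicted_tokens=tokens,
                    corrected_bases=finalize(tokens),
                    terminated_by=(
                        "end_token" if tokens and tokens[-1] == END else "max_steps"
                    ),
                )
            )
    return results


def corrected_records(results: Sequence[DecodeResult]) -> list[SequenceRecord]:
    """DecodeResults as FASTA-ready records (empty decodes become a single
    'A' placeholder-free stub so the record stays writable, logged)."""
    records = []
    for res in results:
        bases = res.corrected_bases
        if not bases:
            log.warning("read %s decoded to an empty sequence", res.read_id)
            bases = "A"
        records.append(SequenceRecord(id=res.read_id, bases=bases))
    return records
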