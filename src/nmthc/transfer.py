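"""Chunked transfer learning.

Long-read corpora are far too large to train on in one pass, but reads
drawn from one genome share structure, so a model pre-trained on one chunk
of reads is a strong warm start for the rest. Reads are hashed by name into
N chunks; the model is trained from scratch on the pre-training chunk, then
each remaining chunk fine-tunes the previous checkpoint at a reduced
learning rate (N − 1 transfer stages). All layers stay trainable in every
stage. The closed 5^k vocabulary keeps the dense output layer's shape
identical across stages, which is what makes the parameter handoff valid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .corpus import CorpusSplit, SentencePair, split_corpus, stable_hash
from .model import ModelConfig, TrainHistory, TrainedModel, train

log = logging.getLogger(__name__)


@dataclass
class ChunkPlan:
    n_chunks: int
    assignment: dict[str, int]

    def chunk_ids(self, chunk: int) -> list[str]:
        return [rid for rid, c in self.assignment.items() if c == chunk]


@dataclass
class TransferSchedule:
    pretrain_chunk: int
    finetune_order: list[int]
    finetune_lr_factor: float
    histories: list[TrainHistory] = field(default_factory=list)


def chunk_by_hash(read_ids: Sequence[str], n_chunks: int, seed: int = 0) -> ChunkPlan:
    """Assign each read to ``stable_hash(seed, id) mod N``; deterministic."""
    if n_chunks < 1:
        raise ValueError("n_chunks must be >= 1")
    if len(set(read_ids)) != len(read_ids):
        raise ValueError("duplicate read ids")
    return ChunkPlan(
        n_chunks=n_chunks,
        assignment={rid: stable_hash(seed, rid) % n_chunks for rid in read_ids},
    )


def _chunk_corpus(
    pairs: Sequence[SentencePair], plan: ChunkPlan, chunk: int, seed: int
) -> CorpusSplit:
    members = [p for p in pairs if plan.assignment[p.read_id] == chunk]
    return split_corpus(members, seed=seed)


def run_transfer(
    corpus: CorpusSplit,
    config: ModelConfig,
    n_chunks: int,
    finetune_lr_factor: float = 0.1,
    checkpoint_dir: str | Path | None = None,
) -> tuple[TrainedModel, TransferSchedule]:
    """Pre-train on chunk 0, then fine-tune through the remaining chunks.

    Chunking is applied to the union of the corpus' train/validation/test
    pairs; each chunk is re-split 80/10/10 internally so every stage has its
    own validation set for early stopping. With ``n_chunks == 1`` this is
    plain training.
    """
    if not 0 < finetune_lr_factor <= 1:
        raise ValueError("finetune_lr_factor must be in (0, 1]")
    pairs = corpus.all_pairs
    if not pairs:
        raise ValueError("empty corpus")
    plan = chunk_by_hash([p.read_id for p in pairs], n_chunks, seed=config.seed)
    schedule = TransferSchedule(
        pretrain_chunk=0,
        finetune_order=list(range(1, n_chunks)),
        finetune_lr_factor=finetune_lr_factor,
    )
    model: TrainedModel | None = None
    for stage, chunk in enumerate([schedule.pretrain_chunk] + schedule.finetune_order):
        stage_corpus = _chunk_corpus(pairs, plan, chunk, seed=config.seed)
        if not stage_corpus.train:
            log.warning("chunk %d is empty; stage skipped", chunk)
            continue
        lr = config.learning_rate if model is None else (
            config.learning_rate * finetune_lr_factor
        )
        model, history = train(
            stage_corpus, config, initial_model=model, learning_rate=lr
        )
        schedule.histories.append(history)
        if checkpoint_dir is not None:
            model.save(Path(checkpoint_dir) / f"stage_{stage}")
    if model is None:
        raise ValueError("every chunk was empty; nothing was trained")
    return model, schedule
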