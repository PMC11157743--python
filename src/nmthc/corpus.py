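"""Parallel-corpus construction from short-read pileups.

One long read plus all short-read alignments onto it become one training
*sentence pair*: a column-aligned (source, target) string pair over
{A,C,G,T,$}. Per-column base/gap votes and per-junction insertion votes are
collected from the extended CIGARs, called by strict majority, and indel
slots are kept column-aligned with the ``'$'`` placeholder — ``'$'`` in the
target marks a base the consensus removes, ``'$'`` in the source marks a
slot where the consensus inserts bases. Stripping ``'$'`` from the source
recovers the raw long read; stripping it from the target yields the
consensus-corrected read.
"""

from __future__ import annotations

import hashlib
import json
from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .io_formats import AlignmentRecord, SequenceRecord, cigar_reference_interval

GAP = "GAP"
PLACEHOLDER = "$"


@dataclass
class PileupColumn:
    pos: int  # 1-based long-read position
    original: str
    votes: Counter  # over {A,C,G,T,GAP}


@dataclass
class JunctionVotes:
    after_pos: int  # insertion follows this 1-based position (0 = before read)
    votes: Counter  # inserted strings; "" = covering read reports no insertion


@dataclass(frozen=True)
class SentencePair:
    read_id: str
    source: str
    target: str
    covered_fraction: float

    def __post_init__(self) -> None:
        if len(self.source) != len(self.target):
            raise ValueError(f"{self.read_id}: source/target lengths differ")
        for s, t in zip(self.source, self.target):
            if s == PLACEHOLDER and t == PLACEHOLDER:
                raise ValueError(f"{self.read_id}: '$' in both source and target")


@dataclass
class CorpusSplit:
    train: list[SentencePair]
    validation: list[SentencePair]
    test: list[SentencePair]

    @property
    def all_pairs(self) -> list[SentencePair]:
        return self.train + self.validation + self.test


def build_pileup(
    long_read: SequenceRecord, alignments: Sequence[AlignmentRecord]
) -> tuple[list[PileupColumn], list[JunctionVotes]]:
    """Collect per-column and per-junction votes from aligned short reads.

    Every M/S op contributes the short read's base at that column, every D
    op a GAP vote. A junction (between ``after_pos`` and ``after_pos + 1``)
    receives one vote per alignment that spans it: the inserted string for
    an I op, or "" when the covering read reports no insertion there.
    """
    L = len(long_read.bases)
    columns = [
        PileupColumn(pos=i + 1, original=long_read.bases[i], votes=Counter())
        for i in range(L)
    ]
    ins_votes: dict[int, Counter] = defaultdict(Counter)
    spanning: dict[int, int] = defaultdict(int)  # junctions covered per alignment

    for aln in alignments:
        if aln.long_read_id != long_read.id:
            raise ValueError(
                f"alignment of {aln.short_read_id} references "
                f"{aln.long_read_id}, not {long_read.id}"
            )
        first, last = cigar_reference_interval(aln.cigar)
        if first < 1 or last > L:
            raise ValueError(
                f"alignment {aln.short_read_id}->{long_read.id} spans "
                f"[{first},{last}] outside [1,{L}]"
            )
        pos = first
        qpos = 0
        trailing_ins = False
        for n, code in aln.cigar.ops:
            if code in ("M", "S"):
                for i in range(n):
                    columns[pos - 1 + i].votes[aln.query_bases[qpos + i]] += 1
                pos += n
                qpos += n
            elif code == "D":
                for i in range(n):
                    columns[pos - 1 + i].votes[GAP] += 1
                pos += n
            else:  # I
                ins_votes[pos - 1][aln.query_bases[qpos : qpos + n]] += 1
                trailing_ins = pos - 1 == last
                qpos += n
        # junctions this alignment spans: between consecutive covered columns,
        # plus the trailing junction when the CIGAR ends with an insertion
        for j in range(first, last):
            spanning[j] += 1
        if trailing_ins:
            spanning[last] += 1

    junctions: list[JunctionVotes] = []
    for after_pos in sorted(set(spanning) | set(ins_votes)):
        votes = Counter(ins_votes.get(after_pos, Counter()))
        n_empty = spanning.get(after_pos, 0) - sum(votes.values())
        if n_empty > 0:
            votes[""] += n_empty
        junctions.append(JunctionVotes(after_pos=after_pos, votes=votes))
    return columns, junctions


def majority_call(votes: Counter, default):
    """Strict-majority winner among votes, or ``default`` on tie/no votes."""
    if not votes:
        return default
    ranked = votes.most_common()
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        return default
    return ranked[0][0]


def call_consensus(
    columns: Sequence[PileupColumn], junctions: Sequence[JunctionVotes]
) -> tuple[list[str], dict[int, str]]:
    """Strict-majority consensus: per-column call in {A,C,G,T,GAP} and
    per-junction inserted string.

    Ties and uncovered columns fall back to the original long-read base;
    junction ties fall back to no insertion.
    """
    column_calls = [majority_call(col.votes, col.original) for col in columns]
    junction_calls = {
        j.after_pos: call
        for j in junctions
        if (call := majority_call(j.votes, "")) != ""
    }
    return column_calls, junction_calls


def fill_placeholders(
    long_read: SequenceRecord,
    column_calls: Sequence[str],
    junction_calls: dict[int, str],
    covered_fraction: float | None = None,
) -> SentencePair:
    """Emit the column-aligned, '$'-filled (source, target) pair."""
    src: list[str] = []
    tgt: list[str] = []
    ins0 = junction_calls.get(0, "")
    if ins0:
        src.append(PLACEHOLDER * len(ins0))
        tgt.append(ins0)
    for i, base in enumerate(long_read.bases):
        call = column_calls[i]
        src.append(base)
        tgt.append(PLACEHOLDER if call == GAP else call)
        ins = junction_calls.get(i + 1, "")
        if ins:
            src.append(PLACEHOLDER * len(ins))
            tgt.append(ins)
    return SentencePair(
        read_id=long_read.id,
        source="".join(src),
        target="".join(tgt),
        covered_fraction=0.0 if covered_fraction is None else covered_fraction,
    )


def build_sentence_pair(
    long_read: SequenceRecord, alignments: Sequence[AlignmentRecord]
) -> SentencePair:
    """Pileup → consensus → placeholder filling for one long read."""
    columns, junctions = build_pileup(long_read, alignments)
    column_calls, junction_calls = call_consensus(columns, junctions)
    covered = sum(1 for col in columns if col.votes) / len(columns)
    return fill_placeholders(long_read, column_calls, junction_calls, covered)


def build_corpus(
    long_reads: Sequence[SequenceRecord],
    alignments: Sequence[AlignmentRecord],
    max_read_len: int | None = None,
) -> list[SentencePair]:
    """One sentence pair per long read, in input order.

    ``max_read_len`` is a training-side cap applied by the caller when
    assembling the train split; this function never drops reads.
    """
    by_read: dict[str, list[AlignmentRecord]] = defaultdict(list)
    for aln in alignments:
        by_read[aln.long_read_id].append(aln)
    pairs = []
    for read in long_reads:
        if max_read_len is not None and len(read.bases) > max_read_len:
            continue
        pairs.append(build_sentence_pair(read, by_read.get(read.id, [])))
    return pairs


def stable_hash(seed: int, name: str) -> int:
    """Seeded, platform-stable hash of a read name (md5-based)."""
    digest = hashlib.md5(f"{seed}:{name}".encode()).digest()
    return int.from_bytes(digest[:8], "big")


def split_corpus(
    pairs: Sequence[SentencePair],
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> CorpusSplit:
    """Hash-shuffle by read name and cut 80/10/10 (train takes the slack)."""
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    ids = [p.read_id for p in pairs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate read_id in corpus")
    order = sorted(pairs, key=lambda p: stable_hash(seed, p.read_id))
    n = len(order)
    n_val = int(n * ratios[1])
    n_test = int(n * ratios[2])
    n_train = n - n_val - n_test
    return CorpusSplit(
        train=order[:n_train],
        validation=order[n_train : n_train + n_val],
        test=order[n_train + n_val :],
    )


# ---------------------------------------------------------------------------
# serialization: two-column TSV + JSON sidecar

def save_corpus(split: CorpusSplit, out_dir: str | Path, k: int) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    membership = {}
    with open(out / "corpus.tsv", "w") as fh:
        for name, pairs in (
            ("train", split.train),
            ("validation", split.validation),
            ("test", split.test),
        ):
            for p in pairs:
                fh.write(f"{p.read_id}\t{p.source}\t{p.target}\n")
                membership[p.read_id] = name
    sidecar = {"k": k, "alphabet": "ACGT$", "split": membership}
    (out / "corpus.json").write_text(json.dumps(sidecar, indent=1))


def load_corpus(in_dir: str | Path) -> tuple[CorpusSplit, int]:
    out = Path(in_dir)
    sidecar = json.loads((out / "corpus.json").read_text())
    membership = sidecar["split"]
    buckets: dict[str, list[SentencePair]] = {
        "train": [], "validation": [], "test": []
    }
    with open(out / "corpus.tsv") as fh:
        for line in fh:
            read_id, source, target = line.rstrip("\n").split("\t")
            buckets[membership[read_id]].append(
                SentencePair(read_id, source, target, covered_fraction=0.0)
            )
    return CorpusSplit(**buckets), sidecar["k"]
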