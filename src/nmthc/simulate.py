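"""Synthetic fixture generator: genome, noisy long reads, accurate short
reads, and an exact ground-truth SAM.

Long reads are sampled as genome substrings and corrupted by a per-base
channel draw — substitution to a different base, insertion of a uniform
base before the current one, or deletion — at configurable rates (presets
emulate PacBio-CLR-like ~13% and ONT-like ~15% totals). The full error
trace of every long read is recorded, so short reads sampled from the
*genome* (which therefore carry the truth signal) can be placed onto each
overlapping long read by coordinate arithmetic alone, yielding exact
extended CIGARs: no external aligner is needed anywhere in the pipeline's
test surface. Short reads carry independent substitution errors (~1% by
default, Illumina-like); indels in short reads are not modelled.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pysam

from .io_formats import SequenceRecord, write_fasta

BASES = "ACGT"


@dataclass(frozen=True)
class ErrorProfile:
    sub_rate: float
    ins_rate: float
    del_rate: float
    name: str | None = None

    def __post_init__(self) -> None:
        for r in (self.sub_rate, self.ins_rate, self.del_rate):
            if not 0 <= r < 1:
                raise ValueError("rates must be in [0, 1)")
        if self.sub_rate + self.ins_rate + self.del_rate >= 1:
            raise ValueError("total error rate must be < 1")

    @property
    def total(self) -> float:
        return self.sub_rate + self.ins_rate + self.del_rate


#: ~13% total, indel-dominant (PacBio CLR regime)
PACBIO_LIKE = ErrorProfile(0.016, 0.066, 0.048, "pacbio-like")
#: ~15% total (ONT regime)
ONT_LIKE = ErrorProfile(0.05, 0.05, 0.05, "ont-like")
#: ~1% substitutions only (Illumina regime, used for short reads)
ILLUMINA_LIKE = ErrorProfile(0.01, 0.0, 0.0, "illumina-like")
ERROR_FREE = ErrorProfile(0.0, 0.0, 0.0, "error-free")

PROFILES = {p.name: p for p in (PACBIO_LIKE, ONT_LIKE, ILLUMINA_LIKE, ERROR_FREE)}


def uniform_profile(total: float, name: str | None = None) -> ErrorProfile:
    """Split a total error rate evenly across the three channels."""
    return ErrorProfile(total / 3, total / 3, total / 3, name)


@dataclass
class LongReadTruth:
    """One simulated long read plus its full error trace.

    Per genome offset ``j`` (0-based within [genome_start, genome_end)):
    ``ins_before[j]`` holds long-read bases inserted before that genome
    base's slot, ``ops[j]`` is the channel outcome ('M' kept, 'S'
    substituted, 'D' deleted), ``emitted[j]`` the long-read base for M/S,
    and ``lr_pos[j]`` its 1-based position on the long read.
    """

    read: SequenceRecord
    genome_start: int  # 0-based
    genome_end: int  # exclusive
    truth_bases: str
    ops: list[str]
    emitted: list[str | None]
    lr_pos: list[int | None]
    ins_before: list[str]


@dataclass
class SimulatedDataset:
    genome: SequenceRecord
    long_truths: list[LongReadTruth]
    short_reads: list[SequenceRecord]
    sam_records: list[dict]

    @property
    def long_reads(self) -> list[SequenceRecord]:
        return [t.read for t in self.long_truths]

    @property
    def truth_by_id(self) -> dict[str, str]:
        return {t.read.id: t.truth_bases for t in self.long_truths}

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta([self.genome], out / "genome.fa")
        write_fasta(self.long_reads, out / "long.fa")
        write_fasta(self.short_reads, out / "short.fa")
        write_truth_sam(self, out / "truth.sam")
        truth = {
            t.read.id: {
                "interval": [t.genome_start, t.genome_end],
                "truth_bases": t.truth_bases,
            }
            for t in self.long_truths
        }
        (out / "truth.json").write_text(json.dumps(truth))


def simulate_genome(length: int, gc: float = 0.5, seed: int = 0) -> SequenceRecord:
    """I.i.d. random genome with P(G) + P(C) = gc."""
    if length < 1:
        raise ValueError("genome length must be >= 1")
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = rng.choice(list(BASES), size=length, p=p)
    return SequenceRecord(id="genome", bases="".join(bases))


def _corrupt_long(
    genome: str, start: int, end: int, profile: ErrorProfile,
    rng: np.random.Generator, read_id: str,
) -> LongReadTruth:
    """Apply the per-base error channel to one genome substring.

    Insertions attach *after* an emitted base (suppressed at the read's
    final base) and boundary deletions are folded into the truth interval:
    an indel at the extreme edge of a read is indistinguishable from the
    read simply starting or ending elsewhere, so keeping edges anchored on
    aligned bases makes the recorded truth exact rather than ambiguous.
    """
    draws = rng.random(end - start)
    channels = []
    for u in draws:
        if u < profile.sub_rate:
            channels.append("S")
        elif u < profile.sub_rate + profile.ins_rate:
            channels.append("I")
        elif u < profile.total:
            channels.append("D")
        else:
            channels.append("M")
    while channels and channels[0] == "D":
        channels.pop(0)
        start += 1
    while channels and channels[-1] == "D":
        channels.pop()
        end -= 1
    if not channels:  # pathological all-deleted draw: keep one base
        channels = ["M"]
        end = start + 1
    if channels[-1] == "I":
        channels[-1] = "M"

    span = end - start
    ops: list[str] = []
    emitted: list[str | None] = []
    lr_pos: list[int | None] = []
    ins_before: list[str] = [""] * span
    pieces: list[str] = []
    pos = 0  # long-read bases emitted so far
    for j, ch in enumerate(channels):
        base = genome[start + j]
        if ch == "S":
            op, out = "S", BASES[(BASES.index(base) + rng.integers(1, 4)) % 4]
        elif ch == "D":
            op, out = "D", None
        else:
            op, out = "M", base
        ops.append(op)
        if out is None:
            emitted.append(None)
            lr_pos.append(None)
        else:
            pieces.append(out)
            pos += 1
            emitted.append(out)
            lr_pos.append(pos)
        if ch == "I":  # inserted base after this one
            ins = BASES[rng.integers(0, 4)]
            ins_before[j + 1] = ins
            pieces.append(ins)
            pos += 1
    return LongReadTruth(
        read=SequenceRecord(id=read_id, bases="".join(pieces)),
        genome_start=start,
        genome_end=end,
        truth_bases=genome[start:end],
        ops=ops,
        emitted=emitted,
        lr_pos=lr_pos,
        ins_before=ins_before,
    )


def simulate_long_reads(
    genome: SequenceRecord,
    n: int,
    len_range: tuple[int, int],
    profile: ErrorProfile,
    seed: int = 0,
) -> list[LongReadTruth]:
    """Noisy long reads with recorded truth intervals and error traces."""
    lo, hi = len_range
    if not 1 <= lo <= hi <= len(genome):
        raise ValueError("len_range must fit inside the genome")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(0, len(genome) - length + 1))
        out.append(
            _corrupt_long(genome.bases, start, start + length, profile, rng, f"lr{i}")
        )
    return out


def _truth_alignment(
    truth: LongReadTruth, sr_bases: str, sr_start: int
) -> tuple[int, list[tuple[int, int]]] | None:
    """Place a substitution-only short read on a long read via the trace.

    Returns (1-based SAM POS on the long read, pysam cigartuples) or None
    when the overlap contains no surviving long-read base. CIGAR codes:
    soft clip 4, '=' 7, 'X' 8, I 1 (short-read-only base), D 2
    (long-read-only base).
    """
    a = max(sr_start, truth.genome_start)
    b = min(sr_start + len(sr_bases), truth.genome_end)
    if b <= a:
        return None
    j0 = a - truth.genome_start
    j1 = b - truth.genome_start  # exclusive, trace offsets
    ms = [j for j in range(j0, j1) if truth.ops[j] != "D"]
    if not ms:
        return None
    first, last = ms[0], ms[-1]
    cig: list[tuple[int, int]] = []

    def push(code: int, n: int = 1) -> None:
        if cig and cig[-1][0] == code:
            cig[-1] = (code, cig[-1][1] + n)
        else:
            cig.append((code, n))

    left_clip = (truth.genome_start + first) - sr_start
    if left_clip:
        push(4, left_clip)
    for j in range(first, last + 1):
        if j > first and truth.ins_before[j]:
            push(2, len(truth.ins_before[j]))  # long-read-only bases
        sr_base = sr_bases[truth.genome_start + j - sr_start]
        if truth.ops[j] == "D":
            push(1)  # short read keeps the base the long read lost
        else:
            push(7 if sr_base == truth.emitted[j] else 8)
    right_clip = (sr_start + len(sr_bases)) - (truth.genome_start + last + 1)
    if right_clip:
        push(4, right_clip)
    return truth.lr_pos[first], cig


def simulate_short_reads_with_truth_sam(
    genome: SequenceRecord,
    long_truths: Sequence[LongReadTruth],
    coverage: float,
    read_len: int = 100,
    short_profile: ErrorProfile = ILLUMINA_LIKE,
    seed: int = 0,
) -> tuple[list[SequenceRecord], list[dict]]:
    """Genome-sampled short reads plus their exact placements on every
    overlapping long read.

    Starts are drawn uniformly over ``[-(read_len-1), genome_len)`` and
    clipped to the genome, so coverage stays near-uniform out to the genome
    ends (edge reads are shortened). Returns the reads and a list of
    SAM-ready record dicts.
    """
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    if short_profile.ins_rate or short_profile.del_rate:
        raise ValueError("short-read error model supports substitutions only")
    L = len(genome)
    rng = np.random.default_rng(seed)
    n = math.ceil(coverage * (L + read_len - 1) / read_len)
    reads: list[SequenceRecord] = []
    sam_records: list[dict] = []
    kept = 0
    for i in range(n):
        start = int(rng.integers(-(read_len - 1), L))
        s, e = max(start, 0), min(start + read_len, L)
        if e - s < min(20, read_len):
            continue
        bases = list(genome.bases[s:e])
        if short_profile.sub_rate:
            hits = np.nonzero(rng.random(len(bases)) < short_profile.sub_rate)[0]
            for j in hits:
                bases[j] = BASES[(BASES.index(bases[j]) + rng.integers(1, 4)) % 4]
        sr = SequenceRecord(id=f"sr{kept}", bases="".join(bases))
        kept += 1
        reads.append(sr)
        for truth in long_truths:
            placed = _truth_alignment(truth, sr.bases, s)
            if placed is None:
                continue
            pos1, cig = placed
            sam_records.append(
                {
                    "qname": sr.id,
                    "rname": truth.read.id,
                    "pos1": pos1,
                    "cigartuples": cig,
                    "seq": sr.bases,
                }
            )
    return reads, sam_records


def write_truth_sam(dataset_or_parts, path: str | Path) -> None:
    """Write the truth alignments as a plain-text SAM via pysam."""
    if isinstance(dataset_or_parts, SimulatedDataset):
        long_reads = dataset_or_parts.long_reads
        sam_records = dataset_or_parts.sam_records
    else:
        long_reads, sam_records = dataset_or_parts
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": r.id, "LN": len(r)} for r in long_reads],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in sam_records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = rec["qname"]
            a.flag = 0
            a.reference_name = rec["rname"]
            a.reference_start = rec["pos1"] - 1
            a.mapping_quality = 60
            a.cigartuples = rec["cigartuples"]
            a.query_sequence = rec["seq"]
            out.write(a)


def simulate_dataset(
    genome_len: int = 2000,
    n_long: int = 50,
    len_range: tuple[int, int] = (100, 200),
    long_profile: ErrorProfile = PACBIO_LIKE,
    coverage: float = 30.0,
    read_len: int = 100,
    short_profile: ErrorProfile = ILLUMINA_LIKE,
    gc: float = 0.5,
    seed: int = 0,
) -> SimulatedDataset:
    """End-to-end fixture: genome + long reads + short reads + truth SAM.

    Sub-seeds for the three stages are derived deterministically from
    ``seed`` so the whole dataset is a pure function of its arguments.
    """
    s1, s2, s3 = [int(s) for s in np.random.SeedSequence(seed).generate_state(3) >> 1]
    genome = simulate_genome(genome_len, gc=gc, seed=s1)
    long_truths = simulate_long_reads(genome, n_long, len_range, long_profile, seed=s2)
    short_reads, sam_records = simulate_short_reads_with_truth_sam(
        genome, long_truths, coverage, read_len, short_profile, seed=s3
    )
    return SimulatedDataset(genome, long_truths, short_reads, sam_records)
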