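"""Sequence and alignment I/O.

FASTA/FASTQ records come in through Biopython, SAM records through pysam.
Alignments are normalised into an *extended CIGAR* over the four-letter
alphabet {M, S, D, I} anchored at a 1-based position on the long read:

* ``M`` — long-read base confirmed by the short read,
* ``S`` — long-read base substituted (short read carries a different base),
* ``D`` — long-read base absent from the short read,
* ``I`` — short-read bases absent from the long read.

All coordinates in this package are 1-based and intervals are fully closed.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pysam
import yaml
from Bio import SeqIO

log = logging.getLogger(__name__)

DNA = frozenset("ACGT")
EXTENDED_OPS = "MSDI"
#: extended-CIGAR codes that consume long-read (reference) positions
REF_OPS = frozenset("MSD")
#: extended-CIGAR codes that consume short-read (query) bases
QUERY_OPS = frozenset("MSI")

_CIGAR_RE = re.compile(r"^(\d+):((?:\d+[MSDI])+)$")
_OP_RE = re.compile(r"(\d+)([MSDI])")


class CigarParseError(ValueError):
    pass


@dataclass(frozen=True)
class SequenceRecord:
    """A sanitized read or genome: ``bases`` is strictly over {A,C,G,T}."""

    id: str
    bases: str
    description: str | None = None

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"record id {self.id!r} is empty or has whitespace")
        if not self.bases:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        bad = set(self.bases) - DNA
        if bad:
            raise ValueError(f"record {self.id!r} has non-ACGT characters {bad}")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class ExtendedCigar:
    """Run-length ops over {M,S,D,I} anchored at a 1-based long-read start."""

    start: int
    ops: tuple[tuple[int, str], ...]

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError("extended-CIGAR start is 1-based; got start < 1")
        if not self.ops:
            raise ValueError("extended CIGAR needs at least one op")
        for n, code in self.ops:
            if n < 1 or code not in EXTENDED_OPS:
                raise ValueError(f"bad op ({n}, {code!r})")
        for (_, a), (_, b) in zip(self.ops, self.ops[1:]):
            if a == b:
                raise ValueError("consecutive ops share a code; not canonical")
        if self.reference_span() < 1:
            raise ValueError("extended CIGAR consumes no reference base")

    def reference_span(self) -> int:
        return sum(n for n, c in self.ops if c in REF_OPS)

    def query_span(self) -> int:
        return sum(n for n, c in self.ops if c in QUERY_OPS)


@dataclass(frozen=True)
class AlignmentRecord:
    """One short read placed on one long read."""

    short_read_id: str
    long_read_id: str
    cigar: ExtendedCigar
    query_bases: str

    def __post_init__(self) -> None:
        if len(self.query_bases) != self.cigar.query_span():
            raise ValueError(
                f"alignment {self.short_read_id}->{self.long_read_id}: "
                f"query length {len(self.query_bases)} != M+S+I span "
                f"{self.cigar.query_span()}"
            )


def _merge_runs(ops: Iterable[tuple[int, str]]) -> tuple[tuple[int, str], ...]:
    merged: list[tuple[int, str]] = []
    for n, code in ops:
        if merged and merged[-1][1] == code:
            merged[-1] = (merged[-1][0] + n, code)
        else:
            merged.append((n, code))
    return tuple(merged)


def parse_extended_cigar(text: str) -> ExtendedCigar:
    """Parse ``"start:ops"`` notation, e.g. ``"5:4M2S3D6M4I1M"``."""
    m = _CIGAR_RE.match(text.strip())
    if m is None:
        raise CigarParseError(f"not a start:ops extended CIGAR: {text!r}")
    start = int(m.group(1))
    if start == 0:
        raise CigarParseError("start position 0: coordinates are 1-based")
    ops = _merge_runs((int(n), c) for n, c in _OP_RE.findall(m.group(2)))
    return ExtendedCigar(start=start, ops=ops)


def format_extended_cigar(cigar: ExtendedCigar) -> str:
    return f"{cigar.start}:" + "".join(f"{n}{c}" for n, c in cigar.ops)


def cigar_reference_interval(cigar: ExtendedCigar) -> tuple[int, int]:
    """1-based closed interval of long-read positions the alignment covers."""
    return cigar.start, cigar.start + cigar.reference_span() - 1


def walk_reference_positions(cigar: ExtendedCigar):
    """Yield ``(op_code, ref_pos_or_after_pos)`` one event per op run.

    For M/S/D runs the yielded position is the first long-read base of the
    run; for I runs it is the long-read position the insertion follows
    (``start - 1`` for a leading insertion).
    """
    pos = cigar.start
    for n, code in cigar.ops:
        if code in REF_OPS:
            yield code, pos
            pos += n
        else:
            yield code, pos - 1


# ---------------------------------------------------------------------------
# FASTA / FASTQ

def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def sanitize_bases(raw: str, read_id: str = "?") -> str:
    """Uppercase and map every non-ACGT character (N, IUPAC codes) to 'A'.

    Keeps the five-character corpus alphabet {A,C,G,T,$} closed.
    """
    up = raw.upper()
    n_bad = sum(1 for c in up if c not in DNA)
    if n_bad:
        log.info("read %s: mapped %d non-ACGT characters to A", read_id, n_bad)
        up = "".join(c if c in DNA else "A" for c in up)
    return up


def read_sequences(path: str | Path, fmt: str | None = None) -> list[SequenceRecord]:
    """Load FASTA or FASTQ (gz-transparent) as sanitized records."""
    path = Path(path)
    if fmt is None:
        stem = path.name[:-3] if path.name.endswith(".gz") else path.name
        fmt = "fastq" if stem.endswith((".fq", ".fastq")) else "fasta"
    records = []
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, fmt):
            records.append(
                SequenceRecord(
                    id=rec.id,
                    bases=sanitize_bases(str(rec.seq), rec.id),
                    description=rec.description or None,
                )
            )
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.bases), 80):
                fh.write(rec.bases[i : i + 80] + "\n")


# ---------------------------------------------------------------------------
# SAM

def _resolve_sam_ops(aln: pysam.AlignedSegment, long_read: SequenceRecord | None):
    """Map one SAM record's CIGAR onto the extended {M,S,D,I} alphabet."""
    seq = aln.query_sequence
    if seq is None:
        raise ValueError(f"SAM record {aln.query_name}: no SEQ stored")
    ops: list[tuple[int, str]] = []
    qpos = 0  # cursor into SEQ
    rpos = aln.reference_start  # 0-based
    query_parts: list[str] = []
    for code, n in aln.cigartuples:
        if code == 7:  # '='
            ops.append((n, "M"))
            query_parts.append(seq[qpos : qpos + n])
            qpos += n
            rpos += n
        elif code == 8:  # 'X'
            ops.append((n, "S"))
            query_parts.append(seq[qpos : qpos + n])
            qpos += n
            rpos += n
        elif code == 0:  # 'M': resolve per base against the long read
            if long_read is None:
                raise ValueError(
                    f"SAM record {aln.query_name}: CIGAR 'M' needs the "
                    f"long-read sequence to resolve match vs substitution"
                )
            for i in range(n):
                q = seq[qpos + i]
                r = long_read.bases[rpos + i]
                ops.append((1, "M" if q == r else "S"))
            query_parts.append(seq[qpos : qpos + n])
            qpos += n
            rpos += n
        elif code == 1:  # I
            ops.append((n, "I"))
            query_parts.append(seq[qpos : qpos + n])
            qpos += n
        elif code == 2:  # D
            ops.append((n, "D"))
            rpos += n
        elif code == 4:  # soft clip: excluded, consumes SEQ
            qpos += n
        elif code in (5, 6):  # hard clip / pad: excluded
            pass
        elif code == 3:  # N skip
            raise ValueError(
                f"SAM record {aln.query_name}: N-skip ops are unsupported"
            )
        else:
            raise ValueError(f"SAM record {aln.query_name}: CIGAR op {code}")
    return _merge_runs(ops), "".join(query_parts)


def sam_to_alignments(
    sam_path: str | Path,
    long_reads: Mapping[str, SequenceRecord],
    short_reads: Mapping[str, SequenceRecord] | None = None,
    include_secondary: bool = True,
) -> list[AlignmentRecord]:
    """Parse a SAM file of short reads aligned to long reads.

    The SAM reference names must be long-read ids. Unmapped records are
    skipped. Reverse-strand records use the reverse-complemented SEQ exactly
    as stored in the SAM. ``short_reads`` is accepted for id checking only;
    SEQ comes from the SAM itself.
    """
    out: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped:
                continue
            if not include_secondary and (aln.is_secondary or aln.is_supplementary):
                continue
            ref = aln.reference_name
            long_read = long_reads.get(ref)
            ops, query = _resolve_sam_ops(aln, long_read)
            query = sanitize_bases(query, aln.query_name)
            cigar = ExtendedCigar(start=aln.reference_start + 1, ops=ops)
            out.append(
                AlignmentRecord(
                    short_read_id=aln.query_name,
                    long_read_id=ref,
                    cigar=cigar,
                    query_bases=query,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Run configuration

CONFIG_SECTIONS = ("corpus", "model", "transfer", "simulate", "evaluate")


def load_config(path: str | Path) -> dict:
    """Load a YAML run config; unknown top-level sections are rejected."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config root must be a mapping")
    unknown = set(cfg) - set(CONFIG_SECTIONS)
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    return {sec: dict(cfg.get(sec) or {}) for sec in CONFIG_SECTIONS}
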