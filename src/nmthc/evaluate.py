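"""Evaluation panel for read sets.

The panel mirrors the standard hybrid-error-correction report: total
bases, aligned (matching) bases, alignment identity = aligned / total,
average and maximum aligned-region length on the read, and N50. It can be
fed from an external aligner's PAF or SAM against a reference genome, or —
for simulator fixtures — from a per-read optimal global alignment against
the known truth bases (edit-distance alignment via edlib). A min–max
normalization maps each metric across methods onto [0, 1] for side-by-side
comparison.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import edlib
import pysam

from .io_formats import SequenceRecord

_CIG_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass(frozen=True)
class MetricsRow:
    label: str
    total_bases: int
    aligned_bases: int
    avg_len: float
    max_len: int
    n50: int

    def __post_init__(self) -> None:
        if self.aligned_bases > self.total_bases:
            raise ValueError("aligned_bases cannot exceed total_bases")

    @property
    def identity(self) -> float:
        return self.aligned_bases / self.total_bases if self.total_bases else 0.0

    def as_dict(self) -> dict:
        return {
            "label": self.label,
            "total_bases": self.total_bases,
            "aligned_bases": self.aligned_bases,
            "identity": self.identity,
            "avg_len": self.avg_len,
            "max_len": self.max_len,
            "n50": self.n50,
        }


@dataclass(frozen=True)
class RefAlignment:
    """One read-to-reference alignment: matches + aligned region on the read."""

    read_id: str
    read_start: int  # 0-based
    read_end: int  # exclusive
    matches: int


def n50(lengths: Sequence[int]) -> int:
    """Smallest length whose descending cumulative sum reaches half the total."""
    if not lengths:
        raise ValueError("n50 of an empty length list")
    ordered = sorted(lengths, reverse=True)
    half = sum(ordered) / 2
    acc = 0
    for length in ordered:
        acc += length
        if acc >= half:
            return length
    raise AssertionError("unreachable")


def min_max_normalize(values: Sequence[float]) -> list[float]:
    """(x − min) / (max − min) per value; degenerate inputs are an error."""
    if len(values) < 2:
        raise ValueError("need at least two values to normalize")
    lo, hi = min(values), max(values)
    if hi == lo:
        raise ValueError("all values equal: min–max normalization undefined")
    return [(v - lo) / (hi - lo) for v in values]


def _panel(label: str, total: int, alns: Sequence[RefAlignment]) -> MetricsRow:
    region_lens = [a.read_end - a.read_start for a in alns]
    return MetricsRow(
        label=label,
        total_bases=total,
        aligned_bases=sum(a.matches for a in alns),
        avg_len=sum(region_lens) / len(region_lens) if region_lens else 0.0,
        max_len=max(region_lens) if region_lens else 0,
        n50=n50(region_lens) if region_lens else 0,
    )


def metrics_from_alignments(
    read_set: Sequence[SequenceRecord],
    alignments: Sequence[RefAlignment],
    label: str = "reads",
) -> MetricsRow:
    """Panel from reference alignments; per read, the best alignment
    (highest match count) is used, unaligned reads count toward total only."""
    if not read_set:
        raise ValueError("empty read set")
    ids = {r.id for r in read_set}
    best: dict[str, RefAlignment] = {}
    for a in alignments:
        if a.read_id not in ids:
            raise ValueError(f"alignment for unknown read {a.read_id}")
        if a.read_id not in best or a.matches > best[a.read_id].matches:
            best[a.read_id] = a
    return _panel(label, sum(len(r) for r in read_set), list(best.values()))


def global_match_count(query: str, target: str) -> int:
    """Match count of an optimal unit-cost global alignment."""
    if not query or not target:
        return 0
    res = edlib.align(query, target, mode="NW", task="path")
    return sum(int(n) for n, op in _CIG_RE.findall(res["cigar"]) if op == "=")


def truth_identity(
    corrected: Mapping[str, str], truth: Mapping[str, str], label: str = "corrected"
) -> tuple[dict[str, float], MetricsRow]:
    """Per-read identity against known truth bases, plus the panel row.

    identity = global-alignment matches / len(corrected read); an empty
    corrected read scores 0 with a warning. Aligned-region length for the
    panel is the full corrected read (the alignment is global).
    """
    if set(corrected) != set(truth):
        only = set(corrected) ^ set(truth)
        raise ValueError(f"read ids present on one side only: {sorted(only)[:5]}")
    per_read: dict[str, float] = {}
    alns: list[RefAlignment] = []
    total = 0
    for rid in corrected:
        seq = corrected[rid]
        total += len(seq)
        if not seq:
            warnings.warn(f"read {rid}: empty corrected sequence, identity 0")
            per_read[rid] = 0.0
            continue
        matches = global_match_count(seq, truth[rid])
        per_read[rid] = matches / len(seq)
        alns.append(RefAlignment(rid, 0, len(seq), matches))
    row = _panel(label, total, alns)
    return per_read, row


# ---------------------------------------------------------------------------
# external-aligner input

def parse_paf(path: str | Path) -> list[RefAlignment]:
    """minimap2 default output: matches from column 10, region from 3–4."""
    out = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise ValueError("truncated PAF line")
            out.append(
                RefAlignment(
                    read_id=f[0],
                    read_start=int(f[2]),
                    read_end=int(f[3]),
                    matches=int(f[9]),
                )
            )
    return out


def parse_ref_sam(path: str | Path) -> list[RefAlignment]:
    """Reference alignments from SAM; matches need '=' ops or an NM tag."""
    out = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped:
                continue
            stats = dict(zip("MIDNSHP=X", aln.get_cigar_stats()[0]))
            if stats["="] or stats["X"]:
                matches = stats["="]
            elif aln.has_tag("NM"):
                mismatches = aln.get_tag("NM") - stats["I"] - stats["D"]
                matches = stats["M"] - mismatches
            else:
                raise ValueError(
                    f"{aln.query_name}: cannot count matches without =/X ops or NM"
                )
            out.append(
                RefAlignment(
                    read_id=aln.query_name,
                    read_start=aln.query_alignment_start,
                    read_end=aln.query_alignment_end,
                    matches=matches,
                )
            )
    return out


def normalize_table(rows: Sequence[MetricsRow]) -> dict[str, list[float]]:
    """Eq-style min–max normalization of each metric across rows."""
    metrics = ("total_bases", "aligned_bases", "identity", "avg_len", "max_len", "n50")
    return {
        m: min_max_normalize([getattr(r, m) if m != "identity" else r.identity for r in rows])
        for m in metrics
    }


def write_metrics_tsv(rows: Sequence[MetricsRow], path: str | Path) -> None:
    cols = ["label", "total_bases", "aligned_bases", "identity",
            "avg_len", "max_len", "n50"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in rows:
            d = r.as_dict()
            fh.write("\t".join(str(d[c]) for c in cols) + "\n")
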