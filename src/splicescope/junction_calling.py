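"""Splice-junction extraction and counting from spliced SAM/BAM alignments.

Junctions are read off the ``N`` operations of each alignment's CIGAR; a read
contributes at most one count to any junction, and only when it carries at
least ``min_anchor`` aligned bases on both sides of the gap.  Per-base
coverage is computed in mRNA coordinates by projecting aligned reference
blocks through the transcript model.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
import pysam

from .transcript_model import TranscriptModel

__all__ = [
    "JunctionCountTable",
    "CoverageTrack",
    "CooccurrenceRecord",
    "extract_junctions_from_cigar",
    "count_junctions",
    "extract_cooccurrence",
    "coverage_profile",
]

# CIGAR operation codes (pysam)
_M, _I, _D, _N, _S, _EQ, _X = 0, 1, 2, 3, 4, 7, 8
_REF_ADVANCE = {_M, _D, _N, _EQ, _X}
_ALIGNED = {_M, _EQ, _X}


@dataclass(frozen=True)
class CooccurrenceRecord:
    """Junctions crossed by a single read, ordered along the reference."""

    read_id: str
    junctions: tuple[tuple[int, int], ...]


class JunctionCountTable:
    """Unique junction-spanning read counts keyed by (junction interval, sample).

    Also records, per key, the smallest flanking anchor actually seen among
    the contributing reads.
    """

    def __init__(self, chrom: str = "", strand: str = "+") -> None:
        self.chrom = chrom
        self.strand = strand
        self._counts: dict[tuple[int, int], dict[str, int]] = {}
        self._anchors: dict[tuple[int, int], dict[str, int]] = {}

    def add(
        self, interval: tuple[int, int], sample: str, count: int = 1, anchor: int | None = None
    ) -> None:
        if count < 0:
            raise ValueError("junction counts must be non-negative")
        per = self._counts.setdefault(tuple(interval), {})
        per[sample] = per.get(sample, 0) + count
        if anchor is not None:
            pa = self._anchors.setdefault(tuple(interval), {})
            pa[sample] = min(pa.get(sample, anchor), anchor)

    def get(self, interval: tuple[int, int], sample: str) -> int:
        return self._counts.get(tuple(interval), {}).get(sample, 0)

    def anchor_min_seen(self, interval: tuple[int, int], sample: str) -> int | None:
        return self._anchors.get(tuple(interval), {}).get(sample)

    @property
    def samples(self) -> list[str]:
        out: set[str] = set()
        for per in self._counts.values():
            out.update(per)
        return sorted(out)

    def junctions(self) -> list[tuple[int, int]]:
        return sorted(self._counts)

    def total(self, sample: str) -> int:
        return sum(per.get(sample, 0) for per in self._counts.values())

    def update(self, other: "JunctionCountTable") -> None:
        for interval, per in other._counts.items():
            for sample, count in per.items():
                self.add(interval, sample, count, other.anchor_min_seen(interval, sample))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (d, a), per in sorted(self._counts.items()):
            for sample in sorted(per):
                rows.append(
                    {
                        "chrom": self.chrom,
                        "start": d,
                        "end": a,
                        "strand": self.strand,
                        "count": per[sample],
                        "sample": sample,
                        "min_anchor": self.anchor_min_seen((d, a), sample),
                    }
                )
        return pd.DataFrame(
            rows,
            columns=["chrom", "start", "end", "strand", "count", "sample", "min_anchor"],
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "JunctionCountTable":
        df = pd.read_csv(path, sep="\t")
        table = cls(
            chrom=str(df["chrom"].iloc[0]) if len(df) else "",
            strand=str(df["strand"].iloc[0]) if len(df) else "+",
        )
        for row in df.itertuples():
            anchor = None if pd.isna(getattr(row, "min_anchor", None)) else int(row.min_anchor)
            table.add((int(row.start), int(row.end)), str(row.sample), int(row.count), anchor)
        return table


@dataclass
class CoverageTrack:
    """Per-mRNA-base read depth with its mean and (population) SD."""

    depth: np.ndarray
    mean: float
    sd: float

    def write_bedgraph(self, path: str | Path, name: str = "mRNA") -> None:
        """Write the track as bedGraph over mRNA coordinates."""
        with open(path, "w") as fh:
            depth = self.depth
            i = 0
            while i < len(depth):
                j = i
                while j < len(depth) and depth[j] == depth[i]:
                    j += 1
                fh.write(f"{name}\t{i}\t{j}\t{int(depth[i])}\n")
                i = j


def extract_junctions_from_cigar(rec: pysam.AlignedSegment) -> list[tuple[int, int]]:
    """Genomic intron intervals spanned by one alignment, one per CIGAR ``N``."""
    if rec.is_unmapped or rec.cigartuples is None:
        raise ValueError(f"read {rec.query_name!r} is unmapped or CIGAR-less")
    out = []
    ref = rec.reference_start
    for op, length in rec.cigartuples:
        if op == _N:
            out.append((ref, ref + length))
        if op in _REF_ADVANCE:
            ref += length
    return out


def _junctions_with_anchors(
    rec: pysam.AlignedSegment,
) -> list[tuple[tuple[int, int], int, int]]:
    """Each junction with the aligned base count on its left and right side."""
    ref = rec.reference_start
    segments: list[int] = [0]  # aligned bases between successive N gaps
    gaps: list[tuple[int, int]] = []
    for op, length in rec.cigartuples:
        if op == _N:
            gaps.append((ref, ref + length))
            segments.append(0)
        elif op in _ALIGNED:
            segments[-1] += length
        if op in _REF_ADVANCE:
            ref += length
    return [(gap, segments[k], segments[k + 1]) for k, gap in enumerate(gaps)]


def _iter_alignments(
    alignments: str | Path | Iterable[pysam.AlignedSegment],
) -> Iterator[pysam.AlignedSegment]:
    if isinstance(alignments, (str, Path)):
        with pysam.AlignmentFile(str(alignments), check_sq=False) as fh:
            yield from fh
    else:
        yield from alignments


def count_junctions(
    alignments: str | Path | Iterable[pysam.AlignedSegment],
    min_anchor: int = 10,
    sample_id: str | None = None,
    chrom: str = "",
    strand: str = "+",
) -> JunctionCountTable:
    """Count unique junction-spanning reads in a SAM/BAM file.

    A read contributes at most once per junction, and only when both
    flanking aligned segments reach ``min_anchor`` bases.  Secondary,
    supplementary and unmapped records are skipped.
    """
    if min_anchor < 1:
        raise ValueError("min_anchor must be >= 1")
    if sample_id is None and isinstance(alignments, (str, Path)):
        sample_id = Path(alignments).stem
    table = JunctionCountTable(chrom=chrom, strand=strand)
    skipped = 0
    for rec in _iter_alignments(alignments):
        if rec.is_unmapped or rec.cigartuples is None:
            skipped += 1
            continue
        if rec.is_secondary or rec.is_supplementary:
            continue
        seen: set[tuple[int, int]] = set()
        if not table.chrom and rec.reference_name:
            table.chrom = rec.reference_name
        for gap, left, right in _junctions_with_anchors(rec):
            anchor = min(left, right)
            if anchor >= min_anchor and gap not in seen:
                table.add(gap, sample_id or "sample", 1, anchor)
                seen.add(gap)
    table.skipped_records = skipped  # type: ignore[attr-defined]
    return table


def extract_cooccurrence(
    alignments: str | Path | Iterable[pysam.AlignedSegment],
    min_anchor: int = 1,
) -> list[CooccurrenceRecord]:
    """One record per mapped read that crosses at least one junction."""
    out = []
    for rec in _iter_alignments(alignments):
        if rec.is_unmapped or rec.cigartuples is None:
            continue
        if rec.is_secondary or rec.is_supplementary:
            continue
        gaps = tuple(
            gap
            for gap, left, right in _junctions_with_anchors(rec)
            if min(left, right) >= min_anchor
        )
        if gaps:
            out.append(CooccurrenceRecord(rec.query_name, gaps))
    return out


def _project_block(
    model: TranscriptModel, gstart: int, gend: int
) -> list[tuple[int, int]]:
    """Project an aligned genomic block onto mRNA intervals (exonic overlap only)."""
    out = []
    for ex in model.exons:
        ovs, ove = max(gstart, ex.genomic_start), min(gend, ex.genomic_end)
        if ovs < ove:
            base = model.exon_mrna_span(ex.index)[0]
            if model.strand == "+":
                out.append((base + ovs - ex.genomic_start, base + ove - ex.genomic_start))
            else:
                out.append((base + ex.genomic_end - ove, base + ex.genomic_end - ovs))
    return out


def coverage_profile(
    alignments: str | Path | Iterable[pysam.AlignedSegment],
    model: TranscriptModel,
) -> CoverageTrack:
    """Per-base mRNA read depth from aligned (M/=/X) reference blocks."""
    depth = np.zeros(model.mrna_length, dtype=np.int64)
    for rec in _iter_alignments(alignments):
        if rec.is_unmapped or rec.cigartuples is None:
            continue
        if rec.is_secondary or rec.is_supplementary:
            continue
        ref = rec.reference_start
        for op, length in rec.cigartuples:
            if op in _ALIGNED:
                for m0, m1 in _project_block(model, ref, ref + length):
                    depth[m0:m1] += 1
            if op in _REF_ADVANCE:
                ref += length
    mean = float(depth.mean()) if len(depth) else 0.0
    sd = float(depth.std()) if len(depth) else 0.0
    return CoverageTrack(depth=depth, mean=mean, sd=sd)
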