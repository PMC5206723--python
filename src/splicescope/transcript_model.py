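"""Single-isoform transcript models and genomic/mRNA coordinate arithmetic.

All genomic coordinates are 0-based half-open intervals on the plus strand
(BED convention); GTF input (1-based inclusive) is converted at the parser
boundary.  Exons are ordered in transcription direction, so a minus-strand
model has exon 1 at the highest genomic coordinate.  A splice junction is
represented by its intron interval ``[donor_pos, acceptor_pos)`` on the
genomic axis with ``donor_pos < acceptor_pos`` regardless of strand;
donor/acceptor *roles* are resolved through the model's strand.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Exon",
    "Junction",
    "IntronicPosition",
    "TranscriptModel",
    "TranscriptNotFoundError",
    "ModelValidationError",
    "derive_canonical_junctions",
    "load_transcript_model",
    "write_junctions_bed",
    "write_transcript_gtf",
    "build_dp427m_like_model",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse-complement a nucleotide string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


class TranscriptNotFoundError(KeyError):
    """Requested transcript id absent from the annotation file."""


class ModelValidationError(ValueError):
    """Exon structure violates the model invariants."""


@dataclass(frozen=True)
class Exon:
    """One exon: 1-based ordinal in transcription direction plus its genomic interval."""

    index: int
    genomic_start: int
    genomic_end: int

    def __post_init__(self) -> None:
        if self.genomic_end <= self.genomic_start:
            raise ModelValidationError(
                f"exon {self.index}: empty interval "
                f"[{self.genomic_start}, {self.genomic_end})"
            )

    @property
    def length(self) -> int:
        return self.genomic_end - self.genomic_start

    @property
    def interval(self) -> tuple[int, int]:
        return (self.genomic_start, self.genomic_end)


@dataclass(frozen=True)
class Junction:
    """A splice junction, i.e. an excised intron interval on the genomic axis.

    ``status`` and ``label`` are annotations and do not take part in
    equality/hashing: two junctions are the same junction iff they remove
    the same genomic interval.
    """

    donor_pos: int
    acceptor_pos: int
    status: str = field(default="novel", compare=False)
    label: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.acceptor_pos <= self.donor_pos:
            raise ModelValidationError(
                f"junction interval [{self.donor_pos}, {self.acceptor_pos}) is empty"
            )

    @property
    def interval(self) -> tuple[int, int]:
        return (self.donor_pos, self.acceptor_pos)

    @property
    def length(self) -> int:
        return self.acceptor_pos - self.donor_pos


@dataclass(frozen=True)
class IntronicPosition:
    """A genomic position falling inside intron ``intron`` (1-based ordinal,
    intron i separates exon i from exon i+1), ``offset`` nt from the intron's
    5' end in transcription direction."""

    intron: int
    offset: int


class TranscriptModel:
    """Ordered exon structure of a single transcript isoform.

    Parameters
    ----------
    name:
        Transcript identifier.
    chrom:
        Reference sequence name.
    strand:
        ``'+'`` or ``'-'``.
    exons:
        Exons in transcription direction (exon 1 first).
    cds_start_mrna:
        0-based mRNA offset of the first codon; positions upstream are 5'UTR.
    """

    def __init__(
        self,
        name: str,
        chrom: str,
        strand: str,
        exons: Sequence[Exon],
        cds_start_mrna: int = 0,
    ) -> None:
        if strand not in ("+", "-"):
            raise ModelValidationError(f"strand must be '+' or '-', got {strand!r}")
        exons = tuple(exons)
        if not exons:
            raise ModelValidationError("a transcript needs at least one exon")
        for k, ex in enumerate(exons, start=1):
            if ex.index != k:
                raise ModelValidationError(
                    f"exon indices must be 1..n in transcription order; "
                    f"position {k} holds index {ex.index}"
                )
        for prev, nxt in zip(exons, exons[1:]):
            if strand == "+":
                gap = nxt.genomic_start - prev.genomic_end
            else:
                gap = prev.genomic_start - nxt.genomic_end
            if gap < 1:
                raise ModelValidationError(
                    f"exons {prev.index} and {nxt.index} overlap or touch "
                    f"(intron length {gap} < 1)"
                )
        self.name = name
        self.chrom = chrom
        self.strand = strand
        self.exons = exons
        self.cds_start_mrna = cds_start_mrna
        # cumulative mRNA offsets: exon i occupies [_cum[i-1], _cum[i])
        self._cum = [0]
        for ex in exons:
            self._cum.append(self._cum[-1] + ex.length)
        if not 0 <= cds_start_mrna <= self.mrna_length:
            raise ModelValidationError(
                f"cds_start_mrna {cds_start_mrna} outside mRNA [0, {self.mrna_length}]"
            )
        # plus-strand sorted exon list for coordinate lookups
        self._plus_sorted = sorted(exons, key=lambda e: e.genomic_start)
        self._plus_starts = [e.genomic_start for e in self._plus_sorted]

    # ------------------------------------------------------------------ basics

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def mrna_length(self) -> int:
        return self._cum[-1]

    @property
    def span(self) -> tuple[int, int]:
        """Genomic [min, max) interval covered by the transcript."""
        return (self._plus_sorted[0].genomic_start, self._plus_sorted[-1].genomic_end)

    def exon_mrna_span(self, index: int) -> tuple[int, int]:
        """mRNA interval occupied by exon ``index`` (1-based)."""
        return (self._cum[index - 1], self._cum[index])

    def introns(self) -> list[tuple[int, int]]:
        """Plus-strand genomic intervals of the introns, in transcription order."""
        out = []
        for prev, nxt in zip(self.exons, self.exons[1:]):
            if self.strand == "+":
                out.append((prev.genomic_end, nxt.genomic_start))
            else:
                out.append((nxt.genomic_end, prev.genomic_start))
        return out

    def donor_site(self, intron: int) -> int:
        """Genomic coordinate of the donor end of intron ``intron`` (1-based).

        For the plus strand this is the interval start (= end of the upstream
        exon); for the minus strand the interval end.
        """
        s, e = self.introns()[intron - 1]
        return s if self.strand == "+" else e

    def acceptor_site(self, intron: int) -> int:
        s, e = self.introns()[intron - 1]
        return e if self.strand == "+" else s

    # ------------------------------------------------- coordinate conversion

    def exon_containing(self, gpos: int) -> Exon | None:
        i = bisect_right(self._plus_starts, gpos) - 1
        if i >= 0 and gpos < self._plus_sorted[i].genomic_end:
            return self._plus_sorted[i]
        return None

    def genome_to_mrna(self, gpos: int) -> int | IntronicPosition:
        """Map a genomic position to an mRNA offset, or flag it intronic.

        Raises ``ValueError`` for positions outside the transcript span.
        """
        lo, hi = self.span
        if not lo <= gpos < hi:
            raise ValueError(f"{gpos} outside transcript span [{lo}, {hi})")
        ex = self.exon_containing(gpos)
        if ex is not None:
            base = self._cum[ex.index - 1]
            if self.strand == "+":
                return base + (gpos - ex.genomic_start)
            return base + (ex.genomic_end - 1 - gpos)
        for ordinal, (s, e) in enumerate(self.introns(), start=1):
            if s <= gpos < e:
                offset = gpos - s if self.strand == "+" else e - 1 - gpos
                return IntronicPosition(ordinal, offset)
        raise ValueError(f"{gpos} not locatable within transcript {self.name}")

    def mrna_to_genome(self, mpos: int) -> int:
        if not 0 <= mpos < self.mrna_length:
            raise ValueError(f"mRNA position {mpos} outside [0, {self.mrna_length})")
        i = bisect_right(self._cum, mpos) - 1
        ex = self.exons[i]
        off = mpos - self._cum[i]
        if self.strand == "+":
            return ex.genomic_start + off
        return ex.genomic_end - 1 - off

    # ------------------------------------------------------------- sequences

    def exon_sequence(self, index: int, genome: str) -> str:
        """Exon sequence in transcription orientation."""
        ex = self.exons[index - 1]
        seq = genome[ex.genomic_start : ex.genomic_end]
        return seq if self.strand == "+" else revcomp(seq)

    def mrna_sequence(self, genome: str) -> str:
        return "".join(self.exon_sequence(i, genome) for i in range(1, self.n_exons + 1))

    def transcribed_slice(self, gstart: int, gend: int, genome: str) -> str:
        """Genomic interval [gstart, gend) read in transcription orientation."""
        seq = genome[gstart:gend]
        return seq if self.strand == "+" else revcomp(seq)

    def map_mrna_interval(self, m0: int, m1: int) -> list[tuple[int, int]]:
        """Plus-strand-sorted genomic blocks covered by mRNA interval [m0, m1)."""
        if not 0 <= m0 < m1 <= self.mrna_length:
            raise ValueError(f"mRNA interval [{m0}, {m1}) outside [0, {self.mrna_length})")
        out = []
        for ex in self.exons:
            lo = max(m0, self._cum[ex.index - 1])
            hi = min(m1, self._cum[ex.index])
            if lo < hi:
                base = self._cum[ex.index - 1]
                if self.strand == "+":
                    out.append((ex.genomic_start + lo - base, ex.genomic_start + hi - base))
                else:
                    out.append((ex.genomic_end - (hi - base), ex.genomic_end - (lo - base)))
        return sorted(out)


def derive_canonical_junctions(model: TranscriptModel) -> list[Junction]:
    """The n_exons − 1 junctions joining consecutive exons of the model.

    A single-exon model yields an empty list.  Labels follow the
    ``ex{i}-ex{i+1}`` convention in transcription order.
    """
    out = []
    for i, (s, e) in enumerate(model.introns(), start=1):
        out.append(Junction(s, e, status="canonical", label=f"ex{i}-ex{i + 1}"))
    return out


# --------------------------------------------------------------------- parsers


def _parse_gtf_attributes(attr: str) -> dict[str, str]:
    out = {}
    for part in attr.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if " " in part:
            key, _, val = part.partition(" ")
            out[key] = val.strip().strip('"')
    return out


def _load_gtf(path: Path, transcript_id: str) -> TranscriptModel:
    exon_rows: list[tuple[str, int, int, str]] = []
    cds_rows: list[tuple[int, int]] = []
    found = False
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ModelValidationError(f"malformed GTF line: {line[:80]!r}")
            chrom, _, feature, start, end, _, strand, _, attrs = fields[:9]
            parsed = _parse_gtf_attributes(attrs)
            if parsed.get("transcript_id") != transcript_id:
                continue
            found = True
            # GTF is 1-based inclusive; convert to 0-based half-open here
            s, e = int(start) - 1, int(end)
            if feature == "exon":
                exon_rows.append((chrom, s, e, strand))
            elif feature == "CDS":
                cds_rows.append((s, e))
    if not found:
        raise TranscriptNotFoundError(f"transcript {transcript_id!r} not found in {path}")
    if not exon_rows:
        raise ModelValidationError(f"transcript {transcript_id!r} has no exon records")
    chrom = exon_rows[0][0]
    strand = exon_rows[0][3]
    intervals = sorted((s, e) for _, s, e, _ in exon_rows)
    if strand == "-":
        intervals = intervals[::-1]
    exons = [Exon(i, s, e) for i, (s, e) in enumerate(intervals, start=1)]
    model = TranscriptModel(transcript_id, chrom, strand, exons)
    if cds_rows:
        if strand == "+":
            first_cds = min(s for s, _ in cds_rows)
        else:
            first_cds = max(e for _, e in cds_rows) - 1
        pos = model.genome_to_mrna(first_cds)
        if isinstance(pos, int):
            model = TranscriptModel(transcript_id, chrom, strand, exons, cds_start_mrna=pos)
    return model


def _load_bed12(path: Path, transcript_id: str) -> TranscriptModel:
    with open(path) as fh:
        for line in fh:
            if line.startswith(("#", "track", "browser")) or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 12:
                raise ModelValidationError(
                    f"BED12 requires 12 columns, got {len(fields)}: {line[:80]!r}"
                )
            if fields[3] != transcript_id:
                continue
            chrom, chrom_start = fields[0], int(fields[1])
            strand = fields[5]
            thick_start, thick_end = int(fields[6]), int(fields[7])
            n_blocks = int(fields[9])
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise ModelValidationError(
                    f"blockCount={n_blocks} but {len(sizes)} sizes / {len(starts)} starts"
                )
            intervals = [
                (chrom_start + st, chrom_start + st + sz) for st, sz in zip(starts, sizes)
            ]
            if strand == "-":
                intervals = intervals[::-1]
            exons = [Exon(i, s, e) for i, (s, e) in enumerate(intervals, start=1)]
            model = TranscriptModel(transcript_id, chrom, strand, exons)
            if thick_end > thick_start:
                gpos = thick_start if strand == "+" else thick_end - 1
                pos = model.genome_to_mrna(gpos)
                if isinstance(pos, int):
                    model = TranscriptModel(
                        transcript_id, chrom, strand, exons, cds_start_mrna=pos
                    )
            return model
    raise TranscriptNotFoundError(f"transcript {transcript_id!r} not found in {path}")


def load_transcript_model(path: str | Path, transcript_id: str) -> TranscriptModel:
    """Load one transcript from a GTF or BED12 annotation file.

    The format is chosen by extension (``.gtf``/``.gff`` vs ``.bed``); other
    extensions are sniffed from the first data line.  Exons are re-ordered
    into transcription direction regardless of file order.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".gtf", ".gff", ".gff3"):
        return _load_gtf(path, transcript_id)
    if suffix == ".bed":
        return _load_bed12(path, transcript_id)
    with open(path) as fh:
        for line in fh:
            if line.startswith(("#", "track", "browser")) or not line.strip():
                continue
            n = len(line.split("\t"))
            return (_load_gtf if n == 9 else _load_bed12)(path, transcript_id)
    raise ModelValidationError(f"{path} contains no data lines")


def write_junctions_bed(
    model: TranscriptModel, junctions: Iterable[Junction], path: str | Path
) -> None:
    """Write junctions (one intron interval per line) as BED6."""
    with open(path, "w") as fh:
        for j in junctions:
            fh.write(
                f"{model.chrom}\t{j.donor_pos}\t{j.acceptor_pos}\t"
                f"{j.label or j.status}\t0\t{model.strand}\n"
            )


def write_transcript_gtf(model: TranscriptModel, path: str | Path) -> None:
    """Write the model as GTF (exon records plus CDS records from cds_start)."""
    with open(path, "w") as fh:
        attrs = f'gene_id "{model.name}"; transcript_id "{model.name}";'
        for ex in model.exons:
            fh.write(
                f"{model.chrom}\tsplicescope\texon\t{ex.genomic_start + 1}\t"
                f"{ex.genomic_end}\t.\t{model.strand}\t.\t{attrs}\n"
            )
        if model.cds_start_mrna < model.mrna_length:
            for s, e in model.map_mrna_interval(model.cds_start_mrna, model.mrna_length):
                fh.write(
                    f"{model.chrom}\tsplicescope\tCDS\t{s + 1}\t{e}\t.\t"
                    f"{model.strand}\t.\t{attrs}\n"
                )


# --------------------------------------------------------------- fixture model

#: exon lengths (nt) pinned in the synthetic Dp427m-like model: the two
#: microexons (71: 39 nt, 78: 32 nt), frame-neutral lengths for the exons
#: whose in-frame skipping is modelled (9, 73, 74), and room for the
#: alternative 3'ss offsets on exons 20 (−2), 54 (−3), 76 (−60), 78 (−4).
DP427M_PINNED_EXON_LENGTHS: dict[int, int] = {
    1: 250,
    9: 150,
    20: 120,
    54: 96,
    71: 39,
    73: 123,
    74: 90,
    76: 120,
    78: 32,
}

#: introns widened to host the three modelled pseudoexons (1a, 21X, 51X).
DP427M_WIDE_INTRONS: dict[int, int] = {1: 1200, 21: 800, 51: 900}


def build_dp427m_like_model(
    n_exons: int = 79,
    strand: str = "+",
    chrom: str = "synthX",
    seed: int = 7,
    exon_lengths: dict[int, int] | None = None,
    intron_length: int = 300,
    intron_lengths: dict[int, int] | None = None,
    cds_start_mrna: int = 100,
    genomic_offset: int = 1000,
) -> TranscriptModel:
    """Construct a synthetic 79-exon transcript model shaped like the muscle
    dystrophin isoform (Dp427m).

    The real exon-length vector is not bundled; lengths are drawn
    reproducibly from a seeded RNG (uniform 60–229 nt, mean ≈ 145 so that 79
    exons total ≈ 11.4 kb) and then overridden by
    :data:`DP427M_PINNED_EXON_LENGTHS` plus any caller-supplied
    ``exon_lengths``.  The model is explicitly synthetic: only the handful of
    published lengths and splice-site offsets are pinned.
    """
    rng = np.random.default_rng(seed)
    lengths = {i: int(v) for i, v in enumerate(rng.integers(60, 230, n_exons), start=1)}
    for i, v in DP427M_PINNED_EXON_LENGTHS.items():
        if i <= n_exons:
            lengths[i] = v
    if exon_lengths:
        lengths.update({i: v for i, v in exon_lengths.items() if i <= n_exons})
    ilens = {i: intron_length for i in range(1, n_exons)}
    for i, v in DP427M_WIDE_INTRONS.items():
        if i < n_exons:
            ilens[i] = v
    if intron_lengths:
        ilens.update({i: v for i, v in intron_lengths.items() if i < n_exons})

    exons = []
    if strand == "+":
        pos = genomic_offset
        for i in range(1, n_exons + 1):
            exons.append(Exon(i, pos, pos + lengths[i]))
            pos += lengths[i] + ilens.get(i, 0)
    else:
        total = sum(lengths.values()) + sum(ilens[i] for i in range(1, n_exons))
        pos = genomic_offset + total
        for i in range(1, n_exons + 1):
            exons.append(Exon(i, pos - lengths[i], pos))
            pos -= lengths[i] + ilens.get(i, 0)
    cds = min(cds_start_mrna, sum(lengths.values()))
    return TranscriptModel("Dp427m-like", chrom, strand, exons, cds_start_mrna=cds)
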