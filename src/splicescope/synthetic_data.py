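"""Synthetic 454-style amplicon data for a single long transcript.

Two simulation paths are provided.  The read-level path emulates the study
conditions of the targeted dystrophin (Dp427m) amplicon libraries: four
replicate skeletal-muscle libraries of ~69,060 shotgun reads of ~387 bp mean
length drawn from an isoform mixture, written as FASTA plus a truth SAM with
``N`` CIGAR gaps over every crossed intron.  The count-level fast path skips
reads entirely and draws per-junction counts binomially at the configured
event rates.

The default event set reproduces the twelve low-level alternative splicing
events reported for the muscle dystrophin transcript (five exon skips, three
pseudoexons, four exonic alternative 3'ss) at their published ASE rates.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pysam
import yaml
from scipy.stats import truncnorm

from .junction_calling import JunctionCountTable
from .transcript_model import (
    Junction,
    TranscriptModel,
    derive_canonical_junctions,
    revcomp,
)

__all__ = [
    "EventSpec",
    "SimConfig",
    "TruthRecord",
    "Isoform",
    "dp427m_reference_events",
    "decoy_skip_events",
    "event_junctions",
    "competing_introns",
    "build_fixture_genome",
    "simulate_isoform_mixture",
    "simulate_reads",
    "simulate_junction_counts",
    "inject_misalignment_artifact",
]

CATEGORIES = ("exon_skip", "pseudoexon", "alt3ss", "alt5ss")


class SimulationConfigError(ValueError):
    """Inconsistent event set or simulation configuration."""


@dataclass(frozen=True)
class EventSpec:
    """One alternative splicing event to simulate.

    ``rate`` is the fraction of transcript molecules carrying the event:
    for exon skipping and alternative splice sites this equals ASE% / 100
    (= 1 − PSI), for pseudoexon inclusion it equals PSI.
    """

    event_id: str
    category: str
    rate: float
    skip_exons: tuple[int, ...] = ()
    pe_intron: int = 0
    pe_interval: tuple[int, int] | None = None  # plus-strand genomic [A, B)
    exon: int = 0  # host exon of an alternative splice site
    offset_nt: int = 0  # signed; negative = exonic truncation
    insert_stop: bool = False  # cryptic exon carries an in-frame stop codon
    strong_alt_site: bool = False  # plant a near-consensus alternative site

    def validate(self, model: TranscriptModel) -> None:
        if self.category not in CATEGORIES:
            raise SimulationConfigError(f"unknown category {self.category!r}")
        if not 0.0 <= self.rate <= 1.0:
            raise SimulationConfigError(f"{self.event_id}: rate {self.rate} outside [0, 1]")
        if self.category == "exon_skip":
            ks = self.skip_exons
            if not ks or ks != tuple(range(ks[0], ks[-1] + 1)):
                raise SimulationConfigError(
                    f"{self.event_id}: skip_exons must be a contiguous run, got {ks}"
                )
            if ks[0] < 2 or ks[-1] > model.n_exons - 1:
                raise SimulationConfigError(
                    f"{self.event_id}: cannot skip terminal exons {ks}"
                )
        elif self.category == "pseudoexon":
            if not 1 <= self.pe_intron <= model.n_exons - 1 or self.pe_interval is None:
                raise SimulationConfigError(f"{self.event_id}: invalid pseudoexon definition")
            s, e = model.introns()[self.pe_intron - 1]
            a, b = self.pe_interval
            if not (s < a < b < e):
                raise SimulationConfigError(
                    f"{self.event_id}: interval {self.pe_interval} not strictly inside "
                    f"intron {self.pe_intron} [{s}, {e})"
                )
        else:
            if not 1 <= self.exon <= model.n_exons:
                raise SimulationConfigError(f"{self.event_id}: exon {self.exon} absent")
            if self.offset_nt == 0:
                raise SimulationConfigError(f"{self.event_id}: offset must be non-zero")
            if -self.offset_nt >= model.exons[self.exon - 1].length:
                raise SimulationConfigError(
                    f"{self.event_id}: offset {self.offset_nt} exhausts exon {self.exon}"
                )

    @property
    def pe_length(self) -> int:
        if self.pe_interval is None:
            return 0
        return self.pe_interval[1] - self.pe_interval[0]


@dataclass(frozen=True)
class SimConfig:
    """Read-level simulation parameters.

    Defaults emulate one 454 amplicon library of the study design: 69,060
    reads of mean length 387 nt (truncated normal, SD 120, minimum 40 nt)
    per replicate, 4 replicates.  Error rates default to a modest 454-like
    regime: 0.1% substitutions plus occasional single-base indels at
    homopolymer runs of length >= 4.
    """

    n_samples: int = 4
    reads_per_sample: int = 69_060
    read_length_mean: float = 387.0
    read_length_sd: float = 120.0
    min_read_length: int = 40
    error_rate: float = 0.001
    homopolymer_indel_rate: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        for name in ("error_rate", "homopolymer_indel_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationConfigError(f"{name} = {v} outside [0, 1]")
        if self.n_samples < 1 or self.reads_per_sample < 1:
            raise SimulationConfigError("need at least one sample and one read")
        if self.read_length_mean < self.min_read_length:
            raise SimulationConfigError("mean read length below the minimum length")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=True)


@dataclass
class TruthRecord:
    """Ground truth of a simulation run."""

    junction_counts: dict[str, Counter] = field(default_factory=dict)
    read_isoform: dict[str, str] = field(default_factory=dict)
    event_counts: dict[str, dict[str, int]] = field(default_factory=dict)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("sample\tstart\tend\tcount\n")
            for sample in sorted(self.junction_counts):
                for (d, a), n in sorted(self.junction_counts[sample].items()):
                    fh.write(f"{sample}\t{d}\t{a}\t{n}\n")


@dataclass(frozen=True)
class Isoform:
    """A spliced isoform as plus-strand-sorted genomic blocks."""

    name: str
    blocks: tuple[tuple[int, int], ...]
    strand: str
    weight: float
    events: tuple[str, ...] = ()

    @property
    def mrna_length(self) -> int:
        return sum(e - s for s, e in self.blocks)

    def junction_intervals(self) -> list[tuple[int, int]]:
        return [(a[1], b[0]) for a, b in zip(self.blocks, self.blocks[1:])]

    def sequence(self, genome: str) -> str:
        seq = "".join(genome[s:e] for s, e in self.blocks)
        return seq if self.strand == "+" else revcomp(seq)

    def map_mrna_interval(self, m0: int, m1: int) -> list[tuple[int, int]]:
        """Plus-strand genomic blocks covered by mRNA interval [m0, m1)."""
        if not 0 <= m0 < m1 <= self.mrna_length:
            raise ValueError(f"mRNA interval [{m0}, {m1}) outside [0, {self.mrna_length})")
        walk = self.blocks if self.strand == "+" else self.blocks[::-1]
        out = []
        pos = 0
        for s, e in walk:
            blen = e - s
            lo, hi = max(m0, pos), min(m1, pos + blen)
            if lo < hi:
                if self.strand == "+":
                    out.append((s + lo - pos, s + hi - pos))
                else:
                    out.append((e - (hi - pos), e - (lo - pos)))
            pos += blen
        return sorted(out)


# ------------------------------------------------------------- event geometry


def event_junctions(model: TranscriptModel, spec: EventSpec) -> list[Junction]:
    """The novel junction(s) realizing an event, in transcription order."""
    introns = model.introns()
    if spec.category == "exon_skip":
        k, m = spec.skip_exons[0], spec.skip_exons[-1]
        if model.strand == "+":
            d, a = introns[k - 2][0], introns[m - 1][1]
        else:
            d, a = introns[m - 1][0], introns[k - 2][1]
        return [Junction(d, a, label=spec.event_id)]
    if spec.category == "pseudoexon":
        s, e = introns[spec.pe_intron - 1]
        a, b = spec.pe_interval
        if model.strand == "+":
            return [
                Junction(s, a, label=f"{spec.event_id}.acc"),
                Junction(b, e, label=f"{spec.event_id}.don"),
            ]
        return [
            Junction(b, e, label=f"{spec.event_id}.acc"),
            Junction(s, a, label=f"{spec.event_id}.don"),
        ]
    if spec.category == "alt3ss":
        s, e = introns[spec.exon - 2]
        if model.strand == "+":
            return [Junction(s, e - spec.offset_nt, label=spec.event_id)]
        return [Junction(s + spec.offset_nt, e, label=spec.event_id)]
    if spec.category == "alt5ss":
        s, e = introns[spec.exon - 1]
        if model.strand == "+":
            return [Junction(s + spec.offset_nt, e, label=spec.event_id)]
        return [Junction(s, e - spec.offset_nt, label=spec.event_id)]
    raise SimulationConfigError(f"unknown category {spec.category!r}")


def competing_introns(spec: EventSpec) -> tuple[int, ...]:
    """Ordinals of the canonical introns whose junctions compete with the event."""
    if spec.category == "exon_skip":
        return (spec.skip_exons[0] - 1, spec.skip_exons[-1])
    if spec.category == "pseudoexon":
        return (spec.pe_intron,)
    if spec.category == "alt3ss":
        return (spec.exon - 1,)
    return (spec.exon,)


def _apply_event_to_blocks(
    model: TranscriptModel, blocks: list[tuple[int, int]], spec: EventSpec
) -> list[tuple[int, int]]:
    if spec.category == "exon_skip":
        drop = {model.exons[k - 1].interval for k in spec.skip_exons}
        return [b for b in blocks if b not in drop]
    if spec.category == "pseudoexon":
        return sorted(blocks + [spec.pe_interval])
    ex = model.exons[spec.exon - 1]
    out = []
    for b in blocks:
        if b == ex.interval:
            s, e = b
            if spec.category == "alt3ss":
                b = (s - spec.offset_nt, e) if model.strand == "+" else (s, e + spec.offset_nt)
            else:
                b = (s, e + spec.offset_nt) if model.strand == "+" else (s - spec.offset_nt, e)
        out.append(b)
    return out


# -------------------------------------------------------------- default events


def dp427m_reference_events(model: TranscriptModel) -> list[EventSpec]:
    """The twelve muscle events at their published mean ASE rates.

    Pseudoexons are placed a few hundred nt into their (synthetic) host
    introns; sizes (162/66/84 nt) and alternative 3'ss offsets
    (−2/−3/−60/−4 nt) are the published ones.
    """

    def pe_interval(intron: int, txn_offset: int, length: int) -> tuple[int, int]:
        s, e = model.introns()[intron - 1]
        if model.strand == "+":
            return (s + txn_offset, s + txn_offset + length)
        return (e - txn_offset - length, e - txn_offset)

    events = [
        EventSpec("del9", "exon_skip", 0.0063, skip_exons=(9,)),
        EventSpec("del71", "exon_skip", 0.0180, skip_exons=(71,)),
        EventSpec("del73", "exon_skip", 0.0032, skip_exons=(73,)),
        EventSpec("del74", "exon_skip", 0.0049, skip_exons=(74,)),
        EventSpec("del78", "exon_skip", 0.0248, skip_exons=(78,)),
        EventSpec(
            "PE1a", "pseudoexon", 0.0306,
            pe_intron=1, pe_interval=pe_interval(1, 400, 162), insert_stop=True,
        ),
        EventSpec(
            "PE21X", "pseudoexon", 0.0040, pe_intron=21, pe_interval=pe_interval(21, 300, 66)
        ),
        EventSpec(
            "PE51X", "pseudoexon", 0.0021, pe_intron=51, pe_interval=pe_interval(51, 350, 84)
        ),
        EventSpec("3ss_ex20", "alt3ss", 0.0018, exon=20, offset_nt=-2),
        EventSpec("3ss_ex54", "alt3ss", 0.0112, exon=54, offset_nt=-3),
        EventSpec("3ss_ex76", "alt3ss", 0.0033, exon=76, offset_nt=-60, strong_alt_site=True),
        EventSpec("3ss_ex78", "alt3ss", 0.0043, exon=78, offset_nt=-4),
    ]
    for ev in events:
        ev.validate(model)
    return events


def decoy_skip_events(
    model: TranscriptModel,
    n: int = 20,
    rate_low: float = 0.0001,
    rate_high: float = 0.0005,
    avoid_exons: Sequence[int] = (),
) -> list[EventSpec]:
    """Single-exon skip decoys at sub-threshold rates, for specificity checks.

    Rates are spread evenly over [rate_low, rate_high]; exons in
    ``avoid_exons`` (and the terminal exons) are never used.
    """
    blocked = set(avoid_exons)
    candidates = [k for k in range(2, model.n_exons) if k not in blocked]
    if len(candidates) < n:
        raise SimulationConfigError("not enough exons for the requested decoys")
    rates = np.linspace(rate_low, rate_high, n)
    out = [
        EventSpec(f"decoy_del{k}", "exon_skip", float(r), skip_exons=(k,))
        for k, r in zip(candidates[:n], rates)
    ]
    for ev in out:
        ev.validate(model)
    return out


# -------------------------------------------------------------- fixture genome

_PY = "CTCTTCTTCCTT"  # pyrimidine-rich filler for acceptor tracts


def build_fixture_genome(
    model: TranscriptModel,
    events: Sequence[EventSpec] = (),
    seed: int = 11,
    nagnag_exon: int | None = 54,
) -> str:
    """Random genome for the fixture model with splice-site features planted.

    Every intron gets GT..AG boundaries and a pyrimidine-rich acceptor
    tract; pseudoexon intervals get their own AG/GT boundaries, a stop-free
    {C,A} interior (plus one in-frame TAA when ``insert_stop`` is set); the
    acceptor of ``nagnag_exon`` is made a NAGNAG tandem (CAGCAG) while all
    other acceptors are kept NAGNAG-free; exonic alternative 3'ss get an AG
    immediately upstream of the alternative acceptor.  Built on the
    transcription strand and reverse-complemented at the end for
    minus-strand models, so all coordinates below are transcription-axis.
    """
    lo, hi = model.span
    glen = hi + max(500, lo)
    rng = np.random.default_rng(seed)
    txn = list(rng.choice(list("ACGT"), size=glen))

    def t(gpos: int) -> int:
        """plus-strand genomic -> transcription-axis coordinate"""
        return gpos if model.strand == "+" else glen - 1 - gpos

    def t_iv(gstart: int, gend: int) -> tuple[int, int]:
        if model.strand == "+":
            return gstart, gend
        return glen - gend, glen - gstart

    def put(pos: int, seq: str) -> None:
        txn[pos : pos + len(seq)] = list(seq)

    def plant_acceptor(site: int, strong: bool = True) -> None:
        """AG ending at transcription-axis position ``site`` plus a tract."""
        tract = _PY if strong else "AAGAAGAAAGAA"
        put(site - 14, tract)
        put(site - 2, "AG")

    def plant_donor(site: int) -> None:
        """GT starting at transcription-axis position ``site``."""
        put(site, "GTAAGT")

    # canonical splice sites
    for i, (s, e) in enumerate(model.introns(), start=1):
        ts, te = t_iv(s, e)
        plant_donor(ts)
        plant_acceptor(te)
    # keep exon openings NAGNAG-free, then plant the one tandem site
    for ex in model.exons[1:]:
        ts, te = t_iv(ex.genomic_start, ex.genomic_end)
        if ex.index == nagnag_exon:
            put(ts, "CAG")
        elif txn[ts + 1] == "A" and txn[ts + 2] == "G":
            put(ts + 2, "C")

    for ev in events:
        if ev.category == "pseudoexon":
            ta, tb = t_iv(*ev.pe_interval)
            interior = "CC" + "".join(rng.choice(list("CA"), size=ev.pe_length - 2))
            if ev.insert_stop:
                # first full codon of the insertion, given the insertion point
                m = model.exon_mrna_span(ev.pe_intron)[1]
                phase = (m - model.cds_start_mrna) % 3
                off = (3 - phase) % 3 + 3
                interior = interior[:off] + "TAA" + interior[off + 3 :]
            put(ta, interior)
            plant_acceptor(ta)
            plant_donor(tb)
        elif ev.category == "alt3ss" and ev.offset_nt < 0:
            ex = model.exons[ev.exon - 1]
            ts, _ = t_iv(ex.genomic_start, ex.genomic_end)
            alt = ts - ev.offset_nt  # transcription-axis alt acceptor
            if ev.strong_alt_site:
                plant_acceptor(alt, strong=True)
                # make the natural acceptor comparatively weak (but intact)
                plant_acceptor(ts, strong=False)
            else:
                # minimal AG only: small offsets sit too close to the
                # natural acceptor for a full tract of their own
                put(alt - 2, "AG")
    out = "".join(txn)
    return out if model.strand == "+" else revcomp(out)


def inject_misalignment_artifact(
    model: TranscriptModel,
    genome: str,
    intron_ordinal: int,
    repeat_length: int,
) -> tuple[str, tuple[int, int]]:
    """Plant an exact repeat straddling a canonical junction.

    Copies ``repeat_length`` bases from the start of the intron interval over
    the bases at its end, making the junction placement shift-ambiguous.
    Returns the modified genome and the resulting (min_shift, max_shift)
    range established by direct string comparison.
    """
    s, e = model.introns()[intron_ordinal - 1]
    down_exon = model.exon_containing(e)
    if down_exon is None or repeat_length > down_exon.length:
        raise ValueError(f"repeat length {repeat_length} exceeds the flanking exon")
    if repeat_length >= e - s:
        raise ValueError("repeat must be shorter than the intron")
    g = list(genome)
    g[e : e + repeat_length] = genome[s : s + repeat_length]
    g2 = "".join(g)
    right = 0
    while e + right < len(g2) and g2[s + right] == g2[e + right]:
        right += 1
    left = 0
    while s - left - 1 >= 0 and g2[s - left - 1] == g2[e - left - 1]:
        left += 1
    return g2, (-left, right)


# ------------------------------------------------------------------ simulators


def simulate_isoform_mixture(
    model: TranscriptModel, events: Sequence[EventSpec], seed: int | None = None
) -> list[Isoform]:
    """Canonical isoform plus one single-event isoform per event.

    Weights are the event rates with the canonical isoform absorbing the
    remainder; events competing for the same intron may not sum above 1.
    The ``seed`` argument is accepted for interface symmetry; the mixture
    itself is deterministic.
    """
    per_intron: Counter = Counter()
    for ev in events:
        ev.validate(model)
        for i in competing_introns(ev):
            per_intron[i] += ev.rate
    for i, total in per_intron.items():
        if total > 1.0 + 1e-9:
            raise SimulationConfigError(
                f"rates at intron {i} sum to {total:.4f} > 1"
            )
    total_rate = sum(ev.rate for ev in events)
    if total_rate > 1.0 + 1e-9:
        raise SimulationConfigError(f"event rates sum to {total_rate:.4f} > 1")
    canonical_blocks = sorted(ex.interval for ex in model.exons)
    out = [
        Isoform("canonical", tuple(canonical_blocks), model.strand, 1.0 - total_rate)
    ]
    for ev in events:
        blocks = _apply_event_to_blocks(model, canonical_blocks, ev)
        out.append(Isoform(ev.event_id, tuple(blocks), model.strand, ev.rate, (ev.event_id,)))
    return out


def _homopolymer_runs(seq: str, min_run: int = 4) -> list[tuple[int, int]]:
    runs = []
    i = 0
    while i < len(seq):
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        if j - i >= min_run:
            runs.append((i, j))
        i = j
    return runs


def _blocks_to_read(
    blocks: list[tuple[int, int]],
    genome: str,
    rng: np.random.Generator,
    error_rate: float,
    homopolymer_indel_rate: float,
) -> tuple[str, list[tuple[int, int]]]:
    """Plus-strand read sequence and CIGAR ops (pysam codes) for the blocks.

    Each reference base of a block is carried as (op, read characters): a
    substitution swaps the character, a homopolymer extension appends a
    duplicate (becoming a 1-base I op), a contraction drops the character
    (a 1-base D op).  Per-base ops are merged into a compact CIGAR at the
    end.
    """
    bases = "ACGT"
    cigar: list[tuple[int, int]] = []
    parts: list[str] = []
    for k, (s, e) in enumerate(blocks):
        if k > 0:
            cigar.append((3, s - blocks[k - 1][1]))  # N gap over the intron
        seq = genome[s:e]
        if homopolymer_indel_rate == 0:
            # fast path: ops stay pure M, only characters may change
            chars = list(seq)
            if error_rate > 0:
                n_err = rng.binomial(len(seq), error_rate)
                for pos in rng.integers(0, len(seq), size=int(n_err)):
                    orig = chars[pos]
                    if orig in bases:
                        chars[pos] = bases[(bases.index(orig) + int(rng.integers(1, 4))) % 4]
            parts.append("".join(chars))
            cigar.append((0, len(seq)))
            continue
        per: list[list] = [[0, c] for c in seq]  # [op, read chars] per ref base
        if homopolymer_indel_rate > 0:
            for rs, re_ in _homopolymer_runs(seq):
                if rng.random() >= homopolymer_indel_rate:
                    continue
                if rng.random() < 0.5:  # run extension: extra read base
                    per[re_ - 1][1] += seq[rs]
                else:  # run contraction: ref base unmatched
                    per[re_ - 1][0] = 2
                    per[re_ - 1][1] = ""
        if error_rate > 0:
            n_err = rng.binomial(len(seq), error_rate)
            for pos in rng.integers(0, len(seq), size=int(n_err)):
                if per[pos][0] == 0:
                    orig = per[pos][1][0]
                    if orig in bases:
                        sub = bases[(bases.index(orig) + int(rng.integers(1, 4))) % 4]
                        per[pos][1] = sub + per[pos][1][1:]
        for op, chars in per:
            if op == 2:
                cigar.append((2, 1))
            else:
                cigar.append((0, 1))
                if len(chars) > 1:
                    cigar.append((1, len(chars) - 1))
                parts.append(chars)
    return "".join(parts), _merge_ops(cigar)


def _merge_ops(ops: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for op, length in ops:
        if length <= 0:
            continue
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + length)
        else:
            out.append((op, length))
    return out


def simulate_reads(
    model: TranscriptModel,
    isoforms: Sequence[Isoform],
    genome: str,
    config: SimConfig,
    out_dir: str | Path,
    prefix: str = "sample",
) -> TruthRecord:
    """Write per-sample FASTA reads and truth SAM alignments.

    Read starts are uniform over each isoform's mRNA; lengths follow a
    truncated normal (clipped at the 3' end of the molecule).  The truth SAM
    carries genomic plus-strand alignments with an ``N`` operation per
    crossed intron, mapping quality 60, and FLAG 16 for minus-strand models.
    Deterministic for a fixed config (per-sample streams are derived from
    ``config.seed`` and the sample ordinal).
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    weights = np.array([iso.weight for iso in isoforms], dtype=float)
    if not math.isclose(weights.sum(), 1.0, abs_tol=1e-9):
        raise SimulationConfigError(f"isoform weights sum to {weights.sum()}, not 1")
    truth = TruthRecord()
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": model.chrom, "LN": len(genome)}],
    }
    flag = 0 if model.strand == "+" else 16
    a = (config.min_read_length - config.read_length_mean) / config.read_length_sd
    for s in range(1, config.n_samples + 1):
        rng = np.random.default_rng([config.seed, s])
        sample = f"{prefix}{s}"
        counts: Counter = Counter()
        truth.junction_counts[sample] = counts
        iso_idx = rng.choice(len(isoforms), size=config.reads_per_sample, p=weights)
        lengths = truncnorm.rvs(
            a,
            np.inf,
            loc=config.read_length_mean,
            scale=config.read_length_sd,
            size=config.reads_per_sample,
            random_state=rng,
        ).astype(int)
        fasta_path = out_dir / f"{sample}.fasta"
        sam_path = out_dir / f"{sample}.sam"
        with open(fasta_path, "w") as fa, pysam.AlignmentFile(
            str(sam_path), "wh", header=header
        ) as sam:
            for ridx in range(config.reads_per_sample):
                iso = isoforms[iso_idx[ridx]]
                start = int(rng.integers(0, iso.mrna_length))
                ln = max(1, min(int(lengths[ridx]), iso.mrna_length - start))
                blocks = iso.map_mrna_interval(start, start + ln)
                seq, cigar = _blocks_to_read(
                    blocks, genome, rng, config.error_rate, config.homopolymer_indel_rate
                )
                name = f"{sample}_r{ridx:06d}"
                truth.read_isoform[name] = iso.name
                for gap in zip(blocks, blocks[1:]):
                    counts[(gap[0][1], gap[1][0])] += 1
                rec = pysam.AlignedSegment(header=pysam.AlignmentHeader.from_dict(header))
                rec.query_name = name
                rec.flag = flag
                rec.reference_id = 0
                rec.reference_start = blocks[0][0]
                rec.mapping_quality = 60
                rec.cigartuples = cigar
                rec.query_sequence = seq
                sam.write(rec)
                fa.write(f">{name}\n{seq if model.strand == '+' else revcomp(seq)}\n")
    return truth


def simulate_junction_counts(
    model: TranscriptModel,
    events: Sequence[EventSpec],
    depth_per_junction: int,
    n_samples: int = 4,
    seed: int = 0,
) -> tuple[JunctionCountTable, TruthRecord]:
    """Fast count-level simulation bypassing reads.

    Per sample, each event's alternative junction count is Binomial(depth,
    rate); canonical junction counts start at ``depth`` and lose the
    alternative reads of every event competing at them.  Pseudoexon events
    assign the same draw to both of their junctions (long reads span the
    whole cryptic exon).
    """
    if depth_per_junction < 1:
        raise SimulationConfigError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    canonical = derive_canonical_junctions(model)
    samples = [f"sample{i}" for i in range(1, n_samples + 1)]
    canon_counts = {
        s: {i: depth_per_junction for i in range(1, model.n_exons)} for s in samples
    }
    table = JunctionCountTable(chrom=model.chrom, strand=model.strand)
    truth = TruthRecord()
    for ev in events:
        ev.validate(model)
        alts = rng.binomial(depth_per_junction, ev.rate, size=n_samples)
        truth.event_counts[ev.event_id] = dict(zip(samples, (int(x) for x in alts)))
        juncs = event_junctions(model, ev)
        for s, alt in zip(samples, alts):
            for j in juncs:
                if alt:
                    table.add(j.interval, s, int(alt))
            for i in competing_introns(ev):
                canon_counts[s][i] = max(0, canon_counts[s][i] - int(alt))
    for s in samples:
        for j, i in zip(canonical, range(1, model.n_exons)):
            table.add(j.interval, s, canon_counts[s][i])
        truth.junction_counts[s] = Counter(
            {j.interval: canon_counts[s][i] for j, i in zip(canonical, range(1, model.n_exons))}
        )
    return table, truth
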