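"""Intron-centric PSI / ASE% quantification and validation arithmetic.

PSI (percent spliced in) is computed from junction-spanning read counts
only.  For single-junction events (alternative splice sites) the alternative
junction competes with one canonical junction at the shared site:
``psi = i / (i + e)``.  For two-junction events the balanced form
``psi = (i1 + i2) / (i1 + i2 + 2e)`` is used, with the inclusion pair being
the flanking canonical junctions for an exon skip and the two cryptic-exon
junctions for a pseudoexon (the exclusion junction then being the unbroken
host intron).

ASE% converts PSI to the reported scale: ``(1 − PSI) × 100`` for exon
skipping and alternative splice sites, ``PSI × 100`` for pseudoexon
inclusion, so that ASE% always measures the abundance of the *alternative*
form.

The replicate-consistency filter admits an event only when its novel
junction reaches ``min_reads`` (inclusive) in at least ``min_samples``
replicates; a pseudoexon's per-sample support is conservatively the minimum
of its two junction counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .event_annotation import SplicingEvent
from .junction_calling import JunctionCountTable
from .transcript_model import TranscriptModel

__all__ = [
    "EventQuant",
    "compute_psi",
    "psi_to_ase_percent",
    "event_support",
    "replicate_filter",
    "summarize_across_samples",
    "quantify_events",
    "detection_limit",
    "expected_reads",
    "is_detectable",
    "isoform_ratio_from_peaks",
    "concordance_table",
]


@dataclass
class EventQuant:
    """Per-sample and summarized quantification of one event."""

    event_id: str
    category: str
    inclusion_reads: dict[str, int] = field(default_factory=dict)
    exclusion_reads: dict[str, int] = field(default_factory=dict)
    psi: dict[str, float | None] = field(default_factory=dict)
    ase_percent: dict[str, float | None] = field(default_factory=dict)
    support: dict[str, int] = field(default_factory=dict)
    passes_filter: bool = False
    mean_ase: float | None = None
    sd_ase: float | None = None


def _competing_canonical(event: SplicingEvent, model: TranscriptModel) -> list[tuple[int, int]]:
    introns = model.introns()
    if event.category == "exon_skip":
        return [introns[event.exons_skipped[0] - 2], introns[event.exons_skipped[-1] - 1]]
    if event.category == "pseudoexon":
        return [introns[event.pe_intron - 1]]
    if event.category == "alt3ss":
        return [introns[event.exon - 2]]
    if event.category == "alt5ss":
        return [introns[event.exon - 1]]
    raise ValueError(f"cannot quantify category {event.category!r}")


def compute_psi(
    event: SplicingEvent,
    counts: JunctionCountTable,
    sample_id: str,
    model: TranscriptModel,
) -> float | None:
    """Intron-centric PSI of one event in one sample; None when uncovered."""
    canon = _competing_canonical(event, model)
    if event.category in ("alt3ss", "alt5ss"):
        i = counts.get(canon[0], sample_id)
        e = counts.get(event.junctions[0].interval, sample_id)
        return i / (i + e) if i + e > 0 else None
    if event.category == "exon_skip":
        i1, i2 = (counts.get(c, sample_id) for c in canon)
        e = counts.get(event.junctions[0].interval, sample_id)
    else:  # pseudoexon: inclusion = the two cryptic junctions
        i1, i2 = (counts.get(j.interval, sample_id) for j in event.junctions)
        e = counts.get(canon[0], sample_id)
    denom = i1 + i2 + 2 * e
    return (i1 + i2) / denom if denom > 0 else None


def psi_to_ase_percent(category: str, psi: float) -> float:
    """Map PSI to the reported ASE percentage for the event category."""
    if not 0.0 <= psi <= 1.0:
        raise ValueError(f"psi {psi} outside [0, 1]")
    return psi * 100.0 if category == "pseudoexon" else (1.0 - psi) * 100.0


def event_support(
    event: SplicingEvent, counts: JunctionCountTable, sample_id: str
) -> int:
    """Per-sample read support of the event's novel junction(s).

    Pseudoexons take the minimum of their two junction counts.
    """
    values = [counts.get(j.interval, sample_id) for j in event.junctions]
    return min(values) if event.category == "pseudoexon" else values[0]


def replicate_filter(
    support_counts: Sequence[int], min_reads: int = 5, min_samples: int = 2
) -> bool:
    """True iff >= min_samples replicates reach min_reads (inclusive)."""
    return sum(c >= min_reads for c in support_counts) >= min_samples


def summarize_across_samples(values: Sequence[float]) -> tuple[float, float]:
    """Arithmetic mean and sample SD (n−1); SD is 0 for a single value."""
    vals = [v for v in values if v is not None]
    if not vals:
        raise ValueError("no defined values to summarize")
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    return mean, sd


def quantify_events(
    events: Iterable[SplicingEvent],
    counts: JunctionCountTable,
    model: TranscriptModel,
    min_reads: int = 5,
    min_samples: int = 2,
) -> list[EventQuant]:
    """PSI/ASE% per sample plus the filter verdict and cross-sample summary.

    Samples with undefined PSI (zero denominator) are excluded from the
    mean/SD, not imputed as zero.
    """
    samples = counts.samples
    out = []
    for ev in events:
        q = EventQuant(ev.event_id, ev.category)
        for s in samples:
            psi = compute_psi(ev, counts, s, model)
            q.psi[s] = psi
            q.ase_percent[s] = None if psi is None else psi_to_ase_percent(ev.category, psi)
            q.support[s] = event_support(ev, counts, s)
            if ev.category == "pseudoexon":
                q.inclusion_reads[s] = sum(counts.get(j.interval, s) for j in ev.junctions)
                q.exclusion_reads[s] = counts.get(
                    _competing_canonical(ev, model)[0], s
                )
            else:
                q.inclusion_reads[s] = sum(
                    counts.get(c, s) for c in _competing_canonical(ev, model)
                )
                q.exclusion_reads[s] = counts.get(ev.junctions[0].interval, s)
        q.passes_filter = replicate_filter(
            [q.support[s] for s in samples], min_reads, min_samples
        )
        defined = [v for v in q.ase_percent.values() if v is not None]
        if defined:
            q.mean_ase, q.sd_ase = summarize_across_samples(defined)
        out.append(q)
    return out


# ------------------------------------------------------------ detection limit


def detection_limit(mean_depth: float, min_reads: int = 10) -> float:
    """Smallest ASE% whose expected read support reaches ``min_reads``."""
    if mean_depth <= 0:
        raise ValueError("depth must be positive")
    return min_reads / mean_depth * 100.0


def expected_reads(ase_percent: float, mean_depth: float) -> float:
    """Expected junction reads for an event at ``ase_percent`` abundance."""
    return ase_percent / 100.0 * mean_depth


def is_detectable(ase_percent: float, mean_depth: float, min_reads: int = 10) -> bool:
    """Reliable detection requires the expected support to exceed min_reads."""
    return expected_reads(ase_percent, mean_depth) > min_reads


# --------------------------------------------------------- validation arithmetic


def isoform_ratio_from_peaks(peaks: pd.DataFrame) -> pd.DataFrame:
    """Fluorescent-peak-area isoform ratios, per replicate and summarized.

    ``peaks`` needs columns ``replicate``, ``isoform``, ``area``.  Per
    replicate, each isoform's ratio is its peak area over the total area of
    the detected isoforms, in percent (ratios sum to 100 exactly).
    Replicates whose total area is zero are dropped with a warning column.
    Returns a frame with per-replicate ratios plus ``mean``/``sd`` per
    isoform (sample SD, n−1).
    """
    required = {"replicate", "isoform", "area"}
    if not required <= set(peaks.columns):
        raise ValueError(f"peak table needs columns {sorted(required)}")
    if (peaks["area"] < 0).any():
        raise ValueError("peak areas must be non-negative")
    rows = []
    for rep, grp in peaks.groupby("replicate"):
        total = grp["area"].sum()
        if len(grp) < 2:
            raise ValueError(f"replicate {rep!r} has fewer than 2 isoforms")
        if total == 0:
            continue  # undefined: all-zero areas
        for _, r in grp.iterrows():
            rows.append(
                {"replicate": rep, "isoform": r["isoform"],
                 "ratio_percent": r["area"] / total * 100.0}
            )
    if not rows:
        raise ValueError("no replicate with a positive total peak area")
    per = pd.DataFrame(rows)
    summary = (
        per.groupby("isoform")["ratio_percent"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0, n="count")
        .reset_index()
    )
    per.attrs["summary"] = summary
    return per


def concordance_table(
    rnaseq: Mapping[str, tuple[float, float]],
    assays: Mapping[str, Mapping[str, tuple[float, float]]],
    precision: int = 2,
) -> pd.DataFrame:
    """Side-by-side ASE% means ± SD from sequencing and orthogonal assays.

    ``rnaseq`` maps event id -> (mean, sd); ``assays`` maps assay name to
    the same structure.  Events missing from an assay render as ``nd``; the
    absolute difference to the sequencing estimate is included per assay.
    """
    rows = []
    for event_id, (m, sd) in rnaseq.items():
        row: dict[str, object] = {
            "event": event_id,
            "rnaseq": f"{m:.{precision}f} (+/-{sd:.{precision}f})",
        }
        for name, table in assays.items():
            if event_id in table:
                am, asd = table[event_id]
                row[name] = f"{am:.{precision}f} (+/-{asd:.{precision}f})"
                row[f"{name}_absdiff"] = round(abs(am - m), precision)
            else:
                row[name] = "nd"
                row[f"{name}_absdiff"] = math.nan
        rows.append(row)
    return pd.DataFrame(rows)
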