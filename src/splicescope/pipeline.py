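"""End-to-end orchestration: call junctions, annotate, quantify, score, report.

The pipeline consumes spliced alignments (one SAM/BAM per replicate), a
single-transcript model and an optional genome FASTA; it never aligns
reads.  All stages are plain library calls and can be re-run individually
from their written intermediates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from . import junction_calling as jc
from . import quantification as quant
from . import splice_site_scoring as sss
from .event_annotation import AnnotationResult, SplicingEvent, annotate_junctions
from .quantification import EventQuant
from .transcript_model import (
    TranscriptModel,
    build_dp427m_like_model,
    derive_canonical_junctions,
    load_transcript_model,
    write_junctions_bed,
)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "make_report", "load_genome"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class RunConfig:
    """Inputs and thresholds for one pipeline run.

    ``alignments`` maps sample id to a SAM/BAM path.  ``model_path`` may be
    None to use the bundled synthetic Dp427m-like fixture model.
    """

    alignments: dict[str, str]
    model_path: str | None = None
    transcript_id: str = ""
    genome_path: str | None = None
    matrices_path: str | None = None
    out_dir: str = "splicescope_out"
    min_reads: int = 5
    min_samples: int = 2
    min_anchor: int = 10
    max_shift: int = 10
    seed: int = 0
    precision: int = 2

    def validate(self) -> None:
        if not self.alignments:
            raise PipelineError("config: need at least one alignment file")
        for name in ("min_reads", "min_samples", "min_anchor", "max_shift"):
            if getattr(self, name) < 1:
                raise PipelineError(f"config: {name} must be positive")


@dataclass
class PipelineResult:
    model: TranscriptModel
    table: jc.JunctionCountTable
    annotation: AnnotationResult
    quants: list[EventQuant]
    coverage: dict[str, jc.CoverageTrack]
    qc: dict
    events_frame: pd.DataFrame = field(default_factory=pd.DataFrame)


def load_genome(path: str | Path, chrom: str) -> str:
    """Read one contig from a FASTA file."""
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id == chrom:
            return str(rec.seq).upper()
    raise PipelineError(f"genome: contig {chrom!r} not found in {path}")


def _events_frame(
    events: list[SplicingEvent], quants: list[EventQuant], precision: int
) -> pd.DataFrame:
    by_id = {q.event_id: q for q in quants}
    rows = []
    for ev in events:
        q = by_id.get(ev.event_id)
        rows.append(
            {
                "event": ev.display_name(),
                "event_id": ev.event_id,
                "category": ev.category,
                "delta_nt": ev.delta_nt,
                "mean_ase_percent": (
                    None if q is None or q.mean_ase is None else round(q.mean_ase, precision)
                ),
                "sd_ase_percent": (
                    None if q is None or q.sd_ase is None else round(q.sd_ase, precision)
                ),
                "predicted_frame": ev.frame,
                "passes_filter": None if q is None else q.passes_filter,
                "flags": ",".join(sorted(ev.flags)),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "event", "event_id", "category", "delta_nt", "mean_ase_percent",
            "sd_ase_percent", "predicted_frame", "passes_filter", "flags",
        ],
    )


def make_report(
    events: list[SplicingEvent], quants: list[EventQuant], precision: int = 2
) -> pd.DataFrame:
    """Inventory table: event name, size note, mean ASE% ± SD, predicted frame."""
    return _events_frame(events, quants, precision)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run all computational stages and write reports under ``config.out_dir``.

    Deterministic given the config; a failing stage raises
    :class:`PipelineError` naming the stage.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        if config.model_path is None:
            model = build_dp427m_like_model()
        else:
            model = load_transcript_model(config.model_path, config.transcript_id)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"model loading: {exc}") from exc

    genome = None
    if config.genome_path is not None:
        genome = load_genome(config.genome_path, model.chrom)

    table = jc.JunctionCountTable(chrom=model.chrom, strand=model.strand)
    cooccurrence = []
    coverage = {}
    try:
        for sample, path in sorted(config.alignments.items()):
            table.update(
                jc.count_junctions(
                    path, min_anchor=config.min_anchor, sample_id=sample,
                    chrom=model.chrom, strand=model.strand,
                )
            )
            cooccurrence.extend(jc.extract_cooccurrence(path, min_anchor=config.min_anchor))
            coverage[sample] = jc.coverage_profile(path, model)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"junction calling: {exc}") from exc

    try:
        annotation = annotate_junctions(
            table.junctions(), model, genome, cooccurrence, max_shift=config.max_shift
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"event annotation: {exc}") from exc

    try:
        quants = quant.quantify_events(
            annotation.events, table, model,
            min_reads=config.min_reads, min_samples=config.min_samples,
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"quantification: {exc}") from exc

    qc = {
        "samples": table.samples,
        "coverage_mean": {s: c.mean for s, c in coverage.items()},
        "coverage_sd": {s: c.sd for s, c in coverage.items()},
        "canonical_junctions_detected": annotation.canonical_detected,
        "canonical_junctions_expected": model.n_exons - 1,
        "events_in_inventory": len(annotation.events),
        "events_excluded_ambiguous": [ev.event_id for ev in annotation.excluded],
        "junctions_unclassified": len(annotation.unclassified),
    }

    events_frame = _events_frame(annotation.events, quants, config.precision)

    # ------------------------------------------------------------- outputs
    table.write_tsv(out / "junctions.tsv")
    write_junctions_bed(
        model,
        [j for ev in annotation.events for j in ev.junctions]
        + derive_canonical_junctions(model),
        out / "junctions.bed",
    )
    for sample, track in coverage.items():
        track.write_bedgraph(out / f"coverage_{sample}.bedGraph", name=model.name)
    events_frame.to_csv(out / "events.tsv", sep="\t", index=False)
    with open(out / "events.json", "w") as fh:
        json.dump(events_frame.to_dict(orient="records"), fh, indent=1)
    quant_rows = []
    for q in quants:
        for s in table.samples:
            quant_rows.append(
                {
                    "event_id": q.event_id, "sample": s,
                    "inclusion_reads": q.inclusion_reads.get(s),
                    "exclusion_reads": q.exclusion_reads.get(s),
                    "psi": q.psi.get(s), "ase_percent": q.ase_percent.get(s),
                    "support": q.support.get(s), "passes_filter": q.passes_filter,
                }
            )
    pd.DataFrame(quant_rows).to_csv(out / "quant.tsv", sep="\t", index=False)
    with open(out / "qc.json", "w") as fh:
        json.dump(qc, fh, indent=1)

    if genome is not None:
        matrices = sss.load_default_matrices(config.matrices_path)
        score_rows = []
        for ev in annotation.events:
            for site, score in sss.score_event_sites(ev, model, genome, matrices).items():
                if isinstance(score, sss.SiteScore):
                    score_rows.append(
                        {
                            "event_id": ev.event_id, "site": site,
                            "window": score.window, "raw": score.raw,
                            "score": None if score.scaled is None
                            else round(score.scaled, config.precision),
                        }
                    )
        pd.DataFrame(score_rows).to_csv(out / "scores.tsv", sep="\t", index=False)

    return PipelineResult(model, table, annotation, quants, coverage, qc, events_frame)
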