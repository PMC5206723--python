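"""Classification of novel splice junctions against a transcript model.

Each junction is resolved into exactly one of: canonical, exon skipping,
alternative 3'/5' splice-site usage, a pseudoexon half-junction (later paired
into a pseudoexon event), or unclassified.  Alternative splice-site offsets
follow the convention that exonic truncation is negative: an acceptor
displaced 3 nt into its exon is reported as −3 nt.  The alternative rendering
that counts the new acceptor's exonic position (one less, e.g. "+59" for a
−60 nt truncation) differs by one and is exposed separately where printed.

Misalignment hazards are handled by shift analysis: a junction whose flanking
repeats allow the same spliced sequence under a shifted intron placement is
flagged ambiguous when any shifted variant coincides with a canonical
junction or another candidate, and excluded from the final inventory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .junction_calling import CooccurrenceRecord
from .transcript_model import (
    Junction,
    TranscriptModel,
    derive_canonical_junctions,
    revcomp,
)

__all__ = [
    "SplicingEvent",
    "AmbiguityResult",
    "AnnotationResult",
    "classify_junction",
    "detect_pseudoexons",
    "detect_nagnag",
    "flag_ambiguous_junction",
    "predict_reading_frame",
    "annotate_junctions",
]

STOP_CODONS = ("TAA", "TAG", "TGA")

FINAL_CATEGORIES = ("exon_skip", "pseudoexon", "alt3ss", "alt5ss")


@dataclass
class SplicingEvent:
    """A classified alternative splicing event (possibly partial).

    ``category`` is one of ``exon_skip``, ``pseudoexon``, ``alt3ss``,
    ``alt5ss``, ``canonical``, ``pe_half_acceptor``, ``pe_half_donor`` or
    ``unclassified``.  ``delta_nt`` is the signed mRNA length change.
    """

    event_id: str
    category: str
    junctions: tuple[Junction, ...] = ()
    exons_skipped: tuple[int, ...] = ()
    exon: int = 0  # host exon of an alternative splice site
    offset_nt: int = 0  # signed; negative = exonic truncation
    pe_intron: int = 0
    pe_interval: tuple[int, int] | None = None
    boundary: int = 0  # intronic boundary of a half-junction
    delta_nt: int = 0
    frame: str = "unknown"
    flags: set[str] = field(default_factory=set)
    reason: str = ""

    @property
    def pe_length(self) -> int:
        return 0 if self.pe_interval is None else self.pe_interval[1] - self.pe_interval[0]

    @property
    def alt_site_exonic_position(self) -> int | None:
        """The "+k" rendering of an exonic alternative splice site.

        An acceptor truncating k nt reads as position k−1 within the exon
        (0-based); ``None`` for other categories.
        """
        if self.category in ("alt3ss", "alt5ss") and self.offset_nt < 0:
            return -self.offset_nt - 1
        return None

    def display_name(self) -> str:
        if self.category == "exon_skip":
            return "del" + "+".join(str(k) for k in self.exons_skipped)
        if self.category == "pseudoexon":
            return f"{self.event_id} ({self.pe_length} nt)"
        if self.category == "alt3ss":
            return f"3'ss exon {self.exon} ({self.offset_nt} nt)"
        if self.category == "alt5ss":
            return f"5'ss exon {self.exon} ({self.offset_nt} nt)"
        return self.event_id


@dataclass(frozen=True)
class AmbiguityResult:
    """Shift interval over which a junction placement is sequence-equivalent."""

    shift_min: int
    shift_max: int
    ambiguous: bool
    collides_with: tuple[tuple[int, int], ...] = ()

    @property
    def width(self) -> int:
        return self.shift_max - self.shift_min


def _site_maps(model: TranscriptModel):
    donors = {model.donor_site(i): i for i in range(1, model.n_exons)}
    acceptors = {model.acceptor_site(i): i + 1 for i in range(1, model.n_exons)}
    return donors, acceptors


def _intron_ordinal_containing(model: TranscriptModel, gpos: int) -> int | None:
    for ordinal, (s, e) in enumerate(model.introns(), start=1):
        if s < gpos < e:
            return ordinal
    return None


def classify_junction(j: Junction, model: TranscriptModel) -> SplicingEvent:
    """Resolve one junction into a (partial) splicing event.

    Mutually exclusive outcomes: canonical; exon_skip (both ends canonical,
    >= 1 exon omitted); alt3ss / alt5ss (one end canonical, the other
    displaced within the adjacent exon); pe_half_* (one end canonical, the
    other strictly inside the same intron); unclassified otherwise.
    """
    donors, acceptors = _site_maps(model)
    d, a = j.interval
    lo, hi = model.span
    if a <= lo or d >= hi:
        return SplicingEvent(j.label or "outside", "unclassified", (j,),
                             reason="junction outside transcript span")
    donor_coord = d if model.strand == "+" else a
    acceptor_coord = a if model.strand == "+" else d
    p = donors.get(donor_coord)  # junction leaves from the donor of exon p
    q = acceptors.get(acceptor_coord)  # junction lands at the acceptor of exon q

    if p is not None and q is not None:
        if q == p + 1:
            return SplicingEvent(f"ex{p}-ex{q}", "canonical", (j,))
        if q > p + 1:
            skipped = tuple(range(p + 1, q))
            delta = -sum(model.exons[k - 1].length for k in skipped)
            return SplicingEvent(
                "del" + "+".join(str(k) for k in skipped),
                "exon_skip", (j,), exons_skipped=skipped, delta_nt=delta,
            )
        return SplicingEvent(j.label or "inverted", "unclassified", (j,),
                             reason="acceptor upstream of donor in transcription order")

    if p is not None:
        ex = model.exon_containing(acceptor_coord)
        if ex is not None and ex.index == p + 1:
            if model.strand == "+":
                disp = acceptor_coord - ex.genomic_start
            else:
                disp = ex.genomic_end - acceptor_coord
            return SplicingEvent(
                f"3ss_ex{p + 1}", "alt3ss", (j,), exon=p + 1,
                offset_nt=-disp, delta_nt=-disp,
            )
        intron = _intron_ordinal_containing(model, acceptor_coord)
        if intron == p:
            return SplicingEvent(
                f"pe_acc_in{p}", "pe_half_acceptor", (j,),
                pe_intron=p, boundary=acceptor_coord,
            )
        return SplicingEvent(j.label or f"from_ex{p}", "unclassified", (j,),
                             reason="acceptor beyond the adjacent exon/intron")

    if q is not None:
        ex = model.exon_containing(donor_coord)
        if ex is not None and ex.index == q - 1:
            if model.strand == "+":
                disp = ex.genomic_end - donor_coord
            else:
                disp = donor_coord - ex.genomic_start
            return SplicingEvent(
                f"5ss_ex{q - 1}", "alt5ss", (j,), exon=q - 1,
                offset_nt=-disp, delta_nt=-disp,
            )
        intron = _intron_ordinal_containing(model, donor_coord)
        if intron == q - 1:
            return SplicingEvent(
                f"pe_don_in{q - 1}", "pe_half_donor", (j,),
                pe_intron=q - 1, boundary=donor_coord,
            )
        return SplicingEvent(j.label or f"to_ex{q}", "unclassified", (j,),
                             reason="donor beyond the adjacent exon/intron")

    return SplicingEvent(j.label or "novel", "unclassified", (j,),
                         reason="neither end at a canonical splice site")


def detect_pseudoexons(
    half_events: Iterable[SplicingEvent],
    cooccurrence: Sequence[CooccurrenceRecord],
    model: TranscriptModel,
) -> list[SplicingEvent]:
    """Pair pseudoexon half-junctions within each host intron.

    An acceptor half (canonical donor joined to an intronic acceptor) is
    paired with the nearest donor half downstream of it in transcription
    direction; the pair delimits the cryptic exon.  ``single_read_verified``
    is set only when one read is seen crossing both junctions.  Unpaired
    halves are not emitted.
    """
    sign = 1 if model.strand == "+" else -1
    by_intron: dict[int, dict[str, list[SplicingEvent]]] = {}
    for ev in half_events:
        if ev.category in ("pe_half_acceptor", "pe_half_donor"):
            side = "acc" if ev.category == "pe_half_acceptor" else "don"
            by_intron.setdefault(ev.pe_intron, {"acc": [], "don": []})[side].append(ev)
    out = []
    for intron, sides in sorted(by_intron.items()):
        accs = sorted(sides["acc"], key=lambda e: sign * e.boundary)
        dons = sorted(sides["don"], key=lambda e: sign * e.boundary)
        used: set[int] = set()
        for acc in accs:
            partner = None
            for k, don in enumerate(dons):
                if k in used:
                    continue
                if sign * don.boundary > sign * acc.boundary:
                    partner = k
                    break
            if partner is None:
                continue
            used.add(partner)
            don = dons[partner]
            lo = min(acc.boundary, don.boundary)
            hi = max(acc.boundary, don.boundary)
            ev = SplicingEvent(
                f"PE{intron}", "pseudoexon",
                (acc.junctions[0], don.junctions[0]),
                pe_intron=intron, pe_interval=(lo, hi), delta_nt=hi - lo,
            )
            wanted = {acc.junctions[0].interval, don.junctions[0].interval}
            if any(wanted <= set(rec.junctions) for rec in cooccurrence):
                ev.flags.add("single_read_verified")
            out.append(ev)
    return out


def detect_nagnag(
    event: SplicingEvent, model: TranscriptModel, genome: str | None
) -> SplicingEvent:
    """Flag a −3 nt alternative acceptor that sits on a NAGNAG tandem motif.

    The 6-mer spanning −3..+3 around the natural 3'ss is tested for two AG
    dinucleotides 3 nt apart.  Events with |offset| != 3 are left untouched.
    """
    if event.category != "alt3ss" or event.offset_nt != -3:
        return event
    if genome is None:
        event.flags.add("nagnag_unknown")
        return event
    s, e = model.introns()[event.exon - 2]
    if model.strand == "+":
        window = genome[e - 3 : e + 3]
    else:
        window = revcomp(genome[s - 3 : s + 3])
    if window[1:3] == "AG" and window[4:6] == "AG":
        event.flags.add("nagnag")
    return event


def flag_ambiguous_junction(
    j: Junction,
    genome: str,
    model: TranscriptModel | None = None,
    candidates: Iterable[tuple[int, int]] = (),
    max_shift: int = 10,
) -> AmbiguityResult:
    """Shift analysis of one junction against homopolymers/repeats.

    A shift of s keeps the spliced sequence identical iff the s bases
    entering the exon on one side equal those leaving on the other; the
    maximal such interval around 0 is reported.  The junction is ambiguous
    when a non-zero shifted placement coincides with a canonical junction or
    one of ``candidates``.
    """
    d, a = j.interval
    right = 0
    while right < max_shift and a + right < len(genome) and genome[d + right] == genome[a + right]:
        right += 1
    left = 0
    while left < max_shift and d - left - 1 >= 0 and genome[d - left - 1] == genome[a - left - 1]:
        left += 1
    known: set[tuple[int, int]] = set(candidates)
    if model is not None:
        known |= {c.interval for c in derive_canonical_junctions(model)}
    known.discard(j.interval)
    collisions = []
    for s in range(-left, right + 1):
        if s and (d + s, a + s) in known:
            collisions.append((d + s, a + s))
    return AmbiguityResult(-left, right, bool(collisions), tuple(collisions))


def _event_mrna_interval(event: SplicingEvent, model: TranscriptModel) -> tuple[int, int]:
    """mRNA interval deleted (skip/alt-ss) or the insertion point (PE)."""
    if event.category == "exon_skip":
        return (
            model.exon_mrna_span(event.exons_skipped[0])[0],
            model.exon_mrna_span(event.exons_skipped[-1])[1],
        )
    if event.category == "pseudoexon":
        pt = model.exon_mrna_span(event.pe_intron)[1]
        return (pt, pt)
    span = model.exon_mrna_span(event.exon)
    n = abs(event.offset_nt)
    if event.category == "alt3ss":
        return (span[0], span[0] + min(n, span[1] - span[0]))
    return (span[1] - min(n, span[1] - span[0]), span[1])


def predict_reading_frame(
    event: SplicingEvent,
    model: TranscriptModel,
    insert_seq: str | None = None,
) -> SplicingEvent:
    """Predict the reading-frame consequence from the mRNA length change.

    A delta not divisible by 3 is out of frame.  Frame-preserving insertions
    are additionally screened for in-frame stop codons when the inserted
    sequence is supplied; without it the call is length-only and flagged.
    Events entirely upstream of the CDS start are non-coding (frame unknown).
    """
    lo, hi = _event_mrna_interval(event, model)
    cds = model.cds_start_mrna
    if (lo < hi and hi <= cds) or (lo == hi and lo < cds):
        event.frame = "unknown"
        return event
    if event.delta_nt % 3 != 0:
        event.frame = "out_of_frame"
        return event
    if event.category != "pseudoexon" or event.delta_nt == 0:
        event.frame = "in_frame"
        return event
    if insert_seq is None:
        event.frame = "in_frame"
        event.flags.add("frame_no_sequence")
        return event
    insert_seq = insert_seq.upper()
    phase = (lo - model.cds_start_mrna) % 3
    off = (3 - phase) % 3
    for k in range(off, len(insert_seq) - 2, 3):
        if insert_seq[k : k + 3] in STOP_CODONS:
            event.frame = "out_of_frame_stop"
            return event
    event.frame = "in_frame"
    return event


@dataclass
class AnnotationResult:
    """Outcome of annotating a junction collection against a model."""

    events: list[SplicingEvent]
    excluded: list[SplicingEvent]
    unclassified: list[SplicingEvent]
    canonical_detected: int


def annotate_junctions(
    junctions: Iterable[Junction | tuple[int, int]],
    model: TranscriptModel,
    genome: str | None = None,
    cooccurrence: Sequence[CooccurrenceRecord] = (),
    max_shift: int = 10,
) -> AnnotationResult:
    """Classify junctions, pair pseudoexons, flag hazards, predict frames.

    Returns the final event inventory (ambiguous-alignment events are
    excluded and reported separately), the unclassified leftovers, and the
    number of canonical junctions observed.
    """
    jlist = [j if isinstance(j, Junction) else Junction(*j) for j in junctions]
    classified = [classify_junction(j, model) for j in jlist]
    canonical_detected = sum(1 for ev in classified if ev.category == "canonical")
    halves = [ev for ev in classified if ev.category.startswith("pe_half")]
    singles = [ev for ev in classified if ev.category in ("exon_skip", "alt3ss", "alt5ss")]
    unclassified = [ev for ev in classified if ev.category == "unclassified"]
    pes = detect_pseudoexons(halves, cooccurrence, model)
    paired = {j.interval for ev in pes for j in ev.junctions}
    unclassified += [ev for ev in halves if ev.junctions[0].interval not in paired]
    events = singles + pes

    excluded: list[SplicingEvent] = []
    if genome is not None:
        # unclassifiable junctions that are shift-equivalent to a canonical
        # junction are misalignment artifacts, reported with the exclusions
        still_unclassified = []
        for ev in unclassified:
            res = flag_ambiguous_junction(ev.junctions[0], genome, model, (), max_shift)
            if res.ambiguous:
                ev.flags.add("ambiguous_alignment")
                excluded.append(ev)
            else:
                still_unclassified.append(ev)
        unclassified = still_unclassified
        candidate_intervals = {j.interval for ev in events for j in ev.junctions}
        kept = []
        for ev in events:
            results = [
                flag_ambiguous_junction(
                    j, genome, model, candidate_intervals - {j.interval}, max_shift
                )
                for j in ev.junctions
            ]
            if any(r.ambiguous for r in results):
                ev.flags.add("ambiguous_alignment")
                excluded.append(ev)
            else:
                kept.append(ev)
        events = kept

    for ev in events:
        if ev.category == "alt3ss":
            detect_nagnag(ev, model, genome)
        insert = None
        if ev.category == "pseudoexon" and genome is not None:
            insert = model.transcribed_slice(*ev.pe_interval, genome)
        predict_reading_frame(ev, model, insert)
    return AnnotationResult(events, excluded, unclassified, canonical_detected)
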