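"""Splice-site strength scoring with position-weight consensus values.

The scorer follows the classical weight-matrix consensus-value scheme: the
raw score of a window is the sum of its per-position nucleotide weights, and
the reported score rescales it between the worst and best achievable windows
onto a 0–100 scale.  Bundled donor (−3..+6) and acceptor (−13..+1) matrices
are Shapiro–Senapathy-style percentage tables shipped as editable YAML; the
windows and weights are deliberately configurable because published web
scorers do not fully document theirs.

Also provided: a NAGNAG scan over all canonical acceptors (two AG
dinucleotides 3 nt apart allow two isoforms differing by one codon).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .event_annotation import SplicingEvent
from .transcript_model import TranscriptModel, revcomp

__all__ = [
    "WeightMatrix",
    "SiteScore",
    "load_default_matrices",
    "consensus_value_score",
    "donor_window",
    "acceptor_window",
    "score_event_sites",
    "scan_nagnag_acceptors",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class WeightMatrix:
    """Per-position nucleotide weights over a splice-site window.

    ``positions`` are relative to the splice site (no position 0); weights
    must cover A, C, G and T at every position.
    """

    site_type: str
    positions: tuple[int, ...]
    weights: tuple[dict[str, float], ...]

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.weights):
            raise ValueError("positions and weights differ in length")
        for pos, w in zip(self.positions, self.weights):
            missing = set(_BASES) - set(w)
            if missing:
                raise ValueError(f"position {pos} lacks weights for {sorted(missing)}")
        if self.max_raw <= self.min_raw:
            raise ValueError("degenerate matrix: max score equals min score")

    @property
    def window_length(self) -> int:
        return len(self.positions)

    @property
    def min_raw(self) -> float:
        return sum(min(w.values()) for w in self.weights)

    @property
    def max_raw(self) -> float:
        return sum(max(w.values()) for w in self.weights)

    def consensus(self) -> str:
        return "".join(max(w, key=w.get) for w in self.weights)

    @classmethod
    def from_dict(cls, d: dict) -> "WeightMatrix":
        positions = tuple(int(p) for p in d["positions"])
        weights = tuple(
            {b: float(v) for b, v in d["weights"][p].items()} for p in positions
        )
        return cls(d["site_type"], positions, weights)


@dataclass(frozen=True)
class SiteScore:
    """Raw and 0–100 rescaled consensus score of one window."""

    window: str
    raw: float | None
    scaled: float | None

    @property
    def defined(self) -> bool:
        return self.scaled is not None


def load_default_matrices(path: str | Path | None = None) -> dict[str, WeightMatrix]:
    """Load the bundled donor/acceptor matrices, or a user YAML of the same shape."""
    if path is None:
        text = (resources.files("splicescope") / "data" / "matrices.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    return {name: WeightMatrix.from_dict(d) for name, d in raw.items()}


def consensus_value_score(window: str, matrix: WeightMatrix) -> SiteScore:
    """Score a window: raw = Σ position weights, scaled onto [0, 100].

    Windows containing non-ACGT characters get an undefined score rather
    than a guess.
    """
    window = window.upper()
    if len(window) != matrix.window_length:
        raise ValueError(
            f"window length {len(window)} != matrix window {matrix.window_length}"
        )
    if set(window) - set(_BASES):
        return SiteScore(window, None, None)
    raw = sum(w[b] for w, b in zip(matrix.weights, window))
    scaled = (raw - matrix.min_raw) / (matrix.max_raw - matrix.min_raw) * 100.0
    return SiteScore(window, raw, scaled)


# ------------------------------------------------------------ window extraction


def _txn_window(
    model: TranscriptModel, genome: str, boundary: int, upstream: int, downstream: int
) -> str:
    """Sequence window around a transcription-axis boundary.

    ``boundary`` is a plus-strand genomic coordinate; the window covers
    ``upstream`` bases before and ``downstream`` bases after it *in
    transcription direction*.
    """
    if model.strand == "+":
        return genome[boundary - upstream : boundary + downstream]
    return revcomp(genome[boundary - downstream : boundary + upstream])


def donor_window(
    model: TranscriptModel, genome: str, boundary: int, matrix: WeightMatrix
) -> str:
    """Window for a 5' splice site whose exon/intron boundary is ``boundary``."""
    up = sum(1 for p in matrix.positions if p < 0)
    return _txn_window(model, genome, boundary, up, matrix.window_length - up)


def acceptor_window(
    model: TranscriptModel, genome: str, boundary: int, matrix: WeightMatrix
) -> str:
    """Window for a 3' splice site whose intron/exon boundary is ``boundary``."""
    up = sum(1 for p in matrix.positions if p < 0)
    return _txn_window(model, genome, boundary, up, matrix.window_length - up)


def _canonical_boundaries(model: TranscriptModel, intron: int) -> tuple[int, int]:
    """(donor boundary, acceptor boundary) of a canonical intron, txn sense."""
    s, e = model.introns()[intron - 1]
    return (s, e) if model.strand == "+" else (e, s)


def score_event_sites(
    event: SplicingEvent,
    model: TranscriptModel,
    genome: str,
    matrices: dict[str, WeightMatrix] | None = None,
) -> dict[str, SiteScore | float | None]:
    """Score the alternative splice site(s) of an event against the natural ones.

    Pseudoexons report (alt 3'ss, alt 5'ss) followed by the flanking
    constitutive donor and acceptor; alternative splice sites report the
    alternative window, the natural one, and their scaled difference.
    """
    matrices = matrices or load_default_matrices()
    don, acc = matrices["donor"], matrices["acceptor"]

    if event.category == "pseudoexon":
        lo, hi = event.pe_interval
        pe_acc_b, pe_don_b = (lo, hi) if model.strand == "+" else (hi, lo)
        host_don, host_acc = _canonical_boundaries(model, event.pe_intron)
        return {
            "alt_acceptor": consensus_value_score(
                acceptor_window(model, genome, pe_acc_b, acc), acc
            ),
            "alt_donor": consensus_value_score(
                donor_window(model, genome, pe_don_b, don), don
            ),
            "flanking_donor": consensus_value_score(
                donor_window(model, genome, host_don, don), don
            ),
            "flanking_acceptor": consensus_value_score(
                acceptor_window(model, genome, host_acc, acc), acc
            ),
        }

    if event.category in ("alt3ss", "alt5ss"):
        is3 = event.category == "alt3ss"
        intron = event.exon - 1 if is3 else event.exon
        nat_don, nat_acc = _canonical_boundaries(model, intron)
        natural_b = nat_acc if is3 else nat_don
        shift = -event.offset_nt  # exonic truncation moves the site into the exon
        if model.strand == "+":
            alt_b = natural_b + shift if is3 else natural_b - shift
        else:
            alt_b = natural_b - shift if is3 else natural_b + shift
        matrix = acc if is3 else don
        wfun = acceptor_window if is3 else donor_window
        alt = consensus_value_score(wfun(model, genome, alt_b, matrix), matrix)
        nat = consensus_value_score(wfun(model, genome, natural_b, matrix), matrix)
        diff = None
        if alt.defined and nat.defined:
            diff = alt.scaled - nat.scaled
        return {"alt_site": alt, "natural_site": nat, "difference": diff}

    if event.category == "exon_skip":
        first, last = event.exons_skipped[0], event.exons_skipped[-1]
        _, acc_b = _canonical_boundaries(model, first - 1)
        don_b, _ = _canonical_boundaries(model, last)
        return {
            "skipped_acceptor": consensus_value_score(
                acceptor_window(model, genome, acc_b, acc), acc
            ),
            "skipped_donor": consensus_value_score(
                donor_window(model, genome, don_b, don), don
            ),
        }
    raise ValueError(f"no sites to score for category {event.category!r}")


def maxentscan_score(window: str, program: str | Path) -> float:
    """Optional adapter to a locally installed maximum-entropy scorer.

    Shells out to the given MaxEntScan-style script (``score5.pl`` /
    ``score3.pl``), feeding one window and parsing the score from the last
    whitespace-separated field.  Never required by the rest of the package;
    raises ``FileNotFoundError`` if the program is absent.
    """
    import subprocess
    import tempfile

    program = Path(program)
    if not program.exists():
        raise FileNotFoundError(f"maximum-entropy scorer not found at {program}")
    with tempfile.NamedTemporaryFile("w", suffix=".fa", delete=False) as fh:
        fh.write(f"> w\n{window}\n")
        tmp = fh.name
    try:
        out = subprocess.run(
            ["perl", str(program), tmp], capture_output=True, text=True, check=True
        )
        return float(out.stdout.split()[-1])
    finally:
        Path(tmp).unlink(missing_ok=True)


def scan_nagnag_acceptors(model: TranscriptModel, genome: str) -> list[int]:
    """Exon ordinals whose canonical acceptor sits on a NAGNAG tandem motif.

    Tests the 6-mer spanning −3..+3 around each canonical 3'ss for two AG
    dinucleotides 3 nt apart (positions 2–3 and 5–6 of the 6-mer).
    """
    hits = []
    for intron in range(1, model.n_exons):
        _, acc_b = _canonical_boundaries(model, intron)
        w = _txn_window(model, genome, acc_b, 3, 3)
        if w[1:3] == "AG" and w[4:6] == "AG":
            hits.append(intron + 1)
    return hits
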