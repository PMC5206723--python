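"""Shared fixtures: the synthetic dystrophin-like model, genome and events."""

import pysam
import pytest

from splicescope.synthetic_data import build_fixture_genome, dp427m_reference_events
from splicescope.transcript_model import Exon, TranscriptModel, build_dp427m_like_model


@pytest.fixture(scope="session")
def model():
    """The 79-exon synthetic Dp427m-like model (plus strand)."""
    return build_dp427m_like_model()


@pytest.fixture(scope="session")
def events(model):
    """The 12 reference events at their published rates."""
    return dp427m_reference_events(model)


@pytest.fixture(scope="session")
def genome(model, events):
    """Fixture genome with splice-site features planted."""
    return build_fixture_genome(model, events)


@pytest.fixture(scope="session")
def minus_model():
    return build_dp427m_like_model(strand="-")


@pytest.fixture
def small_model():
    """Hand-built 5-exon plus-strand model with 100-nt exons, 50-nt introns."""
    exons = [Exon(i, 1000 + (i - 1) * 150, 1100 + (i - 1) * 150) for i in range(1, 6)]
    return TranscriptModel("toy", "chrT", "+", exons, cds_start_mrna=30)


def make_alignment(reference_start, cigar, name="read1", chrom="synthX",
                   reference_length=50_000, flag=0, seq=None):
    """Construct a single mapped pysam record for CIGAR-level tests."""
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": chrom, "LN": reference_length}]}
    )
    rec = pysam.AlignedSegment(header=header)
    rec.query_name = name
    rec.flag = flag
    rec.reference_id = 0
    rec.reference_start = reference_start
    rec.mapping_quality = 60
    rec.cigarstring = cigar
    if seq is not None:
        rec.query_sequence = seq
    return rec
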