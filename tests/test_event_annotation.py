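"""Junction classification, pseudoexon pairing, hazards and frame calls."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from splicescope.event_annotation import (
    SplicingEvent,
    annotate_junctions,
    classify_junction,
    detect_nagnag,
    detect_pseudoexons,
    flag_ambiguous_junction,
    predict_reading_frame,
)
from splicescope.junction_calling import CooccurrenceRecord
from splicescope.synthetic_data import (
    EventSpec,
    event_junctions,
    inject_misalignment_artifact,
)
from splicescope.transcript_model import Junction, derive_canonical_junctions


class TestClassification:
    def test_canonical_junction_recognized(self, model):
        j = derive_canonical_junctions(model)[7]
        assert classify_junction(j, model).category == "canonical"

    def test_skip_of_exon_9(self, model):
        # donor of exon 8 joined to acceptor of exon 10
        j = Junction(model.exons[7].genomic_end, model.exons[9].genomic_start)
        ev = classify_junction(j, model)
        assert ev.category == "exon_skip"
        assert ev.exons_skipped == (9,)
        assert ev.delta_nt == -model.exons[8].length
        assert ev.event_id == "del9"

    def test_multi_exon_skip_label(self, model):
        j = Junction(model.exons[26].genomic_end, model.exons[29].genomic_start)
        ev = classify_junction(j, model)
        assert ev.exons_skipped == (28, 29)
        assert ev.event_id == "del28+29"

    def test_acceptor_displaced_3nt_into_exon_54(self, model):
        s, e = model.introns()[52]
        ev = classify_junction(Junction(s, e + 3), model)
        assert (ev.category, ev.offset_nt, ev.delta_nt) == ("alt3ss", -3, -3)
        assert ev.exon == 54

    def test_acceptor_displaced_60nt_into_exon_76_dual_rendering(self, model):
        s, e = model.introns()[74]
        ev = classify_junction(Junction(s, e + 60), model)
        assert ev.offset_nt == -60
        assert ev.alt_site_exonic_position == 59  # the "exon 76 + 59" rendering

    def test_donor_displaced_into_upstream_exon_is_alt5ss(self, model):
        s, e = model.introns()[29]
        ev = classify_junction(Junction(s - 6, e), model)
        assert (ev.category, ev.exon, ev.offset_nt) == ("alt5ss", 30, -6)

    def test_intronic_acceptor_is_pseudoexon_half(self, model):
        s, e = model.introns()[0]
        ev = classify_junction(Junction(s, s + 400), model)
        assert ev.category == "pe_half_acceptor"
        assert ev.pe_intron == 1 and ev.boundary == s + 400

    def test_junction_outside_span_unclassified(self, model):
        lo, _ = model.span
        ev = classify_junction(Junction(5, lo - 10), model)
        assert ev.category == "unclassified"

    def test_classification_is_exhaustive_and_unique(self, model):
        lo, hi = model.span
        categories = {
            "canonical", "exon_skip", "alt3ss", "alt5ss",
            "pe_half_acceptor", "pe_half_donor", "unclassified",
        }
        import numpy as np

        rng = np.random.default_rng(0)
        for _ in range(300):
            d, a = sorted(rng.integers(lo - 50, hi + 50, size=2))
            if a <= d:
                continue
            assert classify_junction(Junction(d, a), model).category in categories


class TestPseudoexons:
    def _halves(self, model, interval):
        s, e = model.introns()[0]
        a, b = interval
        return [
            classify_junction(Junction(s, a), model),
            classify_junction(Junction(b, e), model),
        ]

    def test_paired_halves_form_162nt_pseudoexon(self, model):
        s, _ = model.introns()[0]
        halves = self._halves(model, (s + 400, s + 562))
        cooc = [CooccurrenceRecord("r1", tuple(h.junctions[0].interval for h in halves))]
        (pe,) = detect_pseudoexons(halves, cooc, model)
        assert pe.category == "pseudoexon"
        assert pe.pe_length == 162 and pe.delta_nt == 162
        assert "single_read_verified" in pe.flags

    def test_without_spanning_read_verification_flag_absent(self, model):
        s, _ = model.introns()[0]
        halves = self._halves(model, (s + 100, s + 184))
        (pe,) = detect_pseudoexons(halves, [], model)
        assert "single_read_verified" not in pe.flags

    def test_unpaired_half_emits_nothing(self, model):
        s, e = model.introns()[0]
        half = classify_junction(Junction(s, s + 200), model)
        assert detect_pseudoexons([half], [], model) == []


class TestNagnag:
    def _alt3(self, exon, offset=-3):
        return SplicingEvent("x", "alt3ss", exon=exon, offset_nt=offset, delta_nt=offset)

    def test_planted_tandem_at_exon_54_detected(self, model, genome):
        ev = detect_nagnag(self._alt3(54), model, genome)
        assert "nagnag" in ev.flags

    def test_non_tandem_acceptor_not_flagged(self, model, genome):
        ev = detect_nagnag(self._alt3(30), model, genome)
        assert "nagnag" not in ev.flags

    def test_window_logic_on_synthetic_sequences(self, small_model):
        # 6-mer ending at the distal acceptor decides the call
        s, e = small_model.introns()[0]
        good = "N" * (e - 3) + "CAGCAG" + "N" * 50
        bad = "N" * (e - 3) + "CTTCAG" + "N" * 50
        assert "nagnag" in detect_nagnag(self._alt3(2), small_model, good).flags
        assert "nagnag" not in detect_nagnag(self._alt3(2), small_model, bad).flags

    def test_offsets_other_than_minus3_not_evaluated(self, model, genome):
        ev = detect_nagnag(self._alt3(76, -60), model, genome)
        assert ev.flags == set()

    def test_missing_sequence_flags_unknown(self, model):
        ev = detect_nagnag(self._alt3(54), model, None)
        assert "nagnag_unknown" in ev.flags


class TestAmbiguity:
    def test_nonrepetitive_flanks_give_zero_shift_range(self, model, genome):
        j = Junction(*model.introns()[29])
        res = flag_ambiguous_junction(j, genome, model)
        assert res.width <= 4  # only chance micro-homology, no planted repeat
        assert not res.ambiguous

    def test_planted_repeat_gives_expected_width(self, model, genome):
        g2, shifts = inject_misalignment_artifact(model, genome, 30, 4)
        j = Junction(*model.introns()[29])
        res = flag_ambiguous_junction(j, g2, model)
        assert res.shift_max >= 4

    def test_homopolymer_collision_with_canonical_junction_excluded(self, model, genome):
        # analog of the exons 3/4 misalignment artifact: a novel junction one
        # base off a canonical one inside a planted repeat
        g2, _ = inject_misalignment_artifact(model, genome, 3, 6)
        s, e = model.introns()[2]
        shifted = Junction(s + 1, e + 1)
        res = flag_ambiguous_junction(shifted, g2, model)
        assert res.ambiguous and (s, e) in res.collides_with
        ann = annotate_junctions(
            [j.interval for j in derive_canonical_junctions(model)] + [shifted.interval],
            model, g2,
        )
        assert all(ev.junctions[0].interval != shifted.interval for ev in ann.events)
        assert any("ambiguous_alignment" in ev.flags for ev in ann.excluded)


class TestReadingFrame:
    def test_32nt_skip_shifts_frame(self, model):
        ev = SplicingEvent("del78", "exon_skip", exons_skipped=(78,), delta_nt=-32)
        assert predict_reading_frame(ev, model).frame == "out_of_frame"

    def test_minus60_acceptor_removes_20_codons_in_frame(self, model):
        ev = SplicingEvent("x", "alt3ss", exon=76, offset_nt=-60, delta_nt=-60)
        assert predict_reading_frame(ev, model).frame == "in_frame"
        assert abs(ev.delta_nt) // 3 == 20

    def test_minus3_acceptor_deletes_one_codon(self, model):
        ev = SplicingEvent("x", "alt3ss", exon=54, offset_nt=-3, delta_nt=-3)
        assert predict_reading_frame(ev, model).frame == "in_frame"
        assert abs(ev.delta_nt) // 3 == 1

    def test_162nt_insertion_with_inframe_stop(self, model):
        insertion_point = model.exon_mrna_span(1)[1]
        phase = (insertion_point - model.cds_start_mrna) % 3
        seq = list("C" * 162)
        off = (3 - phase) % 3
        seq[off : off + 3] = "TAA"
        ev = SplicingEvent("PE1", "pseudoexon", pe_intron=1,
                           pe_interval=(0, 162), delta_nt=162)
        assert predict_reading_frame(ev, model, "".join(seq)).frame == "out_of_frame_stop"

    def test_frame_neutral_insertion_without_stop(self, model):
        ev = SplicingEvent("PE21", "pseudoexon", pe_intron=21,
                           pe_interval=(0, 66), delta_nt=66)
        assert predict_reading_frame(ev, model, "C" * 66).frame == "in_frame"

    def test_insertion_without_sequence_warns(self, model):
        ev = SplicingEvent("PE", "pseudoexon", pe_intron=21,
                           pe_interval=(0, 66), delta_nt=66)
        out = predict_reading_frame(ev, model, None)
        assert out.frame == "in_frame" and "frame_no_sequence" in out.flags

    def test_event_upstream_of_cds_is_noncoding(self, model):
        # the first 10 nt of exon 1 lie entirely in the 5'UTR (CDS starts at 100)
        ev = SplicingEvent("y", "alt3ss", exon=1, offset_nt=-10, delta_nt=-10)
        assert predict_reading_frame(ev, model).frame == "unknown"
        # while an event reaching past the CDS start is frame-evaluated
        ev2 = SplicingEvent("x", "alt5ss", exon=1, offset_nt=-3, delta_nt=-3)
        assert predict_reading_frame(ev2, model).frame == "in_frame"


@settings(max_examples=50, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_frame_call_consistent_with_delta_mod3(model, seed):
    import numpy as np

    rng = np.random.default_rng(seed)
    k = int(rng.integers(2, model.n_exons - 1))
    ev = SplicingEvent("s", "exon_skip", exons_skipped=(k,),
                       delta_nt=-model.exons[k - 1].length)
    out = predict_reading_frame(ev, model)
    if ev.delta_nt % 3 != 0:
        assert out.frame == "out_of_frame"
    else:
        assert out.frame == "in_frame"


def test_full_event_set_recovered_at_zero_error(model, genome, events):
    """Planted reference events are recovered exactly, category by category."""
    junctions = [j for ev in events for j in event_junctions(model, ev)]
    cooc = [
        CooccurrenceRecord(ev.event_id,
                           tuple(j.interval for j in event_junctions(model, ev)))
        for ev in events if ev.category == "pseudoexon"
    ]
    ann = annotate_junctions(junctions, model, genome, cooc)
    got = {(ev.category, ev.delta_nt) for ev in ann.events}
    want = set()
    for ev in events:
        if ev.category == "exon_skip":
            want.add(("exon_skip", -sum(model.exons[k - 1].length for k in ev.skip_exons)))
        elif ev.category == "pseudoexon":
            want.add(("pseudoexon", ev.pe_length))
        else:
            want.add((ev.category, ev.offset_nt))
    assert got == want
    assert len(ann.events) == 12
    assert ann.excluded == [] and ann.unclassified == []
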