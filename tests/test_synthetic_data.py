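"""Simulator correctness: mixtures, count sampling, reads and artifacts."""

import math
from pathlib import Path

import numpy as np
import pysam
import pytest
from Bio import SeqIO

from splicescope.junction_calling import count_junctions
from splicescope.synthetic_data import (
    EventSpec,
    SimConfig,
    SimulationConfigError,
    build_fixture_genome,
    decoy_skip_events,
    event_junctions,
    inject_misalignment_artifact,
    simulate_isoform_mixture,
    simulate_junction_counts,
    simulate_reads,
)


class TestIsoformMixture:
    def test_no_events_gives_single_canonical_isoform(self, model):
        mix = simulate_isoform_mixture(model, [])
        assert len(mix) == 1
        assert mix[0].weight == 1.0
        assert mix[0].mrna_length == model.mrna_length

    def test_single_skip_event_weights(self, model):
        ev = EventSpec("del78", "exon_skip", 0.0248, skip_exons=(78,))
        mix = simulate_isoform_mixture(model, [ev])
        assert [round(i.weight, 4) for i in mix] == [0.9752, 0.0248]
        assert mix[1].mrna_length == model.mrna_length - model.exons[77].length

    def test_two_events_in_distinct_introns_enumerate_to_three_isoforms(self, model):
        evs = [
            EventSpec("a", "exon_skip", 0.1, skip_exons=(9,)),
            EventSpec("b", "exon_skip", 0.25, skip_exons=(40,)),
        ]
        mix = simulate_isoform_mixture(model, evs)
        assert len(mix) == 3
        assert math.isclose(sum(i.weight for i in mix), 1.0)
        assert [i.weight for i in mix[1:]] == [0.1, 0.25]

    def test_rates_exceeding_one_at_a_locus_rejected(self, model):
        evs = [
            EventSpec("a", "alt3ss", 0.6, exon=20, offset_nt=-2),
            EventSpec("b", "alt3ss", 0.5, exon=20, offset_nt=-5),
        ]
        with pytest.raises(SimulationConfigError, match="sum"):
            simulate_isoform_mixture(model, evs)

    def test_event_validation_rejects_inconsistent_definitions(self, model):
        with pytest.raises(SimulationConfigError):
            EventSpec("x", "exon_skip", 0.1, skip_exons=(1,)).validate(model)
        with pytest.raises(SimulationConfigError):
            EventSpec("x", "alt3ss", 0.1, exon=78, offset_nt=-40).validate(model)
        with pytest.raises(SimulationConfigError):
            EventSpec(
                "x", "pseudoexon", 0.1, pe_intron=2, pe_interval=(0, 50)
            ).validate(model)


class TestJunctionCountSimulation:
    def test_rate_zero_and_one_extremes(self, model):
        z = EventSpec("z", "exon_skip", 0.0, skip_exons=(9,))
        o = EventSpec("o", "exon_skip", 1.0, skip_exons=(40,))
        table, truth = simulate_junction_counts(model, [z, o], 500, 4, seed=0)
        zj = event_junctions(model, z)[0]
        oj = event_junctions(model, o)[0]
        for s in table.samples:
            assert table.get(zj.interval, s) == 0
            assert table.get(oj.interval, s) == 500
            # skipping exon 40 at rate 1 removes all reads from its flanks
            assert table.get(model.introns()[38], s) == 0
            assert table.get(model.introns()[39], s) == 0

    def test_binomial_expectation_at_low_rate(self, model):
        # depth 2000, rate 0.0063: E[alt] = 12.6; Monte-Carlo over 10,000 draws
        ev = EventSpec("del9", "exon_skip", 0.0063, skip_exons=(9,))
        _, truth = simulate_junction_counts(model, [ev], 2000, n_samples=10_000, seed=3)
        counts = np.array(list(truth.event_counts["del9"].values()))
        se = math.sqrt(2000 * 0.0063 * (1 - 0.0063) / len(counts))
        assert abs(counts.mean() - 12.6) < 3 * se

    def test_reproducible_under_seed(self, model, events):
        t1, _ = simulate_junction_counts(model, events, 1000, 4, seed=42)
        t2, _ = simulate_junction_counts(model, events, 1000, 4, seed=42)
        assert t1.to_frame().equals(t2.to_frame())


@pytest.fixture(scope="module")
def clean_sim(model, events, genome, tmp_path_factory):
    """Error-free single-sample read simulation shared across read tests."""
    out = tmp_path_factory.mktemp("cleansim")
    mix = simulate_isoform_mixture(model, events)
    cfg = SimConfig(
        n_samples=1, reads_per_sample=5000, seed=17,
        error_rate=0.0, homopolymer_indel_rate=0.0,
    )
    truth = simulate_reads(model, mix, genome, cfg, out)
    return out, truth, cfg


class TestReadSimulation:
    def test_error_free_reads_are_mrna_substrings(self, clean_sim, model, genome, events):
        out, truth, _ = clean_sim
        mix = simulate_isoform_mixture(model, events)
        seqs = {iso.name: iso.sequence(genome) for iso in mix}
        n = 0
        for rec in SeqIO.parse(str(out / "sample1.fasta"), "fasta"):
            assert str(rec.seq) in seqs[truth.read_isoform[rec.id]]
            n += 1
            if n >= 300:
                break
        assert n == 300

    def test_truth_sam_junctions_match_truth_record_exactly(self, clean_sim):
        out, truth, _ = clean_sim
        table = count_junctions(out / "sample1.sam", min_anchor=1, sample_id="s")
        expect = truth.junction_counts["sample1"]
        assert {iv: table.get(iv, "s") for iv in expect} == dict(expect)
        assert table.total("s") == sum(expect.values())

    def test_mean_depth_matches_closed_form(self, clean_sim, model):
        from splicescope.junction_calling import coverage_profile

        out, _, cfg = clean_sim
        track = coverage_profile(out / "sample1.sam", model)
        expected = cfg.reads_per_sample * cfg.read_length_mean / model.mrna_length
        assert abs(track.mean - expected) / expected < 0.10

    def test_identical_seed_identical_bytes(self, model, genome, tmp_path):
        ev = [EventSpec("del9", "exon_skip", 0.1, skip_exons=(9,))]
        mix = simulate_isoform_mixture(model, ev)
        cfg = SimConfig(n_samples=1, reads_per_sample=300, seed=5)
        simulate_reads(model, mix, genome, cfg, tmp_path / "a")
        simulate_reads(model, mix, genome, cfg, tmp_path / "b")
        for name in ("sample1.fasta", "sample1.sam"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_pseudoexon_reads_show_two_flanking_gaps(self, model, genome, tmp_path):
        pe = EventSpec("PE1a", "pseudoexon", 1.0, pe_intron=1,
                       pe_interval=(model.introns()[0][0] + 400,
                                    model.introns()[0][0] + 562))
        mix = simulate_isoform_mixture(model, [pe])
        cfg = SimConfig(n_samples=1, reads_per_sample=400, seed=2,
                        error_rate=0.0, homopolymer_indel_rate=0.0)
        simulate_reads(model, mix, genome, cfg, tmp_path)
        a, b = pe.pe_interval
        s, e = model.introns()[0]
        crossing = with_both = 0
        for rec in pysam.AlignmentFile(str(tmp_path / "sample1.sam"), check_sq=False):
            gaps = [(rec.reference_start, rec.cigartuples)]
            ref = rec.reference_start
            gaps = []
            for op, ln in rec.cigartuples:
                if op == 3:
                    gaps.append((ref, ref + ln))
                if op in (0, 2, 3, 7, 8):
                    ref += ln
            if rec.reference_start < s and ref > e:
                crossing += 1
                if (s, a) in gaps and (b, e) in gaps:
                    with_both += 1
        assert crossing > 0 and with_both == crossing

    def test_homopolymer_indels_produce_consistent_cigars(self, model, genome, tmp_path):
        mix = simulate_isoform_mixture(model, [])
        cfg = SimConfig(n_samples=1, reads_per_sample=300, seed=8,
                        error_rate=0.005, homopolymer_indel_rate=0.2)
        simulate_reads(model, mix, genome, cfg, tmp_path)
        n_indel = 0
        for rec in pysam.AlignmentFile(str(tmp_path / "sample1.sam"), check_sq=False):
            qlen = sum(ln for op, ln in rec.cigartuples if op in (0, 1, 4))
            assert qlen == len(rec.query_sequence)
            if any(op in (1, 2) for op, _ in rec.cigartuples):
                n_indel += 1
        assert n_indel > 0

    def test_invalid_config_rejected(self):
        with pytest.raises(SimulationConfigError):
            SimConfig(error_rate=1.5).validate()
        with pytest.raises(SimulationConfigError):
            SimConfig(read_length_mean=10).validate()


class TestCountVersusReadAgreement:
    def test_read_level_skip_fraction_matches_binomial(self, model, genome, tmp_path):
        # one skip at 50%: the ASE estimate from truth-SAM junction counts
        # must sit within 3 SE of the simulated rate
        from splicescope.event_annotation import annotate_junctions
        from splicescope.quantification import quantify_events

        ev = EventSpec("del9", "exon_skip", 0.5, skip_exons=(9,))
        mix = simulate_isoform_mixture(model, [ev])
        cfg = SimConfig(n_samples=1, reads_per_sample=10_000, seed=13,
                        error_rate=0.0, homopolymer_indel_rate=0.0)
        simulate_reads(model, mix, genome, cfg, tmp_path)
        table = count_junctions(tmp_path / "sample1.sam", min_anchor=1,
                                sample_id="sample1")
        ann = annotate_junctions(table.junctions(), model)
        (q,) = [
            x for x in quantify_events(ann.events, table, model)
            if x.event_id == "del9"
        ]
        n = q.inclusion_reads["sample1"] + q.exclusion_reads["sample1"]
        se = math.sqrt(0.25 / n) * 100
        assert abs(q.ase_percent["sample1"] - 50.0) < 3 * se


class TestMisalignmentArtifact:
    def test_zero_repeat_leaves_junction_unambiguous(self, model, genome):
        g2, shifts = inject_misalignment_artifact(model, genome, 30, 0)
        assert g2 == genome
        assert shifts[1] - shifts[0] >= 0

    def test_planted_repeat_widens_shift_range(self, model, genome):
        _, shifts = inject_misalignment_artifact(model, genome, 30, 4)
        assert shifts[1] >= 4

    def test_repeat_longer_than_exon_rejected(self, model, genome):
        with pytest.raises(ValueError):
            inject_misalignment_artifact(model, genome, 70, model.exons[70].length + 1)


def test_decoy_events_avoid_reserved_exons(model):
    decoys = decoy_skip_events(model, n=20, avoid_exons=[9, 71, 73, 74, 78])
    assert len(decoys) == 20
    used = {d.skip_exons[0] for d in decoys}
    assert used.isdisjoint({9, 71, 73, 74, 78})
    assert all(0.0001 <= d.rate <= 0.0005 for d in decoys)
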