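"""Event enumeration against truth, PSI arithmetic, quantification rules."""

import collections

import pytest

from splicemap.align import ReadAlignment, align_reads, count_junctions, read_fastq
from splicemap.annotation import GeneModel, build_junction_library
from splicemap.events import (
    ASEvent,
    compute_psi,
    enumerate_events,
    quantify_events,
)
from splicemap.simulate import SimulationConfig, simulate_annotation
from tests.conftest import make_gene, make_two_isoform_gene


def test_two_isoform_gene_yields_one_se_event():
    gene = make_two_isoform_gene(
        "g1",
        [(0, 100), (200, 300), (400, 500)],
        [(0, 100), (400, 500)],
    )
    events = enumerate_events([gene])
    assert len(events) == 1
    (ev,) = events
    assert ev.event_type == "SE"
    assert ev.interval_map["cassette"] == (200, 300)
    assert len(ev.inclusion_junctions) == 2 and len(ev.exclusion_junctions) == 1


def test_single_transcript_gene_yields_no_events():
    assert enumerate_events([make_gene("g1", [(0, 100), (200, 300)])]) == []


@pytest.mark.parametrize("strand", ["+", "-"])
def test_event_types_recovered_from_simulated_annotation(strand):
    expected = {"SE": 3, "IR": 2, "A5SS": 1, "A3SS": 1, "MXE": 1, "AFE": 1, "ALE": 1}
    cfg = SimulationConfig(
        seed=4,
        events_per_type=expected,
        n_background_genes=1,
        alternate_strands=(strand == "-"),  # exercise both pure-plus and mixed
    )
    genome, genes, truth = simulate_annotation(cfg)
    events = enumerate_events(genes)
    got = collections.Counter(e.event_type for e in events)
    assert got == collections.Counter(expected)
    # one event per event-gene, matching truth gene by gene
    truth_by_gene = truth.by_gene()
    for ev in events:
        assert truth_by_gene[ev.gene_id].event_type == ev.event_type


def test_enumeration_invariant_to_transcript_listing_for_symmetric_types():
    iso1 = [(0, 100), (200, 300), (400, 500)]
    iso2 = [(0, 100), (400, 500)]
    g_fwd = make_two_isoform_gene("g1", iso1, iso2)
    g_rev = make_two_isoform_gene("g1", iso2, iso1)
    ev_f = enumerate_events([g_fwd])
    ev_r = enumerate_events([g_rev])
    assert [e.event_id for e in ev_f] == [e.event_id for e in ev_r]


def test_duplicate_events_merged_across_transcript_pairs():
    # three transcripts; two pairs exhibit the same cassette event
    from splicemap.annotation import Exon, Transcript

    exons_inc = tuple(
        Exon("c1", s, e, "+") for s, e in [(0, 100), (200, 300), (400, 500)]
    )
    exons_exc = tuple(Exon("c1", s, e, "+") for s, e in [(0, 100), (400, 500)])
    gene = GeneModel(
        "g1",
        (
            Transcript("t1", "g1", exons_inc),
            Transcript("t2", "g1", exons_exc),
            Transcript("t3", "g1", exons_inc),
        ),
    )
    events = enumerate_events([gene])
    assert len(events) == 1


def test_mxe_inclusion_is_genomically_upstream_exon():
    gene = make_two_isoform_gene(
        "g1",
        [(0, 100), (500, 600), (800, 900)],  # downstream alt exon first listed
        [(0, 100), (200, 300), (800, 900)],
    )
    (ev,) = enumerate_events([gene])
    assert ev.event_type == "MXE"
    assert ev.interval_map["exon_a"] == (200, 300)


# ---------------------------------------------------------------------------
# PSI


def test_compute_psi_examples():
    assert compute_psi(10, 5, 2, 1) == pytest.approx(0.5)
    assert compute_psi(0, 7, 2, 1) == 0.0
    assert compute_psi(0, 0, 2, 1) is None
    with pytest.raises(ValueError):
        compute_psi(1, 1, 0, 1)


# ---------------------------------------------------------------------------
# Quantification


def _se_event():
    return ASEvent(
        event_id="SE|g1|x",
        event_type="SE",
        gene_id="g1",
        contig="c1",
        strand="+",
        intervals=(("cassette", (200, 300)),),
        inclusion_junctions=frozenset({"jA", "jB"}),
        exclusion_junctions=frozenset({"jC"}),
        n_inclusion=2,
        n_exclusion=1,
    )


def test_quantify_sums_reported_junctions():
    from splicemap.align import JunctionCount

    ev = _se_event()
    jc = {
        "jA": JunctionCount(4, 2),
        "jB": JunctionCount(6, 3),
        "jC": JunctionCount(5, 2),
    }
    (counts,) = quantify_events([ev], [], jc, "control", 50)
    assert counts.inclusion_reads == 10 and counts.exclusion_reads == 5
    assert compute_psi(
        counts.inclusion_reads,
        counts.exclusion_reads,
        counts.n_inclusion,
        counts.n_exclusion,
    ) == pytest.approx(0.5)


def test_quantify_unreported_junctions_contribute_zero():
    (counts,) = quantify_events([_se_event()], [], {}, "control", 50)
    assert (counts.inclusion_reads, counts.exclusion_reads) == (0, 0)


def test_quantify_rejects_junction_missing_from_library():
    with pytest.raises(KeyError):
        quantify_events([_se_event()], [], {}, "control", 50, library_ids={"jA"})


def test_ir_boundary_reads_require_six_nt_each_side():
    ev = ASEvent(
        event_id="IR|g1|x",
        event_type="IR",
        gene_id="g1",
        contig="c1",
        strand="+",
        intervals=(("intron", (100, 200)),),
        inclusion_junctions=frozenset(),
        exclusion_junctions=frozenset({"jC"}),
        inclusion_boundaries=(100, 200),
        n_inclusion=2,
        n_exclusion=1,
    )
    read_len = 50

    def galn(read_id, pos):
        return ReadAlignment(read_id, "genome", "c1", pos, "+", 0)

    alns = [
        galn("spans_left_exactly", 100 - 6),  # 6 nt right of boundary 100? -> covers [94,144): 6 left, 44 right
        galn("five_left", 100 - 5),  # only 5 nt on the left side
        galn("deep_cover", 120),  # covers boundary 200? [120,170): no
        galn("right_boundary", 160),  # covers 200 with 40/10 split
        galn("too_far", 500),
    ]
    (counts,) = quantify_events([ev], alns, {}, "s", read_len)
    assert counts.inclusion_reads == 2  # spans_left_exactly + right_boundary


def test_estimated_psi_tracks_truth_on_simulated_reads(sim_dataset):
    """|PSI_hat - PSI_true| small for well-covered simulated events."""
    genome, genes = sim_dataset["genome"], sim_dataset["genes"]
    cfg, truth = sim_dataset["config"], sim_dataset["truth"]
    junctions = build_junction_library(genes, genome, cfg.read_len)
    lib_ids = {j.junction_id for j in junctions}
    events = enumerate_events(genes)
    truth_by_gene = truth.by_gene()
    errs = []
    for sample, fq in (("control", sim_dataset["fastq_control"]),
                       ("treated", sim_dataset["fastq_treated"])):
        alns, _ = align_reads(read_fastq(fq), genome, junctions)
        jc = count_junctions(alns)
        counts = quantify_events(events, alns, jc, sample, cfg.read_len, 6, lib_ids)
        for c in counts:
            ev = truth_by_gene[c.gene_id]
            true_psi = ev.psi_control if sample == "control" else ev.psi_treated
            est = compute_psi(
                c.inclusion_reads, c.exclusion_reads, c.n_inclusion, c.n_exclusion
            )
            if est is None:
                continue
            if c.inclusion_reads + c.exclusion_reads >= 100:
                errs.append(abs(est - true_psi))
    assert errs, "no sufficiently covered events"
    assert sum(errs) / len(errs) < 0.05
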