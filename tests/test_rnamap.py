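"""Motif scanning, region geometry, map recovery of planted motifs, bands."""

import numpy as np
import pytest

from splicemap.annotation import GenomeSequence
from splicemap.events import ASEvent, enumerate_events
from splicemap.rnamap import (
    MotifSpec,
    build_motif_map,
    control_confidence_band,
    event_regions,
    extract_region_sequences,
    profile_matrix,
    scan_motif,
    upstream_window_enrichment,
)
from splicemap.simulate import MotifPlantRule, SimulationConfig, simulate_annotation


# ---------------------------------------------------------------------------
# Scanner


@pytest.mark.parametrize(
    "seq,expected",
    [
        ("ACUUAU", []),  # wildtype branchpoint: not a consensus site
        ("ACUAAU", [0]),  # the branchpoint-to-consensus mutation creates one
        ("ACUAACACUAAU", [0, 6]),
        ("actaat", [0]),  # DNA space, case-insensitive
        ("ACUAAUAAU", [0]),  # overlapping half-site not in the core spec
    ],
)
def test_scan_core_consensus(seq, expected):
    assert scan_motif(seq) == expected


def test_scan_half_sites_separately():
    assert scan_motif("ACUAAUAAU", MotifSpec.half_sites()) == [2, 5]


def test_overlapping_matches_allowed():
    assert scan_motif("TAATAAT", MotifSpec.half_sites()) == [0, 3]


# ---------------------------------------------------------------------------
# Region geometry


def _se_event(contig="c1", strand="+", left=(0, 100), cass=(200, 320), right=(420, 520)):
    return ASEvent(
        event_id=f"SE|g|{strand}",
        event_type="SE",
        gene_id="g",
        contig=contig,
        strand=strand,
        intervals=(
            ("cassette", cass),
            ("left_exon", left),
            ("right_exon", right),
        ),
        inclusion_junctions=frozenset({"a", "b"}),
        exclusion_junctions=frozenset({"c"}),
        n_inclusion=2,
        n_exclusion=1,
    )


@pytest.fixture(scope="module")
def toy_genome():
    rng = np.random.default_rng(12)
    return GenomeSequence({"c1": "".join(rng.choice(list("ACGT"), size=600))})


def test_region_extraction_plus_strand_coordinates(toy_genome):
    ev = _se_event()
    segs = extract_region_sequences(ev, toy_genome, U=20, I=80)
    seq = toy_genome["c1"]
    assert segs["up_exon"] == seq[80:100]
    assert segs["up_intron_5p"] == seq[100:180]
    assert segs["up_intron_3p"] == seq[120:200]
    assert segs["cassette"] == seq[200:320]
    assert segs["down_intron_5p"] == seq[320:400]
    assert segs["down_intron_3p"] == seq[340:420]
    assert segs["down_exon"] == seq[420:440]


def test_region_extraction_minus_strand_is_strand_symmetric(toy_genome):
    """Minus-strand regions equal the reverse complement of the mirrored gene."""
    from splicemap.annotation import reverse_complement

    plus = _se_event(strand="+")
    minus = _se_event(strand="-")
    segs_p = extract_region_sequences(plus, toy_genome, U=20, I=80)
    segs_m = extract_region_sequences(minus, toy_genome, U=20, I=80)
    seq = toy_genome["c1"]
    # on '-', the upstream exon is the genomically right one
    assert segs_m["up_exon"] == reverse_complement(seq[420:440])
    assert segs_m["up_intron_3p"] == reverse_complement(seq[320:400])
    assert segs_m["cassette"] == reverse_complement(seq[200:320])
    assert segs_m["down_exon"] == reverse_complement(seq[80:100])


def test_short_intron_masks_missing_positions(toy_genome):
    ev = _se_event(left=(0, 100), cass=(150, 270), right=(370, 470))  # introns 50/100
    mat = profile_matrix([ev], toy_genome, U=20, I=80)
    # segments: U=20 | I=80 | I=80 | E=50 | I=80 | I=80 | U=20
    up5 = mat[0, 20:100]
    assert np.isnan(up5[50:]).all() and not np.isnan(up5[:50]).any()
    up3 = mat[0, 100:180]
    assert np.isnan(up3[:30]).all() and not np.isnan(up3[30:]).any()


def test_terminal_cassette_raises(toy_genome):
    ev = ASEvent(
        event_id="A5SS|g|x",
        event_type="A5SS",
        gene_id="g",
        contig="c1",
        strand="+",
        intervals=(("long_exon", (0, 100)),),
        inclusion_junctions=frozenset({"a"}),
        exclusion_junctions=frozenset({"b"}),
    )
    with pytest.raises(ValueError):
        event_regions(ev, toy_genome)


# ---------------------------------------------------------------------------
# Map on simulated annotation with planted motifs


@pytest.fixture(scope="module")
def planted_dataset():
    psi = {}
    for i in range(1, 61):
        eid = f"SE{i:03d}"
        psi[eid] = (0.4, 0.8) if i <= 20 else (0.5, 0.5)
    cfg = SimulationConfig(
        seed=19,
        events_per_type={"SE": 60},
        psi=psi,
        n_background_genes=0,
        motif_plan=[MotifPlantRule("repressed", "upstream_intron", -25, "ACUAAU")],
    )
    genome, genes, truth = simulate_annotation(cfg)
    events = enumerate_events(genes)
    by_gene = truth.by_gene()
    sets = {"repressed": [], "control": []}
    for e in events:
        sets[by_gene[e.gene_id].label].append(e)
    return genome, sets


def test_planted_upstream_peak_is_profile_maximum(planted_dataset):
    genome, sets = planted_dataset
    profiles = build_motif_map(sets, genome, smooth_window=0)
    rep = profiles["repressed"].to_frame()
    peak = rep.loc[rep["raw_mean"].idxmax()]
    assert peak["segment"] == "up_intron_3p"
    assert -25 <= peak["offset"] <= -20
    assert peak["raw_mean"] == pytest.approx(1.0)  # every repressed exon has it
    # control stays flat at background level
    assert profiles["control"].raw_mean.max() < 0.5


def test_downstream_planting_gives_downstream_peak_only():
    cfg = SimulationConfig(
        seed=23,
        events_per_type={"SE": 15},
        psi={f"SE{i:03d}": (0.8, 0.3) for i in range(1, 16)},  # activated
        n_background_genes=0,
        motif_plan=[MotifPlantRule("activated", "downstream_intron", 30, "ACUAAU")],
    )
    genome, genes, _ = simulate_annotation(cfg)
    events = [e for e in enumerate_events(genes) if e.event_type == "SE"]
    (profile,) = build_motif_map({"activated": events}, genome, smooth_window=0).values()
    df = profile.to_frame()
    peak = df.loc[df["raw_mean"].idxmax()]
    assert peak["segment"] == "down_intron_5p" and peak["offset"] == 30
    up3 = profile.segment_values("up_intron_3p")
    assert np.nanmax(up3) < 0.5


def test_motif_count_conservation_on_deterministic_toy():
    """Profile totals equal the number of motif starts placed in the regions."""
    # motif-free background (all C) with five hand-placed consensus sites
    seq = list("C" * 800)
    # layout: left exon [0,100), intron [100,300), cassette [300,420),
    # intron [420,620), right exon [620,720)
    for pos in (90, 105, 350, 590, 627):
        seq[pos : pos + 6] = "ACTAAT"
    genome = GenomeSequence({"c1": "".join(seq)})
    ev = _se_event(left=(0, 100), cass=(300, 420), right=(620, 720))
    mat = profile_matrix([ev], genome, U=50, I=80, E=50)
    assert np.nansum(mat) == 5
    df_vals = mat[0]
    # up-exon hit 10 nt before the 5'ss -> index U-10 within the first segment
    assert df_vals[50 - 10] == 1
    # up-intron 5p offset 5
    assert df_vals[50 + 5] == 1
    # down-intron 3p: 30 nt before the 3'ss -> last segment index I-30
    assert df_vals[50 + 2 * 80 + 50 + 80 + (80 - 30)] == 1


def test_enrichment_null_identity(planted_dataset):
    """Testing a set against itself gives ratio 1 and an unremarkable p."""
    genome, sets = planted_dataset
    rep = sets["repressed"]  # guaranteed nonzero window density (planted)
    res = upstream_window_enrichment(rep, rep, genome, n_perm=400, seed=2)
    assert res.density_ratio == pytest.approx(1.0)
    assert 0.2 < res.p_value <= 1.0
    # zero-vs-zero window density is also a ratio of 1, not infinite
    ctrl = sets["control"]
    res0 = upstream_window_enrichment(ctrl, ctrl, genome, n_perm=50, seed=2)
    assert res0.density_ratio == pytest.approx(1.0)


def test_enrichment_detects_planted_window_motifs(planted_dataset):
    genome, sets = planted_dataset
    res = upstream_window_enrichment(
        sets["repressed"], sets["control"], genome, n_perm=1000, seed=2
    )
    assert res.density_ratio > 3
    assert res.p_value <= 1 / 1000 + 1e-9


def test_band_determinism_and_degenerate_level(planted_dataset):
    genome, sets = planted_dataset
    ctrl = sets["control"]
    b1 = control_confidence_band(ctrl, 10, genome, n_resamples=200, level=0.9, seed=7)
    b2 = control_confidence_band(ctrl, 10, genome, n_resamples=200, level=0.9, seed=7)
    assert np.array_equal(b1.low, b2.low, equal_nan=True)
    assert np.array_equal(b1.high, b2.high, equal_nan=True)
    b0 = control_confidence_band(ctrl, 10, genome, n_resamples=200, level=0.0, seed=7)
    assert np.allclose(b0.low, b0.high, equal_nan=True)


def test_band_warns_at_unachievable_level(planted_dataset):
    genome, sets = planted_dataset
    with pytest.warns(UserWarning, match="achievable"):
        band = control_confidence_band(
            sets["control"], 10, genome, n_resamples=100, level=0.999999, seed=1
        )
    assert band.level_achieved < band.level_requested


def test_band_rejects_small_pool(planted_dataset):
    genome, sets = planted_dataset
    with pytest.raises(ValueError):
        control_confidence_band(sets["control"][:5], 10, genome, n_resamples=50)


def test_null_sets_covered_and_planted_peak_escapes_band(planted_dataset):
    """Null draws stay inside the 95% band; the planted peak leaves it."""
    genome, sets = planted_dataset
    ctrl = sets["control"]
    size = len(sets["repressed"])
    band = control_confidence_band(
        ctrl, size, genome, n_resamples=1000, level=0.95, seed=29, smooth_window=0
    )
    mat = profile_matrix(ctrl, genome)
    rng = np.random.default_rng(31)
    coverages = []
    for _ in range(50):
        idx = rng.choice(len(ctrl), size, replace=False)
        mean = np.nanmean(mat[idx], axis=0)
        ok = (mean >= band.low - 1e-12) & (mean <= band.high + 1e-12)
        coverages.append(np.nanmean(ok.astype(float)))
    assert np.mean(coverages) >= 0.95
    rep_profile = build_motif_map(
        {"r": sets["repressed"]}, genome, smooth_window=0
    )["r"]
    peak_idx = int(np.nanargmax(rep_profile.raw_mean))
    assert rep_profile.raw_mean[peak_idx] > band.high[peak_idx]
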