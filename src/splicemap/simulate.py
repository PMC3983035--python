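"""Synthetic two-condition RNA-seq with known splicing ground truth.

The generator lays out one gene per alternative-splicing event, each with
exactly two isoforms differing only by that event, on a random-background
genome. Reads for a control and a treated (knockdown) condition are drawn
from the two isoforms at configured per-condition inclusion levels (PSI),
with i.i.d. substitution errors and a uniform start model. QKI-style
``ACUAAY`` motifs can be planted at fixed offsets around cassette exons to
emulate a positional regulatory code; every planted position, isoform
assignment and read origin is recorded so downstream stages can be scored
against exact truth.

Event types, defining-interval conventions and inclusion-isoform labels
match :mod:`splicemap.events`:

* SE  - cassette exon; inclusion isoform carries the exon.
* IR  - retained intron; "inclusion" is the retention (unspliced) isoform.
* A5SS/A3SS - alternative donor/acceptor; inclusion is the longer exon.
* MXE - mutually exclusive exons; inclusion is the genomically upstream one.
* AFE/ALE - alternative first/last exon; inclusion is the first-listed
  transcript's variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import (
    Exon,
    GeneModel,
    GenomeSequence,
    Transcript,
    reverse_complement,
    transcript_sequence,
)

__all__ = [
    "EVENT_TYPES",
    "MOTIFS",
    "MotifPlantRule",
    "SimulationConfig",
    "TruthEvent",
    "PlantedMotif",
    "GroundTruth",
    "simulate_annotation",
    "simulate_reads",
]

EVENT_TYPES = ("SE", "IR", "A5SS", "A3SS", "MXE", "AFE", "ALE")

#: QKI consensus hexamers and half sites, RNA alphabet.
MOTIFS = ("ACUAAU", "ACUAAC", "UAAU", "UAAC")

_CONTIG = "chrS"


def _rna_to_dna(motif: str) -> str:
    return motif.upper().replace("U", "T")


@dataclass(frozen=True)
class MotifPlantRule:
    """Plant ``motif`` at a fixed offset around every cassette exon of a set.

    ``label`` selects SE events by their regulation label (``activated``,
    ``repressed`` or ``control``). Regions and offsets (sense strand):

    * ``upstream_intron``: offset is negative, relative to the cassette 3'
      splice site; the motif occupies ``[3'ss+offset, 3'ss+offset+len)`` and
      must lie fully inside the intron (``offset + len(motif) <= 0``).
    * ``cassette_exon``: offset >= 0 from the exon start.
    * ``downstream_intron``: offset >= 0 from the cassette 5' splice site
      (first intronic base is offset 0).
    """

    label: str
    region: str
    offset: int
    motif: str

    def __post_init__(self) -> None:
        if self.region not in ("upstream_intron", "cassette_exon", "downstream_intron"):
            raise ValueError(f"unknown region {self.region!r}")
        if _rna_to_dna(self.motif) not in {_rna_to_dna(m) for m in MOTIFS}:
            raise ValueError(f"motif {self.motif!r} not in {MOTIFS}")


def _default_events_per_type() -> dict[str, int]:
    return {"SE": 5, "IR": 3, "A5SS": 2, "A3SS": 2, "MXE": 2, "AFE": 2, "ALE": 2}


@dataclass
class SimulationConfig:
    """Study conditions for one simulated experiment.

    ``depth`` is reads per transcript-kilobase per condition; ``psi`` maps an
    event id (e.g. ``"SE001"``) to its (control, treated) inclusion levels,
    falling back to ``default_psi``. Event ids are assigned deterministically
    as ``f"{type}{i:03d}"`` in the order of :data:`EVENT_TYPES`.
    """

    seed: int = 0
    read_len: int = 50
    events_per_type: Mapping[str, int] = field(default_factory=_default_events_per_type)
    psi: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    default_psi: tuple[float, float] = (0.5, 0.5)
    depth: float = 1000.0
    error_rate: float = 0.005
    exon_len: int = 150
    alt_exon_len: int = 120
    intron_len: int = 300
    ss_shift: int = 60
    spacer: int = 500
    n_background_genes: int = 2
    motif_plan: Sequence[MotifPlantRule] = ()
    alternate_strands: bool = True
    unstranded: bool = True

    def __post_init__(self) -> None:
        if self.read_len not in (50, 75):
            raise ValueError("read_len must be 50 or 75")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not 0 <= self.error_rate < 0.05:
            raise ValueError("error_rate must be in [0, 0.05)")
        if self.intron_len < 80:
            raise ValueError("intron_len must be >= 80")
        min_exon = 2 * (self.read_len - 6)
        if self.exon_len < min_exon or self.alt_exon_len < min_exon:
            raise ValueError(f"exon lengths must be >= {min_exon}")
        unknown = set(self.events_per_type) - set(EVENT_TYPES)
        if unknown:
            raise ValueError(f"unknown event types {sorted(unknown)}")
        if not (0 < self.ss_shift < self.alt_exon_len):
            raise ValueError("ss_shift must be in (0, alt_exon_len)")

    def psi_for(self, event_id: str) -> tuple[float, float]:
        pc, pt = self.psi.get(event_id, self.default_psi)
        if not (0 <= pc <= 1 and 0 <= pt <= 1):
            raise ValueError(f"psi out of [0,1] for {event_id}")
        return float(pc), float(pt)


@dataclass
class TruthEvent:
    event_id: str
    event_type: str
    gene_id: str
    strand: str
    label: str
    psi_control: float
    psi_treated: float
    intervals: dict[str, tuple[int, int]]
    inclusion_transcript: str
    exclusion_transcript: str

    @property
    def delta_psi(self) -> float:
        return self.psi_treated - self.psi_control


@dataclass(frozen=True)
class PlantedMotif:
    event_id: str
    label: str
    region: str
    offset: int
    motif: str
    contig: str
    genomic_start: int


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must rediscover."""

    events: list[TruthEvent]
    motifs: list[PlantedMotif]
    contig: str = _CONTIG
    read_origins: Optional[pd.DataFrame] = None

    def event(self, event_id: str) -> TruthEvent:
        for ev in self.events:
            if ev.event_id == event_id:
                return ev
        raise KeyError(event_id)

    def by_gene(self) -> dict[str, TruthEvent]:
        return {ev.gene_id: ev for ev in self.events}

    def events_frame(self) -> pd.DataFrame:
        rows = []
        for ev in self.events:
            row = {
                "event_id": ev.event_id,
                "event_type": ev.event_type,
                "gene_id": ev.gene_id,
                "strand": ev.strand,
                "label": ev.label,
                "psi_control": ev.psi_control,
                "psi_treated": ev.psi_treated,
                "delta_psi": ev.delta_psi,
                "inclusion_transcript": ev.inclusion_transcript,
                "exclusion_transcript": ev.exclusion_transcript,
            }
            for name, (s, e) in ev.intervals.items():
                row[f"{name}_start"], row[f"{name}_end"] = s, e
            rows.append(row)
        return pd.DataFrame(rows)

    def motifs_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(m) for m in self.motifs])


# ---------------------------------------------------------------------------
# Gene layouts (local coordinates, transcription direction)


def _layout(ev_type: str, cfg: SimulationConfig):
    """Return (gene_len, iso1_exons, iso2_exons, defining intervals), local coords.

    iso1 is the a-priori inclusion isoform (may be swapped after genomic
    mapping for MXE on the '-' strand).
    """
    E, C, I, d = cfg.exon_len, cfg.alt_exon_len, cfg.intron_len, cfg.ss_shift
    if ev_type == "SE":
        e1, cass, e2 = (0, E), (E + I, E + I + C), (E + 2 * I + C, 2 * E + 2 * I + C)
        return (
            e2[1],
            [e1, cass, e2],
            [e1, e2],
            {"cassette": cass, "left_exon": e1, "right_exon": e2},
        )
    if ev_type == "IR":
        e1, e2 = (0, E), (E + I, 2 * E + I)
        return (
            e2[1],
            [(0, 2 * E + I)],
            [e1, e2],
            {"intron": (E, E + I), "left_exon": e1, "right_exon": e2},
        )
    if ev_type == "A5SS":
        long, short, e2 = (0, E), (0, E - d), (E + I, 2 * E + I)
        return (
            e2[1],
            [long, e2],
            [short, e2],
            {"long_exon": long, "short_exon": short, "anchor_exon": e2},
        )
    if ev_type == "A3SS":
        e1, long, short = (0, E), (E + I, 2 * E + I), (E + I + d, 2 * E + I)
        return (
            long[1],
            [e1, long],
            [e1, short],
            {"long_exon": long, "short_exon": short, "anchor_exon": e1},
        )
    if ev_type == "MXE":
        e1 = (0, E)
        a = (E + I, E + I + C)
        b = (E + 2 * I + C, E + 2 * I + 2 * C)
        e2 = (E + 3 * I + 2 * C, 2 * E + 3 * I + 2 * C)
        return (
            e2[1],
            [e1, a, e2],
            [e1, b, e2],
            {"exon_a": a, "exon_b": b, "left_exon": e1, "right_exon": e2},
        )
    if ev_type == "AFE":
        f1, f2, shared = (0, E), (E + I, 2 * E + I), (2 * E + 2 * I, 3 * E + 2 * I)
        return (
            shared[1],
            [f1, shared],
            [f2, shared],
            {"exon_a": f1, "exon_b": f2, "shared_exon": shared},
        )
    if ev_type == "ALE":
        e1 = (0, E)
        l1 = (E + I, 2 * E + I)
        l2 = (2 * E + 2 * I, 3 * E + 2 * I)
        return (
            l2[1],
            [e1, l1],
            [e1, l2],
            {"exon_a": l1, "exon_b": l2, "shared_exon": e1},
        )
    raise ValueError(f"unknown event type {ev_type!r}")


def _map_interval(iv: tuple[int, int], offset: int, gene_len: int, strand: str):
    s, e = iv
    if strand == "+":
        return offset + s, offset + e
    return offset + gene_len - e, offset + gene_len - s


def _label_for(psi_c: float, psi_t: float) -> str:
    # Treated = regulator knockdown: inclusion rising on knockdown means the
    # regulator represses the exon; falling means it activates it.
    if psi_t > psi_c + 1e-12:
        return "repressed"
    if psi_t < psi_c - 1e-12:
        return "activated"
    return "control"


def simulate_annotation(
    config: SimulationConfig,
) -> tuple[GenomeSequence, list[GeneModel], GroundTruth]:
    """Build the toy genome, gene models and ground truth for ``config``.

    The genome background is uniform ACGT (seeded); planted motifs overwrite
    the background in DNA space on the sense strand of each gene.
    """
    rng = np.random.default_rng([int(config.seed) & 0x7FFFFFFF, 104729])
    genes: list[GeneModel] = []
    events: list[TruthEvent] = []
    gene_spans: dict[str, tuple[int, int, str]] = {}
    cursor = config.spacer
    gene_index = 0

    def next_strand() -> str:
        nonlocal gene_index
        s = "+" if (not config.alternate_strands or gene_index % 2 == 0) else "-"
        gene_index += 1
        return s

    for ev_type in EVENT_TYPES:
        for i in range(int(config.events_per_type.get(ev_type, 0))):
            event_id = f"{ev_type}{i + 1:03d}"
            gene_id = f"gene_{event_id}"
            strand = next_strand()
            gene_len, iso1_loc, iso2_loc, defin_loc = _layout(ev_type, config)
            iso_exons = []
            for loc in (iso1_loc, iso2_loc):
                ivs = sorted(
                    _map_interval(iv, cursor, gene_len, strand) for iv in loc
                )
                iso_exons.append(
                    tuple(Exon(_CONTIG, s, e, strand) for s, e in ivs)
                )
            intervals = {
                name: _map_interval(iv, cursor, gene_len, strand)
                for name, iv in defin_loc.items()
            }
            t1 = Transcript(f"{gene_id}.iso1", gene_id, iso_exons[0])
            t2 = Transcript(f"{gene_id}.iso2", gene_id, iso_exons[1])
            inclusion, exclusion = t1, t2
            if ev_type == "MXE" and intervals["exon_a"][0] > intervals["exon_b"][0]:
                # inclusion := isoform with the genomically upstream exon
                inclusion, exclusion = t2, t1
                intervals["exon_a"], intervals["exon_b"] = (
                    intervals["exon_b"],
                    intervals["exon_a"],
                )
            psi_c, psi_t = config.psi_for(event_id)
            events.append(
                TruthEvent(
                    event_id=event_id,
                    event_type=ev_type,
                    gene_id=gene_id,
                    strand=strand,
                    label=_label_for(psi_c, psi_t),
                    psi_control=psi_c,
                    psi_treated=psi_t,
                    intervals=intervals,
                    inclusion_transcript=inclusion.transcript_id,
                    exclusion_transcript=exclusion.transcript_id,
                )
            )
            genes.append(GeneModel(gene_id, (t1, t2)))
            gene_spans[gene_id] = (cursor, cursor + gene_len, strand)
            cursor += gene_len + config.spacer

    for i in range(config.n_background_genes):
        gene_id = f"gene_BG{i + 1:03d}"
        strand = next_strand()
        E, I = config.exon_len, config.intron_len
        gene_len = 2 * E + I
        ivs = sorted(
            _map_interval(iv, cursor, gene_len, strand)
            for iv in [(0, E), (E + I, 2 * E + I)]
        )
        tx = Transcript(
            f"{gene_id}.iso1",
            gene_id,
            tuple(Exon(_CONTIG, s, e, strand) for s, e in ivs),
        )
        genes.append(GeneModel(gene_id, (tx,)))
        gene_spans[gene_id] = (cursor, cursor + gene_len, strand)
        cursor += gene_len + config.spacer

    seq = bytearray(
        rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=cursor).tobytes()
    )

    motifs = _plant_motifs(seq, events, config)
    genome = GenomeSequence({_CONTIG: seq.decode()})
    return genome, genes, GroundTruth(events=events, motifs=motifs)


def _plant_motifs(
    seq: bytearray, events: Sequence[TruthEvent], config: SimulationConfig
) -> list[PlantedMotif]:
    planted: list[PlantedMotif] = []
    for rule in config.motif_plan:
        dna = _rna_to_dna(rule.motif)
        m = len(dna)
        targets = [
            ev
            for ev in events
            if ev.event_type == "SE" and ev.label == rule.label
        ]
        for ev in targets:
            cass = ev.intervals["cassette"]
            o = rule.offset
            if rule.region == "upstream_intron":
                if not (-config.intron_len <= o and o + m <= 0):
                    raise ValueError(
                        f"motif at offset {o} falls outside the upstream intron"
                    )
                if ev.strand == "+":
                    gstart = cass[0] + o
                    payload = dna
                else:
                    gstart = cass[1] - o - m
                    payload = reverse_complement(dna)
            elif rule.region == "cassette_exon":
                if not (0 <= o and o + m <= cass[1] - cass[0]):
                    raise ValueError(
                        f"motif at offset {o} falls outside the cassette exon"
                    )
                if ev.strand == "+":
                    gstart = cass[0] + o
                    payload = dna
                else:
                    gstart = cass[1] - o - m
                    payload = reverse_complement(dna)
            else:  # downstream_intron
                if not (0 <= o and o + m <= config.intron_len):
                    raise ValueError(
                        f"motif at offset {o} falls outside the downstream intron"
                    )
                if ev.strand == "+":
                    gstart = cass[1] + o
                    payload = dna
                else:
                    gstart = cass[0] - o - m
                    payload = reverse_complement(dna)
            seq[gstart : gstart + m] = payload.encode()
            planted.append(
                PlantedMotif(
                    event_id=ev.event_id,
                    label=ev.label,
                    region=rule.region,
                    offset=o,
                    motif=rule.motif.upper().replace("T", "U"),
                    contig=_CONTIG,
                    genomic_start=gstart,
                )
            )
    return planted


# ---------------------------------------------------------------------------
# Read simulation

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _add_errors(read: np.ndarray, rng: np.random.Generator, rate: float) -> int:
    """In-place i.i.d. substitution errors; returns the number introduced."""
    if rate <= 0:
        return 0
    mask = rng.random(read.size) < rate
    n = int(mask.sum())
    if n:
        # substitute with one of the three *other* bases
        idx = np.where(mask)[0]
        orig = read[idx]
        repl = _BASES[rng.integers(0, 3, size=n)]
        same = repl == orig
        while same.any():
            repl[same] = _BASES[rng.integers(0, 3, size=int(same.sum()))]
            same = repl == orig
        read[idx] = repl
    return n


def simulate_reads(
    genome: GenomeSequence,
    genes: Sequence[GeneModel],
    truth: GroundTruth,
    config: SimulationConfig,
    control_fastq: str | Path,
    treated_fastq: str | Path,
) -> pd.DataFrame:
    """Write control/treated FASTQ files; return the per-read origin table.

    PSI is the *molar* inclusion fraction: a fraction PSI of the gene's
    transcript molecules carry the inclusion isoform. Reads are sampled
    uniformly from the pooled transcript mass (as fragmentation of an RNA
    pool does), so a read comes from the inclusion isoform with probability
    ``PSI * len_inc / (PSI * len_inc + (1 - PSI) * len_exc)`` and its start
    is uniform over that isoform's admissible positions. Junction-spanning
    read counts are then proportional to molar isoform abundance, which is
    what junction-based PSI estimation assumes. I.i.d. substitution errors
    and (for unstranded libraries) a random read orientation are applied.
    Deterministic under the config seed; the origin table is also attached
    to ``truth.read_origins``.
    """
    rng = np.random.default_rng([int(config.seed) & 0x7FFFFFFF, 7919])
    truth_by_gene = truth.by_gene()
    records: list[tuple] = []
    qual = "I" * config.read_len
    for sample, psi_index, path in (
        ("control", 0, control_fastq),
        ("treated", 1, treated_fastq),
    ):
        with open(path, "w") as fh:
            for gene in genes:
                ev = truth_by_gene.get(gene.gene_id)
                tx_by_id = {t.transcript_id: t for t in gene.transcripts}
                if ev is not None:
                    inc = tx_by_id[ev.inclusion_transcript]
                    exc = tx_by_id[ev.exclusion_transcript]
                    psi = (ev.psi_control, ev.psi_treated)[psi_index]
                else:
                    inc = exc = gene.transcripts[0]
                    psi = 1.0
                mrna = {
                    t.transcript_id: np.frombuffer(
                        transcript_sequence(genome, t).encode(), dtype=np.uint8
                    )
                    for t in {inc, exc}
                }
                for t in (inc, exc):
                    if t.length < config.read_len:
                        raise ValueError(
                            f"transcript {t.transcript_id} shorter than a read"
                        )
                n_reads = max(
                    1,
                    int(round(config.depth * max(inc.length, exc.length) / 1000.0)),
                )
                # fragment sampled from the transcript mass: molar PSI weighted
                # by isoform length
                mass_inc = psi * inc.length
                mass = mass_inc + (1.0 - psi) * exc.length
                p_read_inc = mass_inc / mass if mass > 0 else 0.0
                pick_inc = rng.random(n_reads) < p_read_inc
                for i in range(n_reads):
                    tx = inc if pick_inc[i] else exc
                    arr = mrna[tx.transcript_id]
                    start = int(rng.integers(0, arr.size - config.read_len + 1))
                    read = arr[start : start + config.read_len].copy()
                    n_err = _add_errors(read, rng, config.error_rate)
                    flipped = bool(config.unstranded and rng.random() < 0.5)
                    seq = read.tobytes().decode()
                    if flipped:
                        seq = reverse_complement(seq)
                    read_id = f"{sample}|{gene.gene_id}|{i:06d}"
                    fh.write(f"@{read_id}\n{seq}\n+\n{qual}\n")
                    records.append(
                        (
                            read_id,
                            sample,
                            gene.gene_id,
                            tx.transcript_id,
                            start,
                            flipped,
                            n_err,
                        )
                    )
    origins = pd.DataFrame(
        records,
        columns=[
            "read_id",
            "sample",
            "gene_id",
            "transcript_id",
            "mrna_start",
            "flipped",
            "n_errors",
        ],
    )
    truth.read_origins = origins
    return origins


def read_true_junctions(
    transcript: Transcript, mrna_start: int, read_len: int, min_overhang: int = 1
) -> list[tuple[tuple[int, int], int]]:
    """Junctions (genomic intron bounds) a read spans, with its overhang.

    Used to score aligner output against read origins: a read starting at
    ``mrna_start`` on the spliced mRNA spans the k-th junction when it covers
    the exon boundary with at least ``min_overhang`` nt on each side.
    """
    out = []
    cum = 0
    introns = transcript.introns_in_transcription_order()
    exons = transcript.exons_in_transcription_order()
    for k, exon in enumerate(exons[:-1]):
        cum += len(exon)
        left = cum - mrna_start
        right = mrna_start + read_len - cum
        if left >= min_overhang and right >= min_overhang:
            out.append((introns[k], min(left, right)))
    return out
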