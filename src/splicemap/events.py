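"""Seven-type alternative-splicing event enumeration and quantification.

Events are found by pairwise comparison of the transcripts within each gene:
the two exon chains are split into maximal blocks of disagreement between
shared (coordinate-identical) exons, and each block is classified as one of

* SE   - cassette exon present in one chain between two shared neighbours
* IR   - one chain's single exon exactly spans the other's two exons plus
         the intervening intron
* A5SS / A3SS - a single exon pair sharing one boundary, alternative at the
         donor / acceptor side (strand-aware naming)
* MXE  - two non-overlapping single exons between shared neighbours
* AFE / ALE - non-overlapping terminal exons joined to a shared neighbour

Each event carries the junction ids giving inclusion and exclusion evidence;
inclusion counts are later summed over the inclusion junctions and
normalised per junction, which compensates the 2-vs-1 junction asymmetry of
SE and MXE events in the PSI estimate

    PSI = (inc / n_inc) / (inc / n_inc + exc / n_exc).

Intron retention has no inclusion junction: its retention evidence is
genome-aligned reads crossing either exon-intron boundary with at least the
junction overhang (6 nt) on each side, mirroring the junction rule.
"""

from __future__ import annotations

import itertools
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .align import ReadAlignment
from .annotation import Exon, GeneModel, Transcript, make_junction_id

__all__ = [
    "ASEvent",
    "EventCounts",
    "enumerate_events",
    "quantify_events",
    "compute_psi",
    "events_frame",
    "counts_frame",
]

EVENT_TYPES = ("SE", "IR", "A5SS", "A3SS", "MXE", "AFE", "ALE")


@dataclass(frozen=True)
class ASEvent:
    """One alternative-splicing event with its read-evidence definition."""

    event_id: str
    event_type: str
    gene_id: str
    contig: str
    strand: str
    intervals: tuple[tuple[str, tuple[int, int]], ...]
    inclusion_junctions: frozenset[str]
    exclusion_junctions: frozenset[str]
    inclusion_boundaries: tuple[int, ...] = ()
    n_inclusion: int = 1
    n_exclusion: int = 1

    def __post_init__(self) -> None:
        if self.inclusion_junctions & self.exclusion_junctions:
            raise ValueError(
                f"event {self.event_id}: inclusion/exclusion junctions overlap"
            )

    @property
    def interval_map(self) -> dict[str, tuple[int, int]]:
        return dict(self.intervals)


@dataclass(frozen=True)
class EventCounts:
    """Inclusion/exclusion read counts for one event in one sample."""

    event_id: str
    sample: str
    inclusion_reads: int
    exclusion_reads: int
    n_inclusion: int
    n_exclusion: int
    event_type: str
    gene_id: str

    def __post_init__(self) -> None:
        if self.inclusion_reads < 0 or self.exclusion_reads < 0:
            raise ValueError("negative read counts")


def _jid(gene: GeneModel, intron_start: int, intron_end: int) -> str:
    return make_junction_id(
        gene.gene_id, gene.contig, intron_start, intron_end, gene.strand
    )


def _coords(intervals: Mapping[str, tuple[int, int]]) -> str:
    return ";".join(f"{k}={s}-{e}" for k, (s, e) in sorted(intervals.items()))


def _make_event(
    gene: GeneModel,
    ev_type: str,
    intervals: dict[str, tuple[int, int]],
    inc: set[str],
    exc: set[str],
    n_inc: int,
    n_exc: int,
    boundaries: tuple[int, ...] = (),
) -> ASEvent:
    return ASEvent(
        event_id=f"{ev_type}|{gene.gene_id}|{_coords(intervals)}",
        event_type=ev_type,
        gene_id=gene.gene_id,
        contig=gene.contig,
        strand=gene.strand,
        intervals=tuple(sorted(intervals.items())),
        inclusion_junctions=frozenset(inc),
        exclusion_junctions=frozenset(exc),
        inclusion_boundaries=boundaries,
        n_inclusion=n_inc,
        n_exclusion=n_exc,
    )


def _classify_block(
    gene: GeneModel,
    left: Optional[Exon],
    a_block: list[Exon],
    b_block: list[Exon],
    right: Optional[Exon],
) -> list[ASEvent]:
    """Classify one disagreement block between two exon chains.

    ``a_block`` comes from the first-listed transcript of the pair, which
    defines the inclusion variant for AFE/ALE.
    """
    strand = gene.strand
    out: list[ASEvent] = []
    if not a_block and not b_block:
        return out

    # SE: exon in one chain only, flanked by shared exons adjacent in the other
    for blk, present_first in ((a_block, True), (b_block, False)):
        other = b_block if present_first else a_block
        if len(blk) == 1 and not other and left is not None and right is not None:
            x = blk[0]
            if left.end < x.start and x.end < right.start:
                inc = {
                    _jid(gene, left.end, x.start),
                    _jid(gene, x.end, right.start),
                }
                exc = {_jid(gene, left.end, right.start)}
                out.append(
                    _make_event(
                        gene,
                        "SE",
                        {
                            "cassette": (x.start, x.end),
                            "left_exon": (left.start, left.end),
                            "right_exon": (right.start, right.end),
                        },
                        inc,
                        exc,
                        2,
                        1,
                    )
                )
            return out

    # IR: one chain's single exon spans exactly the other's two exons + intron
    for one, two in ((a_block, b_block), (b_block, a_block)):
        if len(one) == 1 and len(two) == 2:
            x, (b1, b2) = one[0], two
            if x.start == b1.start and x.end == b2.end and b1.end < b2.start:
                exc = {_jid(gene, b1.end, b2.start)}
                out.append(
                    _make_event(
                        gene,
                        "IR",
                        {
                            "intron": (b1.end, b2.start),
                            "left_exon": (b1.start, b1.end),
                            "right_exon": (b2.start, b2.end),
                        },
                        set(),
                        exc,
                        2,
                        1,
                        boundaries=(b1.end, b2.start),
                    )
                )
                return out

    if len(a_block) == 1 and len(b_block) == 1:
        xa, xb = a_block[0], b_block[0]
        overlap = xa.start < xb.end and xb.start < xa.end
        if overlap:
            if xa.start == xb.start and xa.end != xb.end and right is not None:
                # alternative boundary facing the downstream (genomic right)
                long_e, short_e = (xa, xb) if xa.end > xb.end else (xb, xa)
                ev_type = "A5SS" if strand == "+" else "A3SS"
                inc = {_jid(gene, long_e.end, right.start)}
                exc = {_jid(gene, short_e.end, right.start)}
                out.append(
                    _make_event(
                        gene,
                        ev_type,
                        {
                            "long_exon": (long_e.start, long_e.end),
                            "short_exon": (short_e.start, short_e.end),
                            "anchor_exon": (right.start, right.end),
                        },
                        inc,
                        exc,
                        1,
                        1,
                    )
                )
            elif xa.end == xb.end and xa.start != xb.start and left is not None:
                long_e, short_e = (xa, xb) if xa.start < xb.start else (xb, xa)
                ev_type = "A3SS" if strand == "+" else "A5SS"
                inc = {_jid(gene, left.end, long_e.start)}
                exc = {_jid(gene, left.end, short_e.start)}
                out.append(
                    _make_event(
                        gene,
                        ev_type,
                        {
                            "long_exon": (long_e.start, long_e.end),
                            "short_exon": (short_e.start, short_e.end),
                            "anchor_exon": (left.start, left.end),
                        },
                        inc,
                        exc,
                        1,
                        1,
                    )
                )
            return out
        # non-overlapping singletons
        if left is not None and right is not None:
            # MXE; inclusion = genomically upstream exon
            up, down = (xa, xb) if xa.start < xb.start else (xb, xa)
            inc = {
                _jid(gene, left.end, up.start),
                _jid(gene, up.end, right.start),
            }
            exc = {
                _jid(gene, left.end, down.start),
                _jid(gene, down.end, right.start),
            }
            out.append(
                _make_event(
                    gene,
                    "MXE",
                    {
                        "exon_a": (up.start, up.end),
                        "exon_b": (down.start, down.end),
                        "left_exon": (left.start, left.end),
                        "right_exon": (right.start, right.end),
                    },
                    inc,
                    exc,
                    2,
                    2,
                )
            )
        elif (left is None) != (right is None):
            # terminal block: alternative first/last exon (strand decides which)
            shared = right if left is None else left
            genomic_left_terminus = left is None
            if genomic_left_terminus:
                ev_type = "AFE" if strand == "+" else "ALE"
                inc_j = _jid(gene, xa.end, shared.start)
                exc_j = _jid(gene, xb.end, shared.start)
            else:
                ev_type = "ALE" if strand == "+" else "AFE"
                inc_j = _jid(gene, shared.end, xa.start)
                exc_j = _jid(gene, shared.end, xb.start)
            if inc_j == exc_j:
                return out
            out.append(
                _make_event(
                    gene,
                    ev_type,
                    {
                        "exon_a": (xa.start, xa.end),
                        "exon_b": (xb.start, xb.end),
                        "shared_exon": (shared.start, shared.end),
                    },
                    {inc_j},
                    {exc_j},
                    1,
                    1,
                )
            )
    return out


def _pair_events(gene: GeneModel, ta: Transcript, tb: Transcript) -> list[ASEvent]:
    a, b = list(ta.exons), list(tb.exons)
    common = sorted(set(a) & set(b), key=lambda e: e.start)
    bounds = [None, *common, None]
    events: list[ASEvent] = []
    for left, right in itertools.pairwise(bounds):
        def _segment(chain: list[Exon]) -> list[Exon]:
            return [
                e
                for e in chain
                if e not in set(common)
                and (left is None or e.start >= left.end)
                and (right is None or e.end <= right.start)
            ]

        events.extend(
            _classify_block(gene, left, _segment(a), _segment(b), right)
        )
    return events


def enumerate_events(genes: Sequence[GeneModel]) -> list[ASEvent]:
    """All events found by pairwise transcript comparison, merged per gene.

    Duplicate events (same type and defining intervals) arising from
    different transcript pairs are emitted once. Single-transcript genes
    yield nothing.
    """
    out: list[ASEvent] = []
    for gene in genes:
        seen: dict[str, ASEvent] = {}
        for ta, tb in itertools.combinations(gene.transcripts, 2):
            for ev in _pair_events(gene, ta, tb):
                seen.setdefault(ev.event_id, ev)
        out.extend(seen.values())
    return out


def compute_psi(
    inclusion: int, exclusion: int, n_inc_junctions: int, n_exc_junctions: int
) -> Optional[float]:
    """Per-junction-normalised percent spliced in; ``None`` when unobserved."""
    if n_inc_junctions < 1 or n_exc_junctions < 1:
        raise ValueError("junction normalisation counts must be >= 1")
    if inclusion < 0 or exclusion < 0:
        raise ValueError("negative counts")
    inc = inclusion / n_inc_junctions
    exc = exclusion / n_exc_junctions
    if inc + exc == 0:
        return None
    return inc / (inc + exc)


def quantify_events(
    events: Sequence[ASEvent],
    alignments: Iterable[ReadAlignment],
    junction_counts: Mapping[str, "JunctionCount"],
    sample: str,
    read_len: int,
    boundary_overhang: int = 6,
    library_ids: Optional[set[str]] = None,
) -> list[EventCounts]:
    """Attach read evidence to events for one sample.

    Junction evidence sums the *total* reads of each reported junction
    (unreported junctions contribute zero). IR retention evidence counts
    genome alignments crossing either exon-intron boundary with at least
    ``boundary_overhang`` nt on both sides.
    """
    genome_starts: dict[str, np.ndarray] = {}
    tmp: dict[str, list[int]] = defaultdict(list)
    for aln in alignments:
        if aln.kind == "genome":
            tmp[aln.target].append(aln.pos)
    for contig, positions in tmp.items():
        genome_starts[contig] = np.sort(np.asarray(positions, dtype=np.int64))

    def boundary_reads(contig: str, boundary: int) -> int:
        starts = genome_starts.get(contig)
        if starts is None:
            return 0
        lo = boundary + boundary_overhang - read_len
        hi = boundary - boundary_overhang
        return int(
            np.searchsorted(starts, hi, side="right")
            - np.searchsorted(starts, lo, side="left")
        )

    def junction_total(jids: frozenset[str]) -> int:
        total = 0
        for j in jids:
            if library_ids is not None and j not in library_ids:
                raise KeyError(
                    f"event references junction {j} absent from the library"
                )
            jc = junction_counts.get(j)
            if jc is not None:
                total += jc.total
        return total

    out = []
    for ev in events:
        inc = junction_total(ev.inclusion_junctions)
        for b in ev.inclusion_boundaries:
            inc += boundary_reads(ev.contig, b)
        exc = junction_total(ev.exclusion_junctions)
        out.append(
            EventCounts(
                event_id=ev.event_id,
                sample=sample,
                inclusion_reads=inc,
                exclusion_reads=exc,
                n_inclusion=ev.n_inclusion,
                n_exclusion=ev.n_exclusion,
                event_type=ev.event_type,
                gene_id=ev.gene_id,
            )
        )
    return out


def events_frame(events: Sequence[ASEvent]) -> pd.DataFrame:
    rows = []
    for ev in events:
        iv = ev.interval_map
        rows.append(
            {
                "event_id": ev.event_id,
                "event_type": ev.event_type,
                "gene_id": ev.gene_id,
                "contig": ev.contig,
                "strand": ev.strand,
                "intervals": _coords(iv),
                "inclusion_junctions": ",".join(sorted(ev.inclusion_junctions)),
                "exclusion_junctions": ",".join(sorted(ev.exclusion_junctions)),
                "n_inclusion": ev.n_inclusion,
                "n_exclusion": ev.n_exclusion,
            }
        )
    return pd.DataFrame(rows)


def counts_frame(counts: Sequence[EventCounts]) -> pd.DataFrame:
    return pd.DataFrame([vars(c) for c in counts])
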