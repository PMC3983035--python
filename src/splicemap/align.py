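"""Hamming-distance read placement on a toy genome plus a junction library.

Reads are placed at every genome position (both orientations) and junction
offset where the mismatch count is at most ``max_mismatches``; a read is kept
only when exactly one placement attains the minimum mismatch count
(unique-best policy). Ambiguous and unplaceable reads are dropped and
tallied. Candidate generation uses a pigeonhole k-mer seed index: a read is
split into ``max_mismatches + 1`` disjoint seeds, at least one of which must
match exactly at any placement within the mismatch budget, so the seed scan
is exhaustive — equivalent to a full sliding-window Hamming scan.

Junction placements must physically span the junction point (>= 1 nt on each
side); the recorded ``overhang`` is the shorter flanking segment. Junction
evidence is then summarised per junction with the independence rule: a
junction is *reported* only when covered by at least ``min_independent``
reads at distinct start offsets, each with overhang >= ``min_overhang``.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .annotation import GenomeSequence, JunctionEntry, reverse_complement

__all__ = [
    "ReadAlignment",
    "JunctionCount",
    "ReadAligner",
    "align_reads",
    "count_junctions",
    "read_fastq",
    "write_alignment_table",
]

logger = logging.getLogger(__name__)

_ALLOWED = frozenset(b"ACGTN")


@dataclass(frozen=True)
class ReadAlignment:
    """Unique-best placement of one read.

    ``kind`` is ``"genome"`` (``target`` = contig, ``pos`` = forward-strand
    start) or ``"junction"`` (``target`` = junction id, ``pos`` = offset on
    the junction sequence). ``strand`` is the read orientation relative to
    the target. ``overhang`` (junctions only) is the shorter read segment on
    either side of the junction point.
    """

    read_id: str
    kind: str
    target: str
    pos: int
    strand: str
    mismatches: int
    overhang: Optional[int] = None


@dataclass(frozen=True)
class JunctionCount:
    """Read support for one junction."""

    total: int
    independent: int

    def __post_init__(self) -> None:
        if self.independent > self.total:
            raise ValueError("independent reads cannot exceed total reads")


class ReadAligner:
    """Seed-and-verify Hamming aligner over genome contigs + junction entries."""

    def __init__(
        self,
        genome: GenomeSequence,
        junction_library: Sequence[JunctionEntry],
        read_len: int,
        max_mismatches: int = 3,
    ):
        if read_len < (max_mismatches + 1):
            raise ValueError("read too short for the mismatch budget")
        self.read_len = int(read_len)
        self.max_mismatches = int(max_mismatches)
        self.k = max(1, self.read_len // (self.max_mismatches + 1))
        self._targets: list[tuple[str, str, np.ndarray, Optional[JunctionEntry]]] = []
        for name in genome:
            arr = np.frombuffer(genome[name].encode(), dtype=np.uint8)
            self._targets.append(("genome", name, arr, None))
        for entry in junction_library:
            arr = np.frombuffer(entry.sequence.encode(), dtype=np.uint8)
            self._targets.append(("junction", entry.junction_id, arr, entry))
        self._index: dict[bytes, list[tuple[int, int]]] = defaultdict(list)
        k = self.k
        for ti, (_, _, arr, _) in enumerate(self._targets):
            raw = arr.tobytes()
            for pos in range(0, len(raw) - k + 1):
                self._index[raw[pos : pos + k]].append((ti, pos))
        self._seed_offsets = [i * self.k for i in range(self.max_mismatches + 1)]

    def _placements(self, query: bytes) -> set[tuple[int, int, str, int]]:
        """All (target_idx, pos, orientation, mismatches) within budget."""
        L = self.read_len
        found: set[tuple[int, int, str, int]] = set()
        for orient, q in (("+", query), ("-", reverse_complement(query.decode()).encode())):
            qarr = np.frombuffer(q, dtype=np.uint8)
            cands: set[tuple[int, int]] = set()
            for off in self._seed_offsets:
                for ti, pos in self._index.get(q[off : off + self.k], ()):
                    cands.add((ti, pos - off))
            for ti, pos in cands:
                tarr = self._targets[ti][2]
                if pos < 0 or pos + L > tarr.size:
                    continue
                mm = int(np.count_nonzero(tarr[pos : pos + L] != qarr))
                if mm <= self.max_mismatches:
                    found.add((ti, pos, orient, mm))
        return found

    def map_read(self, read_id: str, sequence: str) -> tuple[Optional[ReadAlignment], str]:
        """Place one read; returns (alignment or None, status).

        Status is ``"unique"``, ``"ambiguous"`` or ``"unaligned"``.
        """
        seq = sequence.upper().replace("U", "T")
        if len(seq) != self.read_len:
            raise ValueError(
                f"read {read_id}: length {len(seq)} != aligner read_len {self.read_len}"
            )
        raw = seq.encode()
        if set(raw) - _ALLOWED:
            raise ValueError(f"read {read_id}: non-ACGTN characters")
        placements = []
        for ti, pos, orient, mm in self._placements(raw):
            kind, name, _, entry = self._targets[ti]
            if kind == "junction":
                left = entry.donor_flank - pos
                right = self.read_len - left
                if left < 1 or right < 1:
                    continue  # does not span the junction point
                placements.append((mm, ti, pos, orient, min(left, right)))
            else:
                placements.append((mm, ti, pos, orient, None))
        if not placements:
            return None, "unaligned"
        best = min(p[0] for p in placements)
        top = [p for p in placements if p[0] == best]
        if len(top) > 1:
            return None, "ambiguous"
        mm, ti, pos, orient, over = top[0]
        kind, name, _, _ = self._targets[ti]
        return (
            ReadAlignment(read_id, kind, name, pos, orient, mm, over),
            "unique",
        )


def align_reads(
    reads: Iterable[tuple[str, str]],
    genome: GenomeSequence,
    junction_library: Sequence[JunctionEntry],
    max_mismatches: int = 3,
    read_len: Optional[int] = None,
) -> tuple[list[ReadAlignment], dict[str, int]]:
    """Uniquely place each ``(read_id, sequence)``; drop the rest.

    Returns the unique alignments plus a tally dict with keys ``unique``,
    ``ambiguous`` and ``unaligned`` (also emitted as a log line).
    """
    reads = list(reads)
    if not reads:
        return [], {"unique": 0, "ambiguous": 0, "unaligned": 0}
    if read_len is None:
        read_len = len(reads[0][1])
    aligner = ReadAligner(genome, junction_library, read_len, max_mismatches)
    alignments: list[ReadAlignment] = []
    tally = {"unique": 0, "ambiguous": 0, "unaligned": 0}
    for read_id, seq in reads:
        aln, status = aligner.map_read(read_id, seq)
        tally[status] += 1
        if aln is not None:
            alignments.append(aln)
    logger.info(
        "aligned %d reads: %d unique, %d ambiguous, %d unaligned",
        len(reads),
        tally["unique"],
        tally["ambiguous"],
        tally["unaligned"],
    )
    return alignments, tally


def count_junctions(
    alignments: Iterable[ReadAlignment],
    min_overhang: int = 6,
    min_independent: int = 2,
) -> dict[str, JunctionCount]:
    """Per-junction read support, reported subset only.

    Counts junction alignments with overhang >= ``min_overhang``;
    "independent" reads are those at distinct start offsets. Only junctions
    with at least ``min_independent`` independent reads are returned.
    """
    totals: dict[str, int] = defaultdict(int)
    offsets: dict[str, set[int]] = defaultdict(set)
    for aln in alignments:
        if aln.kind != "junction" or (aln.overhang or 0) < min_overhang:
            continue
        totals[aln.target] += 1
        offsets[aln.target].add(aln.pos)
    return {
        j: JunctionCount(totals[j], len(offsets[j]))
        for j in totals
        if len(offsets[j]) >= min_independent
    }


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    """Load a FASTQ file as ``(read_id, sequence)`` pairs."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]


def write_alignment_table(
    alignments: Iterable[ReadAlignment], path: str | Path
) -> None:
    pd.DataFrame(
        [
            {
                "read_id": a.read_id,
                "kind": a.kind,
                "target": a.target,
                "pos": a.pos,
                "strand": a.strand,
                "mismatches": a.mismatches,
                "overhang": -1 if a.overhang is None else a.overhang,
            }
            for a in alignments
        ]
    ).to_csv(path, sep="\t", index=False)
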