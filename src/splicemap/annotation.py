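"""Genomes, gene models and splice-junction libraries.

All coordinates are 0-based, half-open on the forward genomic strand; GTF
input/output converts to/from the 1-based closed convention at the boundary.
"Downstream" is always meant in the direction of transcription, so on the
``-`` strand the donor exon of a junction is the genomically *rightmost* one.

A junction library joins every exon of a gene to every exon downstream of it
in transcription direction, pooled over all of the gene's transcripts. Each
entry carries ``flank_len = read_len - min_overhang`` nucleotides of exonic
sequence on each side of the junction (truncated when an exon is shorter),
so that a read aligning anywhere on the entry necessarily overhangs the
junction point by at least ``min_overhang`` nucleotides.
"""

from __future__ import annotations

import itertools
from collections import OrderedDict
from collections.abc import Mapping
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from gffutils.iterators import DataIterator

__all__ = [
    "reverse_complement",
    "GenomeSequence",
    "Exon",
    "Transcript",
    "GeneModel",
    "JunctionEntry",
    "read_fasta",
    "write_fasta",
    "read_gtf",
    "write_gtf",
    "junction_flank_length",
    "build_junction_library",
    "make_junction_id",
    "transcript_sequence",
    "write_junction_fasta",
    "write_junction_table",
]

_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an ``ACGTN`` string."""
    return seq.translate(_COMPLEMENT)[::-1]


class AnnotationError(ValueError):
    """Raised for malformed genomes, gene models or GTF input."""


class GenomeSequence(Mapping):
    """Immutable mapping of contig name to an uppercase ``ACGTN`` sequence.

    ``U`` is mapped to ``T`` and case is normalised on construction; any
    other non-``ACGTN`` character is rejected.
    """

    def __init__(self, contigs: Mapping[str, str]):
        if not contigs:
            raise AnnotationError("genome has no contigs")
        normalized: dict[str, str] = {}
        for name, seq in contigs.items():
            s = seq.upper().replace("U", "T")
            if not s:
                raise AnnotationError(f"contig {name!r} is empty")
            bad = set(s) - _ALPHABET
            if bad:
                raise AnnotationError(
                    f"contig {name!r} contains non-ACGTN characters: {sorted(bad)}"
                )
            normalized[name] = s
        self._contigs = normalized

    def __getitem__(self, key: str) -> str:
        return self._contigs[key]

    def __iter__(self) -> Iterator[str]:
        return iter(self._contigs)

    def __len__(self) -> int:
        return len(self._contigs)

    def length(self, contig: str) -> int:
        return len(self._contigs[contig])

    def fetch(self, contig: str, start: int, end: int) -> str:
        """Forward-strand slice ``[start, end)`` with strict bounds checking."""
        seq = self._contigs[contig]
        if not (0 <= start <= end <= len(seq)):
            raise AnnotationError(
                f"fetch [{start}, {end}) out of bounds for contig "
                f"{contig!r} of length {len(seq)}"
            )
        return seq[start:end]

    def fetch_sense(self, contig: str, start: int, end: int, strand: str) -> str:
        """Slice read 5'->3' on the transcribed (sense) strand."""
        s = self.fetch(contig, start, end)
        return reverse_complement(s) if strand == "-" else s


@dataclass(frozen=True, order=True)
class Exon:
    """Genomic interval of one exon (0-based half-open)."""

    contig: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"bad strand {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"bad exon interval [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Transcript:
    """Ordered (genomic) exon chain of one transcript isoform."""

    transcript_id: str
    gene_id: str
    exons: tuple[Exon, ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise AnnotationError(f"transcript {self.transcript_id}: no exons")
        contigs = {e.contig for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(contigs) > 1:
            raise AnnotationError(
                f"transcript {self.transcript_id}: exons on multiple contigs"
            )
        if len(strands) > 1:
            raise AnnotationError(
                f"transcript {self.transcript_id}: exons on mixed strands"
            )
        exons = tuple(sorted(self.exons, key=lambda e: e.start))
        for a, b in itertools.pairwise(exons):
            if b.start < a.end:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: overlapping exons "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )
        object.__setattr__(self, "exons", exons)

    @property
    def contig(self) -> str:
        return self.exons[0].contig

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def length(self) -> int:
        """Spliced (mRNA) length in nucleotides."""
        return sum(len(e) for e in self.exons)

    def exons_in_transcription_order(self) -> tuple[Exon, ...]:
        return self.exons if self.strand == "+" else tuple(reversed(self.exons))

    def introns_in_transcription_order(self) -> list[tuple[int, int]]:
        """Genomic ``(start, end)`` of each intron, ordered 5'->3' on the mRNA."""
        out = []
        for up, down in itertools.pairwise(self.exons_in_transcription_order()):
            left, right = (up, down) if self.strand == "+" else (down, up)
            out.append((left.end, right.start))
        return out


@dataclass(frozen=True)
class GeneModel:
    """All annotated isoforms of one gene, in annotation order."""

    gene_id: str
    transcripts: tuple[Transcript, ...]

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise AnnotationError(f"gene {self.gene_id}: no transcripts")
        for t in self.transcripts:
            if t.gene_id != self.gene_id:
                raise AnnotationError(
                    f"gene {self.gene_id}: transcript {t.transcript_id} "
                    f"belongs to {t.gene_id}"
                )
        if len({t.strand for t in self.transcripts}) > 1:
            raise AnnotationError(f"gene {self.gene_id}: mixed strands")
        if len({t.contig for t in self.transcripts}) > 1:
            raise AnnotationError(f"gene {self.gene_id}: multiple contigs")

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def contig(self) -> str:
        return self.transcripts[0].contig

    def pooled_exons(self) -> list[Exon]:
        """Distinct exons of all transcripts, sorted genomically."""
        return sorted({e for t in self.transcripts for e in t.exons})

    @property
    def span(self) -> tuple[int, int]:
        exons = self.pooled_exons()
        return exons[0].start, max(e.end for e in exons)


@dataclass(frozen=True)
class JunctionEntry:
    """One donor-acceptor junction with its flanking exonic sequence.

    ``sequence`` reads 5'->3' on the mRNA sense strand:
    the last ``donor_flank`` nt of the donor exon followed by the first
    ``acceptor_flank`` nt of the acceptor exon. ``donor_pos``/``acceptor_pos``
    are the genomic splice-site coordinates (exon end on the donor side,
    exon start on the acceptor side, in transcription direction).
    """

    junction_id: str
    gene_id: str
    contig: str
    strand: str
    donor_pos: int
    acceptor_pos: int
    flank_len: int
    donor_flank: int
    acceptor_flank: int
    truncated: bool
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) != self.donor_flank + self.acceptor_flank:
            raise AnnotationError(
                f"junction {self.junction_id}: sequence length mismatch"
            )
        if len(self.sequence) > 2 * self.flank_len:
            raise AnnotationError(
                f"junction {self.junction_id}: sequence longer than 2*flank_len"
            )

    @property
    def intron(self) -> tuple[int, int]:
        """Genomic (start, end) of the spliced-out intron."""
        if self.strand == "+":
            return self.donor_pos, self.acceptor_pos
        return self.acceptor_pos, self.donor_pos


def make_junction_id(
    gene_id: str, contig: str, intron_start: int, intron_end: int, strand: str
) -> str:
    """Stable junction key: gene, contig, genomic intron bounds, strand."""
    return f"{gene_id}|{contig}|{intron_start}|{intron_end}|{strand}"


# ---------------------------------------------------------------------------
# FASTA / GTF I/O


def read_fasta(path: str | Path) -> GenomeSequence:
    """Read a (multi-)FASTA into a :class:`GenomeSequence`.

    Sequences are uppercased and ``U`` is mapped to ``T``; duplicate contig
    names, empty records and non-ACGTN characters are rejected.
    """
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in contigs:
            raise AnnotationError(f"duplicate contig name {rec.id!r}")
        contigs[rec.id] = str(rec.seq)
    return GenomeSequence(contigs)


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in genome:
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Parse Ensembl-dialect GTF ``exon`` features into gene models.

    Only ``exon`` features are consumed; each must carry ``gene_id`` and
    ``transcript_id`` attributes. 1-based closed GTF coordinates are converted
    to 0-based half-open. Transcripts and genes keep their file order (the
    first-listed transcript defines the "inclusion" variant of AFE/ALE events
    downstream).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    tx_exons: OrderedDict[str, list[Exon]] = OrderedDict()
    tx_gene: dict[str, str] = {}
    gene_order: OrderedDict[str, list[str]] = OrderedDict()
    for feat in DataIterator(str(path)):
        if feat.featuretype != "exon":
            continue
        gene_ids = feat.attributes.get("gene_id", [])
        tx_ids = feat.attributes.get("transcript_id", [])
        if not tx_ids or not gene_ids:
            raise AnnotationError(
                f"exon at {feat.seqid}:{feat.start}-{feat.end} lacks "
                "gene_id/transcript_id"
            )
        gid, tid = gene_ids[0], tx_ids[0]
        exon = Exon(feat.seqid, feat.start - 1, feat.end, feat.strand)
        if tid in tx_gene and tx_gene[tid] != gid:
            raise AnnotationError(f"transcript {tid} listed under two genes")
        if tid not in tx_gene:
            tx_gene[tid] = gid
            tx_exons[tid] = []
            gene_order.setdefault(gid, []).append(tid)
        tx_exons[tid].append(exon)
    if not tx_exons:
        raise AnnotationError(f"no exon features in {path}")
    genes = []
    for gid, tids in gene_order.items():
        transcripts = tuple(
            Transcript(tid, gid, tuple(tx_exons[tid])) for tid in tids
        )
        genes.append(GeneModel(gid, transcripts))
    return genes


def write_gtf(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models as GTF exon features (1-based closed coordinates)."""
    with open(path, "w") as fh:
        for gene in genes:
            for tx in gene.transcripts:
                for exon in tx.exons:
                    attrs = (
                        f'gene_id "{gene.gene_id}"; '
                        f'transcript_id "{tx.transcript_id}";'
                    )
                    fh.write(
                        "\t".join(
                            [
                                exon.contig,
                                "splicemap",
                                "exon",
                                str(exon.start + 1),
                                str(exon.end),
                                ".",
                                exon.strand,
                                ".",
                                attrs,
                            ]
                        )
                        + "\n"
                    )


def transcript_sequence(genome: GenomeSequence, transcript: Transcript) -> str:
    """Spliced mRNA sequence, 5'->3' on the sense strand."""
    concat = "".join(
        genome.fetch(e.contig, e.start, e.end) for e in transcript.exons
    )
    return reverse_complement(concat) if transcript.strand == "-" else concat


# ---------------------------------------------------------------------------
# Junction library


def junction_flank_length(read_len: int, min_overhang: int) -> int:
    """Exonic flank placed on each side of a junction.

    A read of length ``read_len`` aligned anywhere on a
    ``2 * (read_len - min_overhang)``-nt junction sequence must cross the
    junction point with at least ``min_overhang`` nt on each side, so the
    flank is ``read_len - min_overhang`` (44 nt for 50-nt reads and 69 nt for
    75-nt reads at the default 6-nt overhang).
    """
    if min_overhang < 1:
        raise ValueError("min_overhang must be >= 1")
    if read_len <= min_overhang:
        raise ValueError(
            f"read_len ({read_len}) must exceed min_overhang ({min_overhang})"
        )
    return read_len - min_overhang


def build_junction_library(
    genes: Sequence[GeneModel],
    genome: GenomeSequence,
    read_len: int,
    min_overhang: int = 6,
) -> list[JunctionEntry]:
    """Join every exon to all downstream exons within each gene.

    Exons are pooled over all transcripts of a gene and every ordered pair
    (donor, acceptor) with the acceptor strictly downstream in transcription
    direction yields one entry, deduplicated by splice-site coordinates.
    When several pooled exons share a splice site, the flank is taken from
    the longest one; exons shorter than the flank truncate it (flagged).
    """
    flank = junction_flank_length(read_len, min_overhang)
    entries: list[JunctionEntry] = []
    for gene in genes:
        contig, strand = gene.contig, gene.strand
        exons = gene.pooled_exons()
        # longest exonic extent available at each splice-site coordinate
        left_ext: dict[int, int] = {}
        right_ext: dict[int, int] = {}
        for e in exons:
            left_ext[e.end] = max(left_ext.get(e.end, 0), len(e))
            right_ext[e.start] = max(right_ext.get(e.start, 0), len(e))
        seen: set[tuple[int, int]] = set()
        for left in exons:
            for right in exons:
                if right.start <= left.end:
                    continue  # overlapping or abutting: no intron
                key = (left.end, right.start)
                if key in seen:
                    continue
                seen.add(key)
                dl = min(flank, left_ext[left.end])
                dr = min(flank, right_ext[right.start])
                plus_seq = genome.fetch(
                    contig, left.end - dl, left.end
                ) + genome.fetch(contig, right.start, right.start + dr)
                if strand == "+":
                    seq, donor_flank, acceptor_flank = plus_seq, dl, dr
                    donor_pos, acceptor_pos = left.end, right.start
                else:
                    seq = reverse_complement(plus_seq)
                    donor_flank, acceptor_flank = dr, dl
                    donor_pos, acceptor_pos = right.start, left.end
                entries.append(
                    JunctionEntry(
                        junction_id=make_junction_id(
                            gene.gene_id, contig, left.end, right.start, strand
                        ),
                        gene_id=gene.gene_id,
                        contig=contig,
                        strand=strand,
                        donor_pos=donor_pos,
                        acceptor_pos=acceptor_pos,
                        flank_len=flank,
                        donor_flank=donor_flank,
                        acceptor_flank=acceptor_flank,
                        truncated=(dl < flank or dr < flank),
                        sequence=seq,
                    )
                )
    return entries


def write_junction_fasta(
    entries: Iterable[JunctionEntry], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for entry in entries:
            fh.write(f">{entry.junction_id}\n{entry.sequence}\n")


def write_junction_table(
    entries: Iterable[JunctionEntry], path: str | Path
) -> None:
    """TSV index of a junction library."""
    import pandas as pd

    rows = [
        {
            "junction_id": e.junction_id,
            "gene_id": e.gene_id,
            "contig": e.contig,
            "strand": e.strand,
            "donor_pos": e.donor_pos,
            "acceptor_pos": e.acceptor_pos,
            "flank_len": e.flank_len,
            "donor_flank": e.donor_flank,
            "acceptor_flank": e.acceptor_flank,
            "truncated": e.truncated,
        }
        for e in entries
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
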