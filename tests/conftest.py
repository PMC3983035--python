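"""Shared fixtures: tiny hand-built annotations and a reusable simulation."""

import numpy as np
import pytest

from splicemap.annotation import Exon, GeneModel, GenomeSequence, Transcript
from splicemap.simulate import SimulationConfig, simulate_annotation, simulate_reads


def make_gene(gene_id, exon_coords, *, contig="c1", strand="+", n_tx=1):
    """Single-transcript gene from a list of (start, end) pairs."""
    exons = tuple(Exon(contig, s, e, strand) for s, e in exon_coords)
    txs = tuple(
        Transcript(f"{gene_id}.t{i+1}", gene_id, exons) for i in range(n_tx)
    )
    return GeneModel(gene_id, txs)


def make_two_isoform_gene(gene_id, iso1, iso2, *, contig="c1", strand="+"):
    t1 = Transcript(
        f"{gene_id}.t1", gene_id, tuple(Exon(contig, s, e, strand) for s, e in iso1)
    )
    t2 = Transcript(
        f"{gene_id}.t2", gene_id, tuple(Exon(contig, s, e, strand) for s, e in iso2)
    )
    return GeneModel(gene_id, (t1, t2))


@pytest.fixture(scope="session")
def random_genome():
    """1-contig 5 kb random genome (seeded)."""
    rng = np.random.default_rng(42)
    seq = "".join(rng.choice(list("ACGT"), size=5000))
    return GenomeSequence({"c1": seq})


@pytest.fixture(scope="session")
def sim_dataset(tmp_path_factory):
    """One full simulated dataset with reads, shared across tests.

    Two events carry real PSI shifts; everything else is null. Error-free
    reads so alignment truth is exact.
    """
    cfg = SimulationConfig(
        seed=11,
        depth=1600,
        error_rate=0.0,
        psi={"SE001": (0.2, 0.8), "MXE001": (0.7, 0.3)},
    )
    genome, genes, truth = simulate_annotation(cfg)
    d = tmp_path_factory.mktemp("simreads")
    fq_c, fq_t = d / "control.fastq", d / "treated.fastq"
    origins = simulate_reads(genome, genes, truth, cfg, fq_c, fq_t)
    return {
        "config": cfg,
        "genome": genome,
        "genes": genes,
        "truth": truth,
        "origins": origins,
        "fastq_control": fq_c,
        "fastq_treated": fq_t,
    }
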