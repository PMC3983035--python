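"""End-to-end orchestration: simulate -> junctions -> align -> events ->
test -> rna-map, with a manifest for reproducibility.

Each stage writes plain-text TSV/FASTA/FASTQ outputs into a run directory;
the manifest records parameters, the seed, per-stage read tallies and
SHA-256 hashes of every written file, so a rerun with the same inputs and
seed is bitwise-identical. Defaults reproduce the reference analysis
parameters: 6-nt minimum junction overhang, up to 3 mismatches, >= 2
independent junction reads, BH alpha 0.05, RPKM >= 0.5 with a > 2-fold
abundance change.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import annotation as ann
from . import align as al
from . import events as ev
from . import rnamap as rm
from . import stats as st
from .simulate import GroundTruth, SimulationConfig, simulate_annotation, simulate_reads

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "summarize"]

logger = logging.getLogger(__name__)

SAMPLES = ("control", "treated")


class PipelineError(RuntimeError):
    """Stage failure; carries the stage name for the exit message."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage: {stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Parameters of one pipeline run.

    Either ``simulation`` is given (synthetic mode) or all four input paths
    (genome FASTA, GTF, control/treated FASTQ). Threshold defaults follow
    the reference analysis.
    """

    simulation: Optional[SimulationConfig] = None
    genome_fasta: Optional[str] = None
    gtf: Optional[str] = None
    fastq_control: Optional[str] = None
    fastq_treated: Optional[str] = None
    read_len: int = 50
    min_overhang: int = 6
    max_mismatches: int = 3
    min_independent: int = 2
    alpha: float = 0.05
    min_rpkm: float = 0.5
    min_fold: float = 2.0
    min_delta_psi: float = 0.0
    map_U: int = 50
    map_I: int = 250
    map_E: int = 50
    map_smooth: int = 20
    map_band_level: float = 0.999999
    map_resamples: int = 2000
    map_n_perm: int = 2000
    control_q_min: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.simulation is None:
            missing = [
                n
                for n in ("genome_fasta", "gtf", "fastq_control", "fastq_treated")
                if getattr(self, n) is None
            ]
            if missing:
                raise ValueError(
                    f"no simulation config and missing input paths: {missing}"
                )
        else:
            self.read_len = self.simulation.read_len


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - rewrap with stage name
                raise PipelineError(name, str(exc)) from exc

        return wrapped

    return deco


@_stage("annotation")
def _load_inputs(config: RunConfig, out: Path):
    truth: Optional[GroundTruth] = None
    if config.simulation is not None:
        genome, genes, truth = simulate_annotation(config.simulation)
        fq_c, fq_t = out / "reads_control.fastq", out / "reads_treated.fastq"
        simulate_reads(genome, genes, truth, config.simulation, fq_c, fq_t)
        ann.write_fasta(genome, out / "genome.fa")
        ann.write_gtf(genes, out / "annotation.gtf")
        truth.events_frame().to_csv(out / "truth_events.tsv", sep="\t", index=False)
        if truth.motifs:
            truth.motifs_frame().to_csv(out / "truth_motifs.tsv", sep="\t", index=False)
        truth.read_origins.to_csv(out / "truth_read_origins.tsv", sep="\t", index=False)
    else:
        for name in ("genome_fasta", "gtf", "fastq_control", "fastq_treated"):
            p = getattr(config, name)
            if not Path(p).exists():
                raise PipelineError("annotation", f"missing input file {p} ({name})")
        genome = ann.read_fasta(config.genome_fasta)
        genes = ann.read_gtf(config.gtf)
        fq_c, fq_t = Path(config.fastq_control), Path(config.fastq_treated)
    return genome, genes, truth, fq_c, fq_t


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Run every stage into ``out_dir``; returns the run directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "parameters": _config_dict(config),
        "seed": config.seed,
        "stages": [],
    }

    genome, genes, truth, fq_c, fq_t = _load_inputs(config, out)
    manifest["stages"].append("annotation")

    junctions = _stage("junctions")(ann.build_junction_library)(
        genes, genome, config.read_len, config.min_overhang
    )
    ann.write_junction_fasta(junctions, out / "junctions.fa")
    ann.write_junction_table(junctions, out / "junctions.tsv")
    manifest["stages"].append("junctions")
    library_ids = {j.junction_id for j in junctions}

    events = _stage("events")(ev.enumerate_events)(genes)
    ev.events_frame(events).to_csv(out / "events.tsv", sep="\t", index=False)
    manifest["stages"].append("events")

    counts_by_sample = {}
    aln_by_sample = {}
    tallies = {}
    for sample, fq in zip(SAMPLES, (fq_c, fq_t)):
        reads = _stage("align")(al.read_fastq)(fq)
        alignments, tally = _stage("align")(al.align_reads)(
            reads, genome, junctions, config.max_mismatches, config.read_len
        )
        al.write_alignment_table(alignments, out / f"alignments_{sample}.tsv")
        jc = al.count_junctions(
            alignments, config.min_overhang, config.min_independent
        )
        counts = _stage("quantify")(ev.quantify_events)(
            events,
            alignments,
            jc,
            sample,
            config.read_len,
            config.min_overhang,
            library_ids,
        )
        counts_by_sample[sample] = counts
        aln_by_sample[sample] = alignments
        tallies[sample] = tally
    pd.concat(
        [ev.counts_frame(counts_by_sample[s]) for s in SAMPLES]
    ).to_csv(out / "event_counts.tsv", sep="\t", index=False)
    manifest["alignment_tallies"] = tallies
    manifest["stages"].append("align+quantify")

    results = _stage("test")(st.test_all_events)(
        counts_by_sample["control"], counts_by_sample["treated"], config.alpha
    )
    if config.min_delta_psi > 0:
        results = [
            dataclasses.replace(
                r,
                significant=r.significant and abs(r.delta_psi) >= config.min_delta_psi,
                direction=(
                    r.direction
                    if r.significant and abs(r.delta_psi) >= config.min_delta_psi
                    else None
                ),
            )
            for r in results
        ]
    st.results_frame(results).to_csv(out / "splicing_results.tsv", sep="\t", index=False)
    n_sig, n_genes = st.significant_summary(results)
    manifest["significant_events"] = n_sig
    manifest["significant_genes"] = n_genes
    logger.info("%d events in %d genes significant", n_sig, n_genes)
    manifest["stages"].append("test")

    expression = _stage("expression")(_expression_table)(
        genes, junctions, aln_by_sample, config
    )
    expression.to_csv(out / "expression.tsv", sep="\t", index=False)
    manifest["expression_changed_genes"] = int(expression["passes_filter"].sum())
    manifest["stages"].append("expression")

    map_summary = _stage("rna_map")(_rna_map_stage)(
        events, results, genome, config, out
    )
    manifest["rna_map"] = map_summary
    manifest["stages"].append("rna_map")

    files = sorted(p.name for p in out.iterdir() if p.is_file() and p.name != "manifest.json")
    manifest["files"] = {name: _sha256(out / name) for name in files}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    if config.simulation is not None:
        d["simulation"]["events_per_type"] = dict(
            config.simulation.events_per_type
        )
        d["simulation"]["psi"] = {k: list(v) for k, v in config.simulation.psi.items()}
        d["simulation"]["motif_plan"] = [
            dataclasses.asdict(r) for r in config.simulation.motif_plan
        ]
    return d


def _expression_table(
    genes: Sequence[ann.GeneModel],
    junctions: Sequence[ann.JunctionEntry],
    aln_by_sample: dict,
    config: RunConfig,
) -> pd.DataFrame:
    """Per-gene uniquely mapped read counts, RPKM and the abundance filter."""
    junction_gene = {j.junction_id: j.gene_id for j in junctions}
    spans = sorted(
        (g.span[0], g.span[1], g.gene_id, g.contig) for g in genes
    )
    starts = np.array([s[0] for s in spans])

    def gene_of(contig: str, pos: int) -> Optional[str]:
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i >= 0:
            s, e, gid, ctg = spans[i]
            if ctg == contig and s <= pos < e:
                return gid
        return None

    lengths = {
        g.gene_id: sum(len(e) for e in g.pooled_exons()) for g in genes
    }
    counts = {g.gene_id: [0, 0] for g in genes}
    totals = [0, 0]
    for col, sample in enumerate(SAMPLES):
        for a in aln_by_sample[sample]:
            totals[col] += 1
            gid = (
                junction_gene.get(a.target)
                if a.kind == "junction"
                else gene_of(a.target, a.pos)
            )
            if gid is not None:
                counts[gid][col] += 1
    passing = set(
        st.rpkm_and_expression_filter(
            {g: tuple(c) for g, c in counts.items()},
            lengths,
            (max(totals[0], 1), max(totals[1], 1)),
            config.min_rpkm,
            config.min_fold,
        )
    )
    rows = []
    for gid, (c_c, c_t) in counts.items():
        rows.append(
            {
                "gene_id": gid,
                "length_nt": lengths[gid],
                "count_control": c_c,
                "count_treated": c_t,
                "rpkm_control": st.rpkm(c_c, max(totals[0], 1), lengths[gid]),
                "rpkm_treated": st.rpkm(c_t, max(totals[1], 1), lengths[gid]),
                "passes_filter": gid in passing,
            }
        )
    return pd.DataFrame(rows)


def _rna_map_stage(
    events: Sequence[ev.ASEvent],
    results: Sequence[st.SplicingTestResult],
    genome: ann.GenomeSequence,
    config: RunConfig,
    out: Path,
) -> dict:
    """Build the positional motif map from the test results.

    Sets: significant SE events split by direction; control = tested SE
    events with q >= ``control_q_min``. Skipped (with a note) when the
    repressed or control set is empty at desk scale.
    """
    by_id = {e.event_id: e for e in events}
    sets: dict[str, list] = {"activated": [], "repressed": [], "control": []}
    for r in results:
        if r.event_type != "SE":
            continue
        event = by_id[r.event_id]
        if r.significant and r.direction:
            sets[r.direction].append(event)
        elif r.q >= config.control_q_min:
            sets["control"].append(event)
    summary = {label: len(evs) for label, evs in sets.items()}
    if not sets["control"] or not (sets["activated"] or sets["repressed"]):
        summary["skipped"] = True
        return summary
    populated = {k: v for k, v in sets.items() if v}
    profiles = rm.build_motif_map(
        populated,
        genome,
        U=config.map_U,
        I=config.map_I,
        E=config.map_E,
        smooth_window=config.map_smooth,
    )
    frames = []
    for label, profile in profiles.items():
        if label != "control":
            band = rm.control_confidence_band(
                sets["control"],
                min(profile.n_events, len(sets["control"])),
                genome,
                n_resamples=config.map_resamples,
                level=config.map_band_level,
                seed=config.seed,
                U=config.map_U,
                I=config.map_I,
                E=config.map_E,
                smooth_window=config.map_smooth,
            )
            profile.band_low, profile.band_high = band.low, band.high
            summary[f"band_level_{label}"] = band.level_achieved
        frames.append(profile.to_frame())
    pd.concat(frames).to_csv(out / "rna_map_profiles.tsv", sep="\t", index=False)
    if sets["repressed"]:
        enr = rm.upstream_window_enrichment(
            sets["repressed"],
            sets["control"],
            genome,
            n_perm=config.map_n_perm,
            seed=config.seed,
        )
        pd.DataFrame([dataclasses.asdict(enr)]).to_csv(
            out / "rna_map_enrichment.tsv", sep="\t", index=False
        )
        summary["upstream_enrichment_ratio"] = enr.density_ratio
        summary["upstream_enrichment_p"] = enr.p_value
    return summary


def summarize(run_dir: str | Path) -> dict:
    """Pure summary of a completed run directory.

    Reports significant events per type, affected genes, direction
    breakdown and — when ground truth is present — recovery of the planted
    events (sensitivity and observed false-discovery proportion, matching
    caller events to truth by gene and type).
    """
    run = Path(run_dir)
    res_path = run / "splicing_results.tsv"
    if not res_path.exists():
        raise PipelineError("summarize", f"no splicing_results.tsv in {run}")
    results = pd.read_csv(res_path, sep="\t")
    summary: dict = {"n_tested": int(len(results))}
    if results.empty:
        summary.update(
            {"n_significant": 0, "n_genes": 0, "per_type": {}, "direction": {}}
        )
    else:
        sig = results[results["significant"]]
        summary["n_significant"] = int(len(sig))
        summary["n_genes"] = int(sig["gene_id"].nunique())
        summary["per_type"] = (
            sig["event_type"].value_counts().to_dict() if len(sig) else {}
        )
        summary["direction"] = (
            sig["direction"].value_counts().to_dict() if len(sig) else {}
        )
    truth_path = run / "truth_events.tsv"
    if truth_path.exists():
        truth = pd.read_csv(truth_path, sep="\t")
        changed = truth[truth["psi_control"] != truth["psi_treated"]]
        if len(results):
            sig = results[results["significant"]]
            sig_keys = set(zip(sig["gene_id"], sig["event_type"]))
        else:
            sig_keys = set()
        truth_keys = set(zip(changed["gene_id"], changed["event_type"]))
        recovered = sum(1 for k in truth_keys if k in sig_keys)
        false_hits = sum(1 for k in sig_keys if k not in truth_keys)
        summary["truth"] = {
            "planted_changed": len(truth_keys),
            "recovered": recovered,
            "sensitivity": recovered / len(truth_keys) if truth_keys else float("nan"),
            "false_discoveries": false_hits,
            "fdp": false_hits / len(sig_keys) if sig_keys else 0.0,
        }
    return summary
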