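# splicemap

Junction-based differential alternative-splicing analysis for two-condition
(control vs knockdown) RNA-seq, with a positional motif "RNA map" around
regulated cassette exons — plus a synthetic-data generator that provides
exact ground truth for every stage.

## The problem

RNA-binding proteins such as QKI steer splice-site choice in a
position-dependent way: the same factor activates exon inclusion from one
side of an exon and represses it from the other, e.g. by occupying the
branchpoint (18–35 nt upstream of the 3' splice site) and blocking SF1.
Detecting which exons respond to a factor knockdown, and where the factor's
sequence motif sits relative to those exons, takes a pipeline of well-worn
but fiddly steps. `splicemap` implements that pipeline as a tested,
reusable library:

1. **Junction library** — join every exon of a gene to all exons downstream
   of it (in transcription direction), pooled across isoforms. Each entry
   carries `read_len − min_overhang` nt of exonic sequence per side
   (44 nt for 50-nt reads, 69 nt for 75-nt reads at the default 6-nt
   overhang), so any read aligned to it overhangs the junction point by
   ≥ 6 nt on both sides.
2. **Alignment** — Hamming-distance placement of reads on the genome (both
   orientations) and the junction library with ≤ 3 mismatches; a read is
   kept only when exactly one placement attains the minimum mismatch count
   (ambiguous reads are discarded). A junction is *reported* only when
   covered by ≥ 2 reads at distinct start offsets.
3. **Event calling** — the seven classical event types (SE, IR, A5SS,
   A3SS, MXE, AFE, ALE) enumerated by pairwise transcript comparison, each
   with its inclusion- and exclusion-evidence junction sets.
4. **Statistics** — per event, PSI (percent spliced in) from
   junction-normalised counts,

       PSI = (inc/n_inc) / (inc/n_inc + exc/n_exc),

   a two-sided Fisher exact test on the 2×2 table of inclusion/exclusion
   counts × condition, Benjamini–Hochberg adjustment across all testable
   events (q < 0.05), direction calls (treated = knockdown: ΔPSI < 0 means
   the factor normally *activates* the exon), and an RPKM ≥ 0.5 / > 2-fold
   gene-abundance filter to separate expression from splicing changes.
5. **RNA map** — exact occurrences of the QKI consensus ACUAA(U/C), scanned
   on the pre-mRNA sense strand, averaged per position over splice-site
   anchored regions of activated / repressed / control cassette exons, with
   a resampled null band from the control pool and a permutation test for
   enrichment in the [−40, −1] branchpoint window upstream of the 3'ss.

The synthetic-data module generates a toy genome with one gene per event
(two isoforms differing only by that event), per-condition PSI, sequencing
errors, and consensus motifs planted at chosen offsets — every read origin
and motif position is recorded, so recovery can be scored exactly.

## Worked example

`examples/` holds one narrative script per capability. The differential
call (`python examples/02_differential_splicing.py`) simulates a knockdown
with two real PSI shifts among 18 events and prints:

```
control: 6134 unique / 0 ambiguous / 58 unaligned reads
treated: 6129 unique / 0 ambiguous / 63 unaligned reads

2 events in 2 genes significant (BH q < 0.05) out of 18 tested
     IR gene_IR001   PSI 0.78 -> 0.13 (q=1.8e-14) activated
     SE gene_SE001   PSI 0.25 -> 0.91 (q=2.4e-11) repressed
   A5SS gene_A5SS001 PSI 0.45 -> 0.31 (q=0.67) ns
    AFE gene_AFE001  PSI 0.32 -> 0.53 (q=0.67) ns
```

Exactly the two planted events are called, with the right directions: the
retained intron whose retention collapses on knockdown was *activated* by
the factor, the cassette exon whose inclusion jumps was *repressed*. The
RNA-map example (`03_rna_map.py`) plants ACUAAU at −25 nt from the 3'ss of
every repressed exon and reports:

```
repressed-set peak: 1.00 motifs/exon at -25 nt from the 3'ss (up_intron_3p)
control profile maximum: 0.017 (background only)
[-40,-1] window density ratio 15.0, permutation p = 0.001
```

i.e. the map recovers the planted branchpoint-window signature.

There is also a thin CLI (`splicemap simulate|junctions|align|events|test|
rna-map|run|summarize`); `splicemap run --seed 5 --out runs/demo` executes
the whole pipeline with the reference thresholds and writes a manifest of
hashed outputs, and `splicemap summarize runs/demo` reports significant
events per type plus sensitivity/false-discovery against the ground truth.

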