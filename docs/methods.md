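# Methods

This note documents the models, conventions and numerical choices behind
`splicemap`, and what its synthetic benchmarks do and do not establish.

## Coordinates and junction library

All coordinates are 0-based half-open on the forward genomic strand; GTF
I/O converts to/from 1-based closed at the boundary. "Downstream" is always
meant in transcription direction, so on the `-` strand the donor exon of a
junction is the genomically rightmost one and junction sequences are
reverse-complemented to read 5'→3' on the mRNA.

The library joins every exon of a gene to all downstream exons, pooled over
all of the gene's transcripts and deduplicated by splice-site coordinates
within the gene (identical coordinates in two different genes yield two
entries — junction evidence is gene-scoped). Each side carries
`flank = read_len − min_overhang` nt of exonic sequence (44/69 nt for
50/75-nt reads at the default 6-nt overhang): a full-length read aligned
anywhere on the entry then necessarily spans the junction with ≥ 6 nt on
each side. Exons shorter than the flank truncate it (the entry is flagged)
rather than dropping the junction; when several pooled exons share a splice
site the flank is taken from the longest.

## Aligner

A seed-and-verify Hamming aligner over genome contigs plus junction
entries. The read is split into `max_mismatches + 1` disjoint k-mers; by
pigeonhole at least one seed is exact at any placement within the budget,
so candidate generation is exhaustive and the result equals a full
sliding-window scan (asserted against a brute-force oracle in the tests).
Both read orientations are queried against all targets: libraries are
unstranded, so a junction read may arrive as the reverse complement of the
sense-oriented library sequence. The uniqueness contract is *unique best*:
a read is kept iff exactly one placement attains the minimum mismatch
count; a read with one best and one worse placement is unique, a tie is
ambiguous and dropped (mapper "ambiguity" is otherwise reporting-mode
dependent; minimum-mismatch uniqueness is a clean, testable contract).
Junction placements must physically span the junction point (≥ 1 nt each
side). "Independent" junction reads are reads at distinct start offsets —
a guard against duplicate stacks; a junction is reported only with ≥ 2
independent reads, each with ≥ 6 nt overhang.

Indels, quality-aware scoring and FM-index scalability are out of scope: a
k-mer hash over a desk-scale genome suffices, and the simulator produces
substitution errors only.

## Event model and PSI

Events come from pairwise transcript comparison within a gene: the two
exon chains are partitioned into disagreement blocks between
coordinate-identical shared exons, and each block is classified (SE, IR,
A5SS/A3SS with strand-aware donor/acceptor naming, MXE, AFE/ALE).
Duplicate events across transcript pairs merge once per gene. Conventions
where a choice had to be made:

* **Inclusion labels.** SE: the cassette-carrying isoform. IR: the
  retention (unspliced) isoform. A5SS/A3SS: the longer exon. MXE: the
  genomically upstream alternative exon (direction labels make the choice
  immaterial downstream). AFE/ALE: the variant of the first-listed
  transcript in the annotation.
* **Evidence.** Inclusion/exclusion counts are sums over the event's
  junction sets, using only *reported* junctions. IR has no inclusion
  junction; retention evidence is genome-aligned reads crossing either
  exon–intron boundary with ≥ 6 nt on both sides, mirroring the junction
  overhang rule. Exon-body reads never contribute (junction-only policy;
  isoform-level EM quantification is out of scope).
* **PSI.** `PSI = (inc/n_inc) / (inc/n_inc + exc/n_exc)` with `n_inc`,
  `n_exc` the junction counts of each side — this compensates the 2-vs-1
  junction asymmetry of SE/MXE. Events with zero evidence on both sides
  are undefined and excluded from testing.

## Statistics

Per event, a two-sided Fisher exact test on `[[inc_ctrl, exc_ctrl],
[inc_trt, exc_trt]]` (p sums hypergeometric probabilities ≤ the observed
table's; verified to 1e-7 against exhaustive enumeration), then
Benjamini–Hochberg across all *testable* events of all types jointly
(untestable tables are excluded before adjustment rather than set to
p = 1, so they do not dilute m). Significance is q < α (default 0.05) with
no ΔPSI floor by default (`min_delta_psi` is an optional flag). The design
is one library per condition, no replicates; replicate-aware models
(GLMs, beta-binomial) are deliberately out of scope. The inclusion fold
change is reported as the PSI ratio treated/control. The direction label
reads the treated sample as a regulator knockdown: ΔPSI < 0 ⇒
"activated" (the factor normally promotes inclusion), ΔPSI > 0 ⇒
"repressed".

The abundance filter computes RPKM = 1e9·count/(total·length) per gene
(uniquely mapped genome + junction reads, exon-union gene length) and
passes genes whose larger-sample RPKM is ≥ 0.5 with a strictly > 2-fold
between-condition change.

## RNA map

Motif matching is exact (ACUAA(U/C) scanned as ACTAAT/ACTAAC in DNA space
on the pre-mRNA sense strand; no PWM — the consensus is a literal
hexamer). Half sites UAAU/UAAC are available as a separate track and never
summed into the core curve. The region layout anchors on the four splice
sites of a cassette-exon event:

    [up-exon last U][up-intron first I][up-intron last I]
    [cassette, E length-normalised bins]
    [down-intron first I][down-intron last I][down-exon first U]

with defaults U = 50, I = 250, E = 50 (configurable; the geometry is a
package choice). Intron segments shorter than requested are masked missing
position-wise and excluded from averaging — never zero-filled; introns
shorter than 2I make the two anchored segments overlap and a motif start
there counts in both. Curves are smoothed with a centred 20-nt moving
average within segments (cassette bins unsmoothed); peak-location tests
use the unsmoothed profile.

The control band resamples size-matched sets from the control pool without
replacement and takes outward-rounded empirical quantiles of per-position
means. At the conventional 99.9999% display level the extreme quantile is
unresolvable with desk-scale resampling, so the function warns and reports
the achievable level (resampled extremes) instead — raise `n_resamples`
to sharpen it. Band coverage is validated at 95% with 1,000 resamples.
Upstream-window enrichment uses the mean motif count per event in
[−40, −1] relative to the 3'ss, as a ratio over the control pool, with a
size-matched permutation p using the add-one correction (p is never 0;
p ≤ 1/n_perm when no resample reaches the observed ratio). A 0/0 density
ratio is reported as 1 (no signal either way); a positive test density
over a zero control density is infinite, with p still from permutation.
Control sets default to tested cassette events with q ≥ 0.5 (clearly
unregulated), flag-overridable — expression matching is not attempted.

## Synthetic data

The generator lays out one gene per event on a random uniform-ACGT contig
(500-nt spacers, alternating strands to exercise strand handling), each
gene exactly two isoforms differing only by its event. Defaults: 50-nt
reads; exon 150 nt and alternative exon 120 nt (≥ 2·(read_len − 6), so
flanks never truncate); introns 300 nt (floor 80 nt, keeping the [−40, 0]
window clear of the opposite splice site); donor/acceptor shifts 60 nt;
error rate 0.005 substitutions/base (typical short-read scale); depth
1,000 reads per transcript-kilobase per condition; constant quality "I"
(Phred 40). Motifs are planted in DNA space on the sense strand
(ACUAAU ↔ ACTAAT, reverse-complemented for `-` genes) at fixed offsets
around cassette exons of a labelled set; planting overwrites background,
and chance background occurrences are left in place (they are part of the
null).

**Read model.** PSI is the *molar* inclusion fraction: a fraction PSI of
the gene's transcript molecules carry the inclusion isoform. Reads are
sampled uniformly from the pooled transcript mass, as fragmentation of an
RNA pool does — a read comes from an isoform with probability
PSI·len/(PSI·len_inc + (1−PSI)·len_exc), with a uniform start within that
isoform. This matters: junction-spanning counts are then proportional to
molar abundance (up to the small edge factor len/(len − read_len + 1)),
which is exactly what junction-count PSI estimation assumes. Choosing the
isoform per read with unweighted probability PSI instead would make counts
proportional to molar fraction divided by isoform length and bias the
estimator by the isoform length ratio (≈ 0.1 at PSI 0.5 for the default
geometry). Reads are unstranded (random orientation); no positional bias,
no indels, no PCR duplicates, no paired ends, no expression confounding
beyond depth.

What passing on this generator shows: the pipeline's logic — junction
geometry, unique-best alignment, event classification, counting rules,
test calibration, map geometry — is correct under a clean substitution-
error model. What it does not show: robustness to coverage bias, indels,
mis-annotation, overlapping genes, or repetitive genomes; real libraries
violate all of these to some degree.

## Validation problem sizes

The test suite runs at desk scale, chosen so the whole suite finishes in
well under a minute of CPU: Fisher vs brute-force enumeration on 1,000
random tables (margins ≤ 60, rel. tol 1e-7); BH vs the textbook step-up
on 1,000 random vectors (length ≤ 500); aligner vs exhaustive Hamming
scan for 2,000 simulated reads on a ~14-kb genome plus 100% true-junction
recovery for error-free reads with two-sided ≥ 6-nt overhang; exact
recovery of a planted 7-type event census; detection power/FDR over 50
seeded replicates of 120 events (100 null, 20 at ΔPSI = 0.4, ~200
junction reads each — mean sensitivity ≥ 0.9, empirical FDR within
0.05 + 2·MC-SE); mean |PSI error| < 0.03 at ≥ 200 junction reads/event
through the full read path; and RNA-map recovery of ACUAAU planted at
−25 nt (profile maximum in [−25, −20], permutation p ≤ 0.001 at 1,000
permutations, 95% band coverage at 1,000 resamples).

## Known limitations

* Complex or nested event graphs (multi-exon differences that are not one
  of the seven patterns) are skipped, not mis-classified.
* The aligner is exact-Hamming; a single indel shifts every downstream
  base and the read is lost as unalignable. Reads spanning a junction
  with < 6 nt overhang occasionally land on the genome near exon ends
  with ≤ 3 "mismatches" — real mappers share this edge behaviour, and the
  overhang/independence rules exist precisely to keep such reads out of
  the evidence.
* GFF3, CDS/UTR modelling, alternative contigs and genome-scale indexing
  are out of scope.
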