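"""Simulate a two-condition splicing experiment and build its junction library.

Generates a toy genome with one gene per alternative-splicing event (the
seven types: SE, IR, A5SS, A3SS, MXE, AFE, ALE), then joins every exon to
all downstream exons of its gene with 44-nt exonic flanks (50-nt reads,
6-nt minimum overhang).
"""

import collections

from splicemap import SimulationConfig, build_junction_library, simulate_annotation
from splicemap.annotation import junction_flank_length

cfg = SimulationConfig(seed=1)
genome, genes, truth = simulate_annotation(cfg)

print(f"genome: {genome.length('chrS'):,} nt on 1 contig")
print(f"genes: {len(genes)} ({len(truth.events)} carry an AS event)")
per_type = collections.Counter(ev.event_type for ev in truth.events)
print("planted events:", dict(per_type))

flank = junction_flank_length(cfg.read_len, 6)
library = build_junction_library(genes, genome, cfg.read_len)
print(f"junction flank for {cfg.read_len}-nt reads: {flank} nt per side")
print(f"junction library: {len(library)} entries "
      f"(every exon joined to each downstream exon, per gene)")
example = library[0]
print(f"example entry {example.junction_id}: "
      f"{len(example.sequence)} nt = {example.donor_flank}+{example.acceptor_flank}")
# A read aligning anywhere on such an entry overhangs the junction point by
# at least 6 nt on each side, which is what makes it junction evidence.
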