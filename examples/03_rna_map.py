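"""Positional ACUAA(U/C) RNA map around regulated cassette exons.

Plants the QKI consensus ACUAAU 25 nt upstream of the 3' splice site of
every "repressed" cassette exon — where branchpoints live (18-35 nt
upstream) — and shows that the map's maximum lands there, that the planted
peak escapes the control resampling band, and that the [-40, -1] upstream
window is significantly enriched by permutation.
"""

import numpy as np

from splicemap import (
    MotifPlantRule,
    SimulationConfig,
    build_motif_map,
    control_confidence_band,
    enumerate_events,
    simulate_annotation,
    upstream_window_enrichment,
)

psi = {f"SE{i:03d}": ((0.4, 0.8) if i <= 25 else (0.5, 0.5)) for i in range(1, 86)}
cfg = SimulationConfig(
    seed=3,
    events_per_type={"SE": 85},
    psi=psi,
    n_background_genes=0,
    motif_plan=[MotifPlantRule("repressed", "upstream_intron", -25, "ACUAAU")],
)
genome, genes, truth = simulate_annotation(cfg)
label_of = {ev.gene_id: ev.label for ev in truth.events}
sets = {"repressed": [], "control": []}
for event in enumerate_events(genes):
    sets[label_of[event.gene_id]].append(event)
print({k: len(v) for k, v in sets.items()}, "cassette exons")

profiles = build_motif_map(sets, genome, smooth_window=0)
rep = profiles["repressed"].to_frame()
peak = rep.loc[rep["raw_mean"].idxmax()]
print(f"repressed-set peak: {peak['raw_mean']:.2f} motifs/exon at "
      f"{int(peak['offset'])} nt from the 3'ss ({peak['segment']})")
print(f"control profile maximum: {profiles['control'].raw_mean.max():.3f} "
      "(background only)")

band = control_confidence_band(
    sets["control"], len(sets["repressed"]), genome,
    n_resamples=1000, level=0.95, seed=3, smooth_window=0,
)
idx = int(np.nanargmax(profiles["repressed"].raw_mean))
print(f"band at the peak position: [{band.low[idx]:.3f}, {band.high[idx]:.3f}] "
      f"vs observed {profiles['repressed'].raw_mean[idx]:.2f} -> outside the null")

enr = upstream_window_enrichment(
    sets["repressed"], sets["control"], genome, n_perm=1000, seed=3
)
print(f"[-40,-1] window density ratio {enr.density_ratio:.1f}, "
      f"permutation p = {enr.p_value:.2g}")
# A ratio >> 1 with tiny p says the consensus concentrates exactly where the
# branchpoint is read by SF1 — the positional signature of splicing repression.
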