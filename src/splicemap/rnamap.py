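"""Positional motif maps around cassette exons (the "RNA map").

The map counts exact occurrences of the QKI binding consensus ACUAA(U/C)
(scanned as ACTAAT/ACTAAC in DNA space, sense strand of the pre-mRNA) at
each position of a fixed region layout anchored on the four splice sites of
a cassette-exon event:

    [up-exon last U nt][up-intron first I nt][up-intron last I nt]
    [cassette exon, length-normalised to E bins]
    [down-intron first I nt][down-intron last I nt][down-exon first U nt]

Intron segments shorter than requested are masked missing position-wise
(never padded with zeros); when an intron is shorter than 2I the two
anchored segments overlap and a motif there is counted in both. Profiles
for a QKI-activated, QKI-repressed and unregulated control exon set are
averaged per position; a resampling band around the control profile gives
the null expectation, and a permutation test quantifies motif enrichment in
the presumed branchpoint window 40 nt upstream of the 3' splice site of
repressed exons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import GenomeSequence
from .events import ASEvent

__all__ = [
    "MotifSpec",
    "EventRegions",
    "MotifProfile",
    "ConfidenceBand",
    "EnrichmentResult",
    "scan_motif",
    "extract_region_sequences",
    "event_regions",
    "profile_matrix",
    "build_motif_map",
    "control_confidence_band",
    "upstream_window_enrichment",
]

SEGMENTS = (
    "up_exon",
    "up_intron_5p",
    "up_intron_3p",
    "cassette",
    "down_intron_5p",
    "down_intron_3p",
    "down_exon",
)


def _dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


@dataclass(frozen=True)
class MotifSpec:
    """Exact motifs scanned on the pre-mRNA sense strand.

    Defaults to the QKI core consensus ACUAAY (Y = C or U); the UAAY half
    sites can be scanned as a separate spec, never summed into the core
    curve.
    """

    motifs: tuple[str, ...] = ("ACTAAT", "ACTAAC")

    def __post_init__(self) -> None:
        if not self.motifs:
            raise ValueError("empty motif set")
        object.__setattr__(
            self, "motifs", tuple(_dna(m) for m in self.motifs)
        )

    @classmethod
    def half_sites(cls) -> "MotifSpec":
        return cls(("TAAT", "TAAC"))


def scan_motif(sequence: str, spec: MotifSpec = MotifSpec()) -> list[int]:
    """0-based start positions of all (overlapping) exact motif matches."""
    seq = _dna(sequence)
    hits: set[int] = set()
    for motif in spec.motifs:
        start = seq.find(motif)
        while start != -1:
            hits.add(start)
            start = seq.find(motif, start + 1)
    return sorted(hits)


@dataclass(frozen=True)
class EventRegions:
    """Sense pre-mRNA of one cassette-exon event with segment bookkeeping.

    ``sequence`` runs 5'->3' from the start of the upstream flanking exon to
    the end of the downstream flanking exon (transcription order).
    """

    event_id: str
    sequence: str
    up_exon_len: int
    up_intron_len: int
    cassette_len: int
    down_intron_len: int
    down_exon_len: int

    @property
    def cassette_start(self) -> int:
        return self.up_exon_len + self.up_intron_len

    @property
    def cassette_end(self) -> int:
        return self.cassette_start + self.cassette_len

    @property
    def down_exon_start(self) -> int:
        return self.cassette_end + self.down_intron_len


def event_regions(event: ASEvent, genome: GenomeSequence) -> EventRegions:
    """Extract the sense pre-mRNA span of an SE event.

    Requires the event's defining intervals to include the cassette and both
    flanking exons (terminal cassette exons cannot be mapped and raise).
    """
    iv = event.interval_map
    if event.event_type != "SE" or not {"cassette", "left_exon", "right_exon"} <= set(iv):
        raise ValueError(
            f"event {event.event_id}: not a flanked cassette-exon event"
        )
    left, cass, right = iv["left_exon"], iv["cassette"], iv["right_exon"]
    span = genome.fetch_sense(event.contig, left[0], right[1], event.strand)
    if event.strand == "+":
        up_exon, down_exon = left, right
        up_intron = (left[1], cass[0])
        down_intron = (cass[1], right[0])
    else:
        up_exon, down_exon = right, left
        up_intron = (cass[1], right[0])
        down_intron = (left[1], cass[0])
    return EventRegions(
        event_id=event.event_id,
        sequence=span,
        up_exon_len=up_exon[1] - up_exon[0],
        up_intron_len=up_intron[1] - up_intron[0],
        cassette_len=cass[1] - cass[0],
        down_intron_len=down_intron[1] - down_intron[0],
        down_exon_len=down_exon[1] - down_exon[0],
    )


def extract_region_sequences(
    event: ASEvent, genome: GenomeSequence, U: int = 50, I: int = 250
) -> dict[str, str]:
    """Anchored segment sequences of one event, sense strand.

    Segments shorter than requested are returned short (their missing
    positions are excluded from profile averaging, not zero-filled).
    """
    r = event_regions(event, genome)
    s = r.sequence
    cs, ce, ds = r.cassette_start, r.cassette_end, r.down_exon_start
    return {
        "up_exon": s[max(0, r.up_exon_len - U) : r.up_exon_len],
        "up_intron_5p": s[r.up_exon_len : r.up_exon_len + min(I, r.up_intron_len)],
        "up_intron_3p": s[cs - min(I, r.up_intron_len) : cs],
        "cassette": s[cs:ce],
        "down_intron_5p": s[ce : ce + min(I, r.down_intron_len)],
        "down_intron_3p": s[ds - min(I, r.down_intron_len) : ds],
        "down_exon": s[ds : ds + min(U, r.down_exon_len)],
    }


def _segment_slices(U: int, I: int, E: int) -> dict[str, slice]:
    sizes = {
        "up_exon": U,
        "up_intron_5p": I,
        "up_intron_3p": I,
        "cassette": E,
        "down_intron_5p": I,
        "down_intron_3p": I,
        "down_exon": U,
    }
    out, start = {}, 0
    for name in SEGMENTS:
        out[name] = slice(start, start + sizes[name])
        start += sizes[name]
    return out


def _segment_offsets(U: int, I: int, E: int) -> tuple[list[str], list[int]]:
    """(segment name, anchored offset) per profile position.

    Offsets are splice-site anchored: exonic positions count up to their
    splice site (up_exon: -U..-1 before the 5'ss; down_exon: 0..U-1 after
    the 3'ss); intron 5p segments count 0..I-1 from their donor; intron 3p
    segments count -I..-1 to their acceptor; cassette positions are bin
    indices 0..E-1.
    """
    segs, offs = [], []
    for name in SEGMENTS:
        if name in ("up_exon",):
            rng = range(-U, 0)
        elif name == "down_exon":
            rng = range(0, U)
        elif name.endswith("_5p"):
            rng = range(0, I)
        elif name.endswith("_3p"):
            rng = range(-I, 0)
        else:
            rng = range(0, E)
        segs += [name] * len(rng)
        offs += list(rng)
    return segs, offs


def profile_matrix(
    events: Sequence[ASEvent],
    genome: GenomeSequence,
    spec: MotifSpec = MotifSpec(),
    U: int = 50,
    I: int = 250,
    E: int = 50,
) -> np.ndarray:
    """Per-event motif-count vectors over the region layout.

    Shape (n_events, 2U + 4I + E); masked-missing positions are NaN. A motif
    start falling where two anchored intron segments overlap is counted in
    both.
    """
    if not events:
        raise ValueError("empty event set")
    P = 2 * U + 4 * I + E
    sl = _segment_slices(U, I, E)
    mat = np.zeros((len(events), P))
    for n, event in enumerate(events):
        r = event_regions(event, genome)
        row = mat[n]
        # mask positions without sequence coverage
        if r.up_exon_len < U:
            row[sl["up_exon"]][: U - r.up_exon_len] = np.nan
        if r.up_intron_len < I:
            row[sl["up_intron_5p"]][r.up_intron_len :] = np.nan
            row[sl["up_intron_3p"]][: I - r.up_intron_len] = np.nan
        if r.down_intron_len < I:
            row[sl["down_intron_5p"]][r.down_intron_len :] = np.nan
            row[sl["down_intron_3p"]][: I - r.down_intron_len] = np.nan
        if r.down_exon_len < U:
            row[sl["down_exon"]][r.down_exon_len :] = np.nan

        cs, ce, ds = r.cassette_start, r.cassette_end, r.down_exon_start
        ue, ui = r.up_exon_len, r.up_intron_len
        for h in scan_motif(r.sequence, spec):
            if h < ue:
                back = ue - h  # 1..ue before the 5'ss
                if back <= U:
                    row[sl["up_exon"].start + U - back] += 1
                continue
            if h < cs:
                off = h - ue
                if off < I:
                    row[sl["up_intron_5p"].start + off] += 1
                dist = cs - h  # 1..ui to the 3'ss
                if dist <= I:
                    row[sl["up_intron_3p"].start + I - dist] += 1
                continue
            if h < ce:
                rel = (h - cs) / r.cassette_len
                row[sl["cassette"].start + min(E - 1, int(rel * E))] += 1
                continue
            if h < ds:
                off = h - ce
                if off < I:
                    row[sl["down_intron_5p"].start + off] += 1
                dist = ds - h
                if dist <= I:
                    row[sl["down_intron_3p"].start + I - dist] += 1
                continue
            off = h - ds
            if off < U:
                row[sl["down_exon"].start + off] += 1
    return mat


def _smooth_segments(
    values: np.ndarray, U: int, I: int, E: int, window: int
) -> np.ndarray:
    """Centred NaN-aware moving average within each non-cassette segment."""
    if window <= 1:
        return values
    from scipy.ndimage import uniform_filter1d

    out = values.astype(float).copy()
    sl = _segment_slices(U, I, E)
    for name in SEGMENTS:
        if name == "cassette":
            continue
        seg = values[..., sl[name]]
        w = min(window, seg.shape[-1])
        vals = np.nan_to_num(seg)
        cov = (~np.isnan(seg)).astype(float)
        num = uniform_filter1d(vals, size=w, axis=-1, mode="constant", cval=0.0)
        den = uniform_filter1d(cov, size=w, axis=-1, mode="constant", cval=0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            sm = num / den
        sm[den == 0] = np.nan
        out[..., sl[name]] = sm
    return out


@dataclass
class MotifProfile:
    """Positional mean motif count for one event set."""

    label: str
    n_events: int
    U: int
    I: int
    E: int
    mean: np.ndarray  # smoothed (if a window was given)
    raw_mean: np.ndarray
    coverage: np.ndarray  # events contributing per position
    smooth_window: int = 0
    band_low: Optional[np.ndarray] = None
    band_high: Optional[np.ndarray] = None

    def to_frame(self) -> pd.DataFrame:
        segs, offs = _segment_offsets(self.U, self.I, self.E)
        df = pd.DataFrame(
            {
                "set": self.label,
                "segment": segs,
                "offset": offs,
                "mean": self.mean,
                "raw_mean": self.raw_mean,
                "coverage": self.coverage.astype(int),
            }
        )
        if self.band_low is not None:
            df["band_low"] = self.band_low
            df["band_high"] = self.band_high
        return df

    def segment_values(self, segment: str, raw: bool = True) -> np.ndarray:
        sl = _segment_slices(self.U, self.I, self.E)[segment]
        return (self.raw_mean if raw else self.mean)[sl]


def build_motif_map(
    event_sets: Mapping[str, Sequence[ASEvent]],
    genome: GenomeSequence,
    spec: MotifSpec = MotifSpec(),
    U: int = 50,
    I: int = 250,
    E: int = 50,
    smooth_window: int = 20,
) -> dict[str, MotifProfile]:
    """Positional motif profile per labelled event set (e.g. activated /
    repressed / control cassette exons)."""
    profiles = {}
    for label, events in event_sets.items():
        mat = profile_matrix(events, genome, spec, U, I, E)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            raw = np.nanmean(mat, axis=0)
        coverage = (~np.isnan(mat)).sum(axis=0)
        mean = (
            _smooth_segments(raw, U, I, E, smooth_window)
            if smooth_window and smooth_window > 1
            else raw
        )
        profiles[label] = MotifProfile(
            label=label,
            n_events=len(events),
            U=U,
            I=I,
            E=E,
            mean=mean,
            raw_mean=raw,
            coverage=coverage,
            smooth_window=smooth_window or 0,
        )
    return profiles


@dataclass
class ConfidenceBand:
    low: np.ndarray
    high: np.ndarray
    level_requested: float
    level_achieved: float
    n_resamples: int


def _resampled_means(
    mat: np.ndarray,
    set_size: int,
    n_resamples: int,
    rng: np.random.Generator,
    chunk: int = 256,
) -> np.ndarray:
    n = mat.shape[0]
    vals = np.nan_to_num(mat)
    cov = (~np.isnan(mat)).astype(float)
    out = np.empty((n_resamples, mat.shape[1]))
    done = 0
    while done < n_resamples:
        m = min(chunk, n_resamples - done)
        idx = np.stack(
            [rng.choice(n, size=set_size, replace=False) for _ in range(m)]
        )
        num = vals[idx].sum(axis=1)
        den = cov[idx].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[done : done + m] = np.where(den > 0, num / den, np.nan)
        done += m
    return out


def control_confidence_band(
    control_events: Sequence[ASEvent],
    set_size: int,
    genome: GenomeSequence,
    spec: MotifSpec = MotifSpec(),
    n_resamples: int = 10_000,
    level: float = 0.999999,
    seed: Optional[int] = None,
    U: int = 50,
    I: int = 250,
    E: int = 50,
    smooth_window: int = 20,
) -> ConfidenceBand:
    """Null band for a size-matched set drawn from the control pool.

    ``set_size`` events are resampled without replacement ``n_resamples``
    times; the band is the empirical (1-level)/2 and 1-(1-level)/2 quantile
    of the per-position set means (outward-rounded order statistics). When
    the requested level is beyond what ``n_resamples`` can resolve (as with
    the default 99.9999% at desk-scale resampling), the band falls back to
    the resampled extremes and a warning reports the achievable level.
    """
    if not 0 <= level < 1:
        raise ValueError("level must be in [0, 1)")
    if set_size > len(control_events):
        raise ValueError(
            f"control pool ({len(control_events)}) smaller than set_size ({set_size})"
        )
    rng = np.random.default_rng(seed)
    mat = profile_matrix(control_events, genome, spec, U, I, E)
    means = _resampled_means(mat, set_size, n_resamples, rng)
    if smooth_window and smooth_window > 1:
        means = _smooth_segments(means, U, I, E, smooth_window)
    alpha = (1.0 - level) / 2.0
    achievable = 1.0 - 2.0 / (n_resamples + 1)
    if level > achievable:
        warnings.warn(
            f"requested {level:.7%} band is not resolvable with "
            f"{n_resamples} resamples; reporting the achievable "
            f"{achievable:.5%} band (resampled extremes)",
            stacklevel=2,
        )
        low = np.nanmin(means, axis=0)
        high = np.nanmax(means, axis=0)
        achieved = achievable
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            low = np.nanquantile(means, alpha, axis=0, method="lower")
            high = np.nanquantile(means, 1 - alpha, axis=0, method="higher")
        achieved = level
    return ConfidenceBand(
        low=low,
        high=high,
        level_requested=level,
        level_achieved=achieved,
        n_resamples=n_resamples,
    )


@dataclass
class EnrichmentResult:
    density_ratio: float
    p_value: float
    n_test: int
    n_control: int
    window: tuple[int, int]
    n_perm: int
    mean_test: float
    mean_control: float
    truncated_events: int  # introns shorter than the window


def _window_counts(
    events: Sequence[ASEvent],
    genome: GenomeSequence,
    spec: MotifSpec,
    window: tuple[int, int],
) -> tuple[np.ndarray, int]:
    """Motif starts in [window] nt relative to each cassette 3' splice site."""
    lo, hi = window
    if not (lo <= hi < 0):
        raise ValueError("window must be negative offsets relative to the 3'ss")
    counts = np.zeros(len(events))
    truncated = 0
    for n, event in enumerate(events):
        r = event_regions(event, genome)
        if r.up_intron_len < -lo:
            truncated += 1
        cs = r.cassette_start
        for h in scan_motif(r.sequence, spec):
            off = h - cs
            if lo <= off <= hi:
                counts[n] += 1
    return counts, truncated


def upstream_window_enrichment(
    test_events: Sequence[ASEvent],
    control_events: Sequence[ASEvent],
    genome: GenomeSequence,
    spec: MotifSpec = MotifSpec(),
    window: tuple[int, int] = (-40, -1),
    n_perm: int = 10_000,
    seed: Optional[int] = None,
) -> EnrichmentResult:
    """Motif enrichment in the branchpoint window upstream of the 3'ss.

    Statistic: mean motif count per event in the window for the test set
    over the control-pool mean. Significance: fraction of size-matched
    control resamples with a ratio at least as large, with the +1
    add-one correction so p is never exactly zero (p <= 1/n_perm when no
    resample reaches the observed ratio).
    """
    if not test_events or not control_events:
        raise ValueError("empty event set")
    rng = np.random.default_rng(seed)
    test_counts, trunc_t = _window_counts(test_events, genome, spec, window)
    ctrl_counts, trunc_c = _window_counts(control_events, genome, spec, window)
    mean_test = float(test_counts.mean())
    mean_ctrl = float(ctrl_counts.mean())

    def _ratio(num: float) -> float:
        if mean_ctrl > 0:
            return num / mean_ctrl
        return float("inf") if num > 0 else 1.0  # 0/0: no signal either way

    ratio = _ratio(mean_test)
    size = min(len(test_events), len(control_events))
    exceed = 0
    for _ in range(n_perm):
        sub = ctrl_counts[rng.choice(ctrl_counts.size, size=size, replace=False)]
        if _ratio(float(sub.mean())) >= ratio:
            exceed += 1
    p = (1 + exceed) / (n_perm + 1)
    return EnrichmentResult(
        density_ratio=ratio,
        p_value=p,
        n_test=len(test_events),
        n_control=len(control_events),
        window=window,
        n_perm=n_perm,
        mean_test=mean_test,
        mean_control=mean_ctrl,
        truncated_events=trunc_t + trunc_c,
    )
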