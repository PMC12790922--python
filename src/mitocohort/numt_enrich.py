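"""Distributional statistics of NUMT breakpoints.

Mitochondrial side: an ECDF of breakpoint positions along the
16,569 bp circle (evaluated linearly) and per-region breakpoint
densities normalised by region length. Nuclear side: a permutation
test of whether NUMT insertion windows (+-100 bp around the nuclear
anchor) overlap an annotation track more often than the same number of
uniformly placed windows; p-values use the (count >= observed) + 1 over
n_perm + 1 convention so a fixed seed fixes p exactly and p can never
be zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from mitocohort.circular import MT_GENOME_LENGTH
from mitocohort.io_formats import BedInterval
from mitocohort.numt_detect import NumtEvent
from mitocohort.rcrs import Region


@dataclass(frozen=True)
class EnrichmentResult:
    track_name: str
    numt_class: str
    observed: int
    n_perm: int
    null_geq: int
    p_value: float


class MitoBreakpointEcdf:
    """Right-continuous empirical CDF of mtDNA breakpoint positions."""

    def __init__(self, breakpoints: Sequence[int], genome_len: int = MT_GENOME_LENGTH):
        bps = np.asarray(sorted(breakpoints), dtype=float)
        if bps.size == 0:
            raise ValueError("ECDF needs at least one breakpoint")
        if bps[0] < 1 or bps[-1] > genome_len:
            raise ValueError("breakpoints outside 1..genome_len")
        self._sorted = bps
        self.genome_len = genome_len

    def __call__(self, pos):
        pos = np.asarray(pos, dtype=float)
        vals = np.searchsorted(self._sorted, pos, side="right") / self._sorted.size
        return float(vals) if vals.ndim == 0 else vals


def mito_breakpoint_ecdf(
    breakpoints: Sequence[int], genome_len: int = MT_GENOME_LENGTH
) -> MitoBreakpointEcdf:
    return MitoBreakpointEcdf(breakpoints, genome_len=genome_len)


def normalized_region_counts(
    breakpoints: Sequence[int],
    region_table: Sequence[Region],
    min_region_len: int = 200,
) -> list[dict]:
    """Breakpoints-per-bp for each region of the mtDNA tiling.

    Short regions (< ``min_region_len``) are reported but flagged
    excluded: their normalised counts are dominated by sampling noise.
    """
    bps = np.asarray(sorted(breakpoints), dtype=int)
    out = []
    for region in region_table:
        n = int(
            np.searchsorted(bps, region.end, side="right")
            - np.searchsorted(bps, region.start, side="left")
        )
        out.append(
            {
                "region": region.name,
                "region_class": region.region_class,
                "length": region.length,
                "count": n,
                "per_bp": n / region.length,
                "excluded_short": region.length < min_region_len,
            }
        )
    return out


def _concat_track(
    track: Sequence[BedInterval], offsets: dict[str, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Merge a track into disjoint sorted intervals on the concatenated
    genome coordinate (half-open)."""
    ivs = sorted(
        (offsets[iv.chrom] + iv.start, offsets[iv.chrom] + iv.end)
        for iv in track
        if iv.chrom in offsets
    )
    if not ivs:
        return np.empty(0), np.empty(0)
    starts, ends = [ivs[0][0]], [ivs[0][1]]
    for s, e in ivs[1:]:
        if s <= ends[-1]:
            ends[-1] = max(ends[-1], e)
        else:
            starts.append(s)
            ends.append(e)
    return np.asarray(starts, dtype=float), np.asarray(ends, dtype=float)


def _window_overlaps(
    win_start: np.ndarray, win_end: np.ndarray, t_starts: np.ndarray, t_ends: np.ndarray
) -> np.ndarray:
    """Half-open window vs merged disjoint track overlap, vectorised."""
    if t_starts.size == 0:
        return np.zeros(win_start.shape, dtype=bool)
    idx = np.searchsorted(t_starts, win_end, side="left")
    has_prev = idx > 0
    prev_end = np.where(has_prev, t_ends[np.maximum(idx - 1, 0)], -np.inf)
    return has_prev & (prev_end > win_start)


def nuclear_enrichment_permutation(
    events: Sequence[NumtEvent] | Sequence[int],
    track: Sequence[BedInterval],
    chrom_sizes: dict[str, int],
    n_perm: int = 10_000,
    flank: int = 100,
    rng_seed: int | None = None,
    track_name: str = "track",
    numt_class: str = "all",
    event_chroms: Sequence[str] | None = None,
    per_chromosome: bool = False,
) -> EnrichmentResult:
    """Upper-tail permutation enrichment of NUMT windows against a track.

    The observed statistic is the number of events whose +-``flank`` bp
    window around the nuclear anchor overlaps the track. Each of the
    ``n_perm`` permutations draws the same number of positions uniformly
    over the genome defined by ``chrom_sizes`` (or within each event's
    own chromosome when ``per_chromosome``), truncating windows at
    chromosome ends, and counts overlaps the same way.

    ``events`` may be NumtEvent objects or raw 1-based anchor positions
    (then ``event_chroms`` names each one's chromosome).
    """
    if not track:
        raise ValueError("empty annotation track")
    if not events:
        raise ValueError("no events to test")
    chroms = sorted(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    offsets = {}
    acc = 0
    for c in chroms:
        offsets[c] = acc
        acc += chrom_sizes[c]
    genome_len = acc

    if isinstance(events[0], NumtEvent):
        anchors = np.array([ev.anchor for ev in events])
        ev_chroms = [ev.nuclear_chrom for ev in events]
    else:
        anchors = np.asarray(events, dtype=float)
        if event_chroms is None:
            raise ValueError("event_chroms required when events are raw positions")
        ev_chroms = list(event_chroms)
    for c in ev_chroms:
        if c not in offsets:
            raise ValueError(f"event chromosome {c!r} absent from chrom_sizes")

    t_starts, t_ends = _concat_track(track, offsets)
    chrom_lo = np.array([offsets[c] for c in ev_chroms], dtype=float)
    chrom_hi = chrom_lo + np.array([chrom_sizes[c] for c in ev_chroms], dtype=float)
    # anchors are 1-based; concatenated coordinate is 0-based half-open
    g_anchor = chrom_lo + anchors - 1
    obs_start = np.maximum(g_anchor - flank, chrom_lo)
    obs_end = np.minimum(g_anchor + flank + 1, chrom_hi)
    observed = int(_window_overlaps(obs_start, obs_end, t_starts, t_ends).sum())

    rng = np.random.default_rng(rng_seed)
    n_ev = len(ev_chroms)
    null_geq = 0
    # chunk permutations to bound memory at ~1e7 floats
    chunk = max(1, int(1e7 // max(n_ev, 1)))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        if per_chromosome:
            u = rng.random((m, n_ev))
            g = chrom_lo + np.floor(u * (chrom_hi - chrom_lo))
            lo, hi = np.broadcast_to(chrom_lo, g.shape), np.broadcast_to(chrom_hi, g.shape)
        else:
            g = np.floor(rng.random((m, n_ev)) * genome_len)
            ci = np.searchsorted(np.cumsum(sizes), g, side="right")
            lo = np.cumsum(sizes)[ci] - sizes[ci]
            hi = lo + sizes[ci]
        ws = np.maximum(g - flank, lo)
        we = np.minimum(g + flank + 1, hi)
        counts = _window_overlaps(ws, we, t_starts, t_ends).sum(axis=1)
        null_geq += int((counts >= observed).sum())
        done += m

    return EnrichmentResult(
        track_name=track_name,
        numt_class=numt_class,
        observed=observed,
        n_perm=n_perm,
        null_geq=null_geq,
        p_value=(null_geq + 1) / (n_perm + 1),
    )
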