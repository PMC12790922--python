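"""Invariable nucleotides and maximal invariable intervals of mtDNA.

A position is *variable* when any SNV falls on it or any deletion
removes it (left-anchored VCF convention: for REF=ACT ALT=A at pos p,
the deleted bases are p+1 and p+2; the anchor base itself is
unchanged). Insertions do not change existing bases, so they leave the
position set alone but break interval continuity at their anchor gap.
Invariable intervals are the maximal runs of non-variable positions,
additionally split at every insertion gap; the 16,569 -> 1 adjacency
is not joined (intervals are reported linearly).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import hypergeom, mannwhitneyu

from mitocohort.circular import MT_GENOME_LENGTH
from mitocohort.mt_variants import MtVariantSummary
from mitocohort.rcrs import Region


@dataclass(frozen=True)
class InvariableInterval:
    start: int  # 1-based inclusive
    end: int

    def __post_init__(self):
        if not 1 <= self.start <= self.end:
            raise ValueError(f"bad interval [{self.start}, {self.end}]")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def variable_positions(summaries: Iterable[MtVariantSummary]) -> set[int]:
    """Positions whose reference base is changed by any SNV or deletion."""
    out: set[int] = set()
    for s in summaries:
        if s.vtype == "SNV":
            out.add(s.pos)
        elif s.vtype == "deletion":
            # left-anchored: anchor base kept, following bases deleted
            ndel = len(s.ref) - len(s.alt)
            out.update(range(s.pos + 1, s.pos + 1 + ndel))
    return out


def insertion_anchors(summaries: Iterable[MtVariantSummary]) -> set[int]:
    """Inter-base gaps broken by insertions: an insertion anchored at
    position k inserts between k and k+1, returning gap index k."""
    return {s.pos for s in summaries if s.vtype == "insertion"}


def invariable_intervals(
    variable_set: Iterable[int],
    gap_set: Iterable[int] = (),
    genome_len: int = MT_GENOME_LENGTH,
) -> list[InvariableInterval]:
    """Maximal runs of invariable positions, split at insertion gaps.

    Length-1 runs are included (callers derive the "> 1 nt" and
    "> 10 nt" summaries from the length field).
    """
    variable = set(variable_set)
    gaps = set(gap_set)
    out: list[InvariableInterval] = []
    start = None
    for pos in range(1, genome_len + 1):
        if pos in variable:
            if start is not None:
                out.append(InvariableInterval(start, pos - 1))
                start = None
            continue
        if start is None:
            start = pos
        if pos in gaps or pos == genome_len:
            out.append(InvariableInterval(start, pos))
            start = None
    return out


def interval_region_stats(
    intervals: Sequence[InvariableInterval],
    region_table: Sequence[Region],
    genome_len: int = MT_GENOME_LENGTH,
) -> dict:
    """Per-region invariable-base proportions with enrichment tests.

    For each region class: proportion = invariable bases in class /
    class length; one-tailed upper hypergeometric p for over-
    representation of invariable bases (drawing the total number of
    invariable bases from the genome); one-tailed Mann-Whitney rank-sum
    p comparing that class's interval-length distribution against all
    other classes (alternative: longer intervals in the class).
    """
    inv_mask = np.zeros(genome_len + 1, dtype=bool)
    for iv in intervals:
        inv_mask[iv.start : iv.end + 1] = True
    n_inv_total = int(inv_mask[1:].sum())

    class_len: dict[str, int] = {}
    class_inv: dict[str, int] = {}
    for region in region_table:
        cl = region.region_class
        class_len[cl] = class_len.get(cl, 0) + region.length
        class_inv[cl] = class_inv.get(cl, 0) + int(
            inv_mask[region.start : region.end + 1].sum()
        )

    # interval lengths assigned to the class of the interval midpoint
    def class_of(pos: int) -> str:
        for region in region_table:
            if region.start <= pos <= region.end:
                return region.region_class
        raise ValueError(f"position {pos} uncovered")

    lengths_by_class: dict[str, list[int]] = {cl: [] for cl in class_len}
    for iv in intervals:
        lengths_by_class[class_of((iv.start + iv.end) // 2)].append(iv.length)

    rows = {}
    for cl, length in class_len.items():
        inv = class_inv[cl]
        hg_p = float(hypergeom.sf(inv - 1, genome_len, length, n_inv_total))
        own = lengths_by_class[cl]
        other = [x for c, ls in lengths_by_class.items() if c != cl for x in ls]
        if own and other:
            rs_p = float(mannwhitneyu(own, other, alternative="greater").pvalue)
        else:
            rs_p = float("nan")
        rows[cl] = {
            "region_class": cl,
            "length": length,
            "invariable_bases": inv,
            "proportion": inv / length,
            "hypergeom_p": hg_p,
            "ranksum_p": rs_p,
        }
    return rows


def intersect_interval_sets(
    cohort_intervals: Sequence[Sequence[InvariableInterval]],
    min_len: int = 10,
    genome_len: int = MT_GENOME_LENGTH,
) -> list[InvariableInterval]:
    """Positionwise intersection of invariable bases across cohorts,
    re-segmented into maximal runs and filtered to length > min_len."""
    if len(cohort_intervals) < 2:
        raise ValueError("need at least two cohorts to intersect")
    mask = np.ones(genome_len + 1, dtype=bool)
    mask[0] = False
    for ivs in cohort_intervals:
        m = np.zeros(genome_len + 1, dtype=bool)
        for iv in ivs:
            m[iv.start : iv.end + 1] = True
        mask &= m
    out: list[InvariableInterval] = []
    start = None
    for pos in range(1, genome_len + 1):
        if mask[pos]:
            if start is None:
                start = pos
        elif start is not None:
            out.append(InvariableInterval(start, pos - 1))
            start = None
    if start is not None:
        out.append(InvariableInterval(start, genome_len))
    return [iv for iv in out if iv.length > min_len]


def conservation_identity(
    variable_set: Iterable[int],
    intervals: Sequence[InvariableInterval],
    gap_set: Iterable[int] = (),
    genome_len: int = MT_GENOME_LENGTH,
) -> bool:
    """Check |variable positions| + |invariable bases| == genome length.

    Insertion gaps split intervals without consuming bases, so the
    identity must hold exactly for any cohort.
    """
    n_var = len({p for p in variable_set if 1 <= p <= genome_len})
    n_inv = sum(iv.length for iv in intervals)
    return n_var + n_inv == genome_len


def score_track_ranksum(
    intervals: Sequence[InvariableInterval],
    scores: Sequence[float],
    genome_len: int = MT_GENOME_LENGTH,
) -> float:
    """One-tailed rank-sum p that per-base conservation scores inside
    invariable intervals exceed those outside (scores indexed 1..L,
    supplied by the user, e.g. phastCons or phyloP tracks)."""
    scores = np.asarray(scores, dtype=float)
    if scores.size != genome_len:
        raise ValueError(f"need {genome_len} per-base scores, got {scores.size}")
    mask = np.zeros(genome_len, dtype=bool)
    for iv in intervals:
        mask[iv.start - 1 : iv.end] = True
    inside, outside = scores[mask], scores[~mask]
    if inside.size == 0 or outside.size == 0:
        return float("nan")
    return float(mannwhitneyu(inside, outside, alternative="greater").pvalue)
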