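"""Non-reference NUMT detection from discordant read pairs and split reads.

Detection follows the standard paired-end evidence chain:

1. ``select_discordant`` keeps read pairs with exactly one mate on the
   mitochondrial contig and one on a primary nuclear chromosome, above
   a MAPQ floor.
2. ``cluster_discordant`` chains nuclear-side positions per sample by
   single linkage with a 500 bp maximum gap; clusters supported by
   fewer than five pairs are discarded.
3. ``group_events`` merges clusters across samples whose span midpoints
   lie within 1000 bp on the same chromosome into one NUMT event.
4. ``refine_breakpoints`` collects split reads within 500 bp flanks of
   the cluster span and confirms a junction when at least two split
   reads agree on the exact (nuclear, mitochondrial) coordinate pair.
5. ``numt_size`` measures the inserted arc on the circular 16,569 bp
   mitochondrial genome; ``flag_known`` marks events overlapping a
   published NUMT set padded by 500 bp.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, replace
from typing import Callable, Iterable, Sequence

import numpy as np

from mitocohort.circular import MT_GENOME_LENGTH, arc_length
from mitocohort.io_formats import AlignmentRecordLite, BedInterval, is_mito
from mitocohort.mt_variants import frequency_category

logger = logging.getLogger(__name__)

_PRIMARY_CHROMS = {f"chr{i}" for i in range(1, 23)} | {"chrX", "chrY"} | {
    str(i) for i in range(1, 23)
} | {"X", "Y"}


@dataclass(frozen=True)
class DiscordantPair:
    """A read pair bridging the nuclear genome and chrM."""

    sample_id: str
    nuclear_chrom: str
    nuclear_pos: int
    nuclear_strand: str
    mito_pos: int
    mito_strand: str
    mapq_min: int

    def __post_init__(self):
        if not 1 <= self.mito_pos <= MT_GENOME_LENGTH:
            raise ValueError(f"mito position {self.mito_pos} outside mtDNA")


@dataclass(frozen=True)
class SplitRead:
    """A clipped read whose segments pin a nuclear/mito junction."""

    read_id: str
    sample_id: str
    nuclear_chrom: str
    nuclear_bp: int    # 1-based junction coordinate on the nucleus
    mito_bp: int       # 1-based junction coordinate on chrM


@dataclass
class NumtCluster:
    sample_id: str
    nuclear_chrom: str
    span_start: int
    span_end: int
    n_pairs: int
    member_ids: tuple[int, ...] = ()

    @property
    def midpoint(self) -> float:
        return (self.span_start + self.span_end) / 2.0


@dataclass
class NumtEvent:
    event_id: str
    nuclear_chrom: str
    span_start: int
    span_end: int
    samples: frozenset[str]
    n_pairs: int
    nuclear_bp_left: int | None = None
    nuclear_bp_right: int | None = None
    mito_bp_a: int | None = None
    mito_bp_b: int | None = None
    size_bp: int | None = None
    n_split_reads: int = 0
    refined: bool = False
    freq_category: str | None = None
    known: bool = False

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def anchor(self) -> float:
        return (self.span_start + self.span_end) / 2.0


def select_discordant(
    records: Iterable[AlignmentRecordLite],
    min_mapq: int = 20,
) -> list[DiscordantPair]:
    """Keep pairs with exactly one mate on chrM and one on a primary
    nuclear chromosome; drop pairs below the MAPQ floor.

    Input records are per-read; the nuclear-side record of each
    qualifying pair is used (one DiscordantPair per read record whose
    own side is nuclear and whose mate is chrM, so mate records on chrM
    do not double-count the pair).
    """
    out: list[DiscordantPair] = []
    for rec in records:
        if is_mito(rec.chrom) or not is_mito(rec.mate_chrom):
            continue  # need this side nuclear, mate mitochondrial
        if rec.chrom not in _PRIMARY_CHROMS:
            continue
        if rec.mapq < min_mapq:
            continue
        if not 1 <= rec.mate_pos <= MT_GENOME_LENGTH:
            continue
        out.append(
            DiscordantPair(
                sample_id=rec.sample_id,
                nuclear_chrom=rec.chrom,
                nuclear_pos=rec.pos,
                nuclear_strand=rec.strand,
                mito_pos=rec.mate_pos,
                mito_strand="+",
                mapq_min=rec.mapq,
            )
        )
    return out


def cluster_discordant(
    pairs: Sequence[DiscordantPair],
    max_gap: int = 500,
    min_pairs: int = 5,
) -> list[NumtCluster]:
    """Single-linkage chaining of discordant pairs on the nuclear axis.

    Within each (sample, chromosome), sorted nuclear positions whose
    successive gaps are <= ``max_gap`` join one cluster; clusters with
    fewer than ``min_pairs`` members are discarded. Order-independent
    by construction (positions are sorted first).
    """
    by_key: dict[tuple[str, str], list[tuple[int, int]]] = defaultdict(list)
    for i, p in enumerate(pairs):
        by_key[(p.sample_id, p.nuclear_chrom)].append((p.nuclear_pos, i))
    clusters: list[NumtCluster] = []
    for (sample, chrom), members in sorted(by_key.items()):
        members.sort()
        run: list[tuple[int, int]] = [members[0]]
        for pos, idx in members[1:]:
            if pos - run[-1][0] <= max_gap:
                run.append((pos, idx))
            else:
                clusters.extend(_emit_cluster(sample, chrom, run, min_pairs))
                run = [(pos, idx)]
        clusters.extend(_emit_cluster(sample, chrom, run, min_pairs))
    return clusters


def _emit_cluster(sample, chrom, run, min_pairs) -> list[NumtCluster]:
    if len(run) < min_pairs:
        return []
    return [
        NumtCluster(
            sample_id=sample,
            nuclear_chrom=chrom,
            span_start=run[0][0],
            span_end=run[-1][0],
            n_pairs=len(run),
            member_ids=tuple(idx for _, idx in run),
        )
    ]


def group_events(
    clusters: Sequence[NumtCluster],
    max_dist: int = 1000,
) -> list[NumtEvent]:
    """Merge per-sample clusters into cross-sample NUMT events.

    Single-linkage on cluster span midpoints per chromosome with a
    1000 bp distance cap; carriers are counted as distinct samples.
    """
    by_chrom: dict[str, list[NumtCluster]] = defaultdict(list)
    for c in clusters:
        by_chrom[c.nuclear_chrom].append(c)
    events: list[NumtEvent] = []
    for chrom, cs in sorted(by_chrom.items()):
        cs.sort(key=lambda c: (c.midpoint, c.sample_id))
        group: list[NumtCluster] = [cs[0]]
        for c in cs[1:]:
            if c.midpoint - group[-1].midpoint <= max_dist:
                group.append(c)
            else:
                events.append(_emit_event(chrom, group, len(events)))
                group = [c]
        events.append(_emit_event(chrom, group, len(events)))
    return events


def _emit_event(chrom: str, group: list[NumtCluster], n: int) -> NumtEvent:
    return NumtEvent(
        event_id=f"NUMT_{n + 1:05d}",
        nuclear_chrom=chrom,
        span_start=min(c.span_start for c in group),
        span_end=max(c.span_end for c in group),
        samples=frozenset(c.sample_id for c in group),
        n_pairs=sum(c.n_pairs for c in group),
    )


# A split aligner maps one clipped alignment record to a junction
# (nuclear_chrom, nuclear_bp, mito_bp), or None when unalignable.
SplitAligner = Callable[[AlignmentRecordLite], "SplitRead | None"]


def segment_junction_aligner(record: AlignmentRecordLite) -> SplitRead | None:
    """Default aligner for records that already carry their segmentation.

    Expects ``cigar_or_segments`` of the form
    ``"<chrom>:<start>-<end>;chrM:<start>-<end>"`` (either order): the
    junction is the nuclear segment boundary facing the mito segment,
    i.e. the nuclear end and the mito start (first base of the inserted
    arc on that side). Records without parseable two-locus segments
    yield None.
    """
    parts = record.cigar_or_segments.split(";")
    if len(parts) != 2:
        return None
    segs = []
    for part in parts:
        try:
            chrom, span = part.split(":")
            s, e = span.split("-")
            segs.append((chrom, int(s), int(e)))
        except ValueError:
            return None
    mito = [s for s in segs if is_mito(s[0])]
    nuc = [s for s in segs if not is_mito(s[0])]
    if len(mito) != 1 or len(nuc) != 1:
        return None
    nchrom, nstart, nend = nuc[0]
    _, mstart, mend = mito[0]
    # nuclear segment listed first -> read runs nucleus->mito: junction at
    # nuclear end / mito start; mito-first is the mirrored right junction.
    if not is_mito(segs[0][0]):
        nuclear_bp, mito_bp = nend, mstart
    else:
        nuclear_bp, mito_bp = nstart, mend
    return SplitRead(
        read_id=record.read_id,
        sample_id=record.sample_id,
        nuclear_chrom=nchrom,
        nuclear_bp=nuclear_bp,
        mito_bp=mito_bp,
    )


def refine_breakpoints(
    event: NumtEvent,
    split_records: Sequence[AlignmentRecordLite],
    aligner: SplitAligner = segment_junction_aligner,
    flank: int = 500,
    min_split: int = 2,
) -> NumtEvent:
    """Confirm exact breakpoints from split reads near the event.

    Split reads whose nuclear anchor falls within
    [span_start - flank, span_end + flank] are realigned by ``aligner``
    into candidate (nuclear_bp, mito_bp) junctions. A junction is
    confirmed when >= ``min_split`` reads agree on it exactly. The
    event is refined only when two distinct junctions (the left and
    right side of the insertion) are both confirmed; otherwise it is
    retained unrefined, preserving frequency accounting.
    """
    lo, hi = event.span_start - flank, event.span_end + flank
    junctions: Counter[tuple[int, int]] = Counter()
    n_used = 0
    for rec in split_records:
        if not rec.is_split:
            continue
        try:
            sr = aligner(rec)
        except Exception:  # aligner failure on one read must not kill the event
            logger.warning("split aligner failed on read %s; skipped", rec.read_id)
            continue
        if sr is None or sr.nuclear_chrom != event.nuclear_chrom:
            continue
        if not lo <= sr.nuclear_bp <= hi:
            continue
        junctions[(sr.nuclear_bp, sr.mito_bp)] += 1
        n_used += 1
    confirmed = sorted(j for j, n in junctions.items() if n >= min_split)
    ev = replace(event, n_split_reads=n_used)
    if len(confirmed) >= 2:
        if len(confirmed) > 2:
            # concatenated / complex insertion signature: leave unrefined,
            # mirrored by the complex-event side channel in call_numts
            return ev
        (nl, ma), (nr, mb) = sorted(confirmed)  # left/right by nuclear coord
        ev.nuclear_bp_left, ev.nuclear_bp_right = nl, nr
        ev.mito_bp_a, ev.mito_bp_b = ma, mb
        ev.size_bp = numt_size(ma, mb, orientation="forward")
        ev.refined = True
    return ev


def numt_size(
    mito_bp_a: int,
    mito_bp_b: int,
    orientation: str = "shorter",
    genome_len: int = MT_GENOME_LENGTH,
) -> int:
    """Inserted mtDNA bases between two breakpoints on the circle.

    ``orientation='forward'`` walks a->b in increasing coordinates
    (wrapping the origin); ``'shorter'`` (default without orientation
    evidence) takes the smaller arc; identical breakpoints denote a
    full-circle insertion of genome_len - 1 bases (the junction base is
    not duplicated).
    """
    return arc_length(mito_bp_a, mito_bp_b, orientation=orientation, genome_len=genome_len)


def flag_known(
    events: Sequence[NumtEvent],
    known_numts: Sequence[BedInterval],
    pad: int = 500,
) -> list[NumtEvent]:
    """Mark events overlapping a published NUMT interval padded +-500 bp.

    Refined events are matched on their breakpoint interval, unrefined
    events on the cluster span (1-based inclusive both ways).
    """
    by_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for iv in known_numts:
        # BED half-open 0-based -> 1-based inclusive, then pad
        by_chrom[iv.chrom].append((iv.start + 1 - pad, iv.end + pad))
    out = []
    for ev in events:
        if ev.refined:
            lo, hi = ev.nuclear_bp_left, ev.nuclear_bp_right
        else:
            lo, hi = ev.span_start, ev.span_end
        hit = any(s <= hi and e >= lo for s, e in by_chrom.get(ev.nuclear_chrom, ()))
        out.append(replace(ev, known=hit))
    return out


def assign_frequency_classes(events: Sequence[NumtEvent], n_cohort: int) -> list[NumtEvent]:
    """Attach the common/rare/ultra-rare/private class per carrier count."""
    return [
        replace(ev, freq_category=frequency_category(ev.n_samples, n_cohort))
        for ev in events
    ]


def per_sample_numt_stats(
    events: Sequence[NumtEvent],
    samples: Sequence[str],
) -> tuple[dict[str, int], float, float]:
    """Per-sample NUMT counts plus cohort mean and sample SD (ddof=1)."""
    counts = {s: 0 for s in samples}
    for ev in events:
        for s in ev.samples:
            if s in counts:
                counts[s] += 1
    values = np.array(list(counts.values()), dtype=float)
    mean = float(values.mean()) if len(values) else float("nan")
    sd = float(values.std(ddof=1)) if len(values) > 1 else float("nan")
    return counts, mean, sd


def call_numts(
    records: Sequence[AlignmentRecordLite],
    n_cohort: int,
    known_numts: Sequence[BedInterval] = (),
    min_mapq: int = 20,
    max_gap: int = 500,
    min_pairs: int = 5,
    group_dist: int = 1000,
    flank: int = 500,
    min_split: int = 2,
    aligner: SplitAligner = segment_junction_aligner,
) -> list[NumtEvent]:
    """End-to-end NUMT calling from alignment evidence records."""
    pairs = select_discordant([r for r in records if not r.is_split], min_mapq=min_mapq)
    clusters: list[NumtCluster] = []
    by_sample: dict[str, list[DiscordantPair]] = defaultdict(list)
    for p in pairs:
        by_sample[p.sample_id].append(p)
    for sample_pairs in by_sample.values():
        clusters.extend(cluster_discordant(sample_pairs, max_gap=max_gap, min_pairs=min_pairs))
    if not clusters:
        return []
    events = group_events(clusters, max_dist=group_dist)
    split_records = [r for r in records if r.is_split]
    events = [
        refine_breakpoints(ev, split_records, aligner=aligner, flank=flank, min_split=min_split)
        for ev in events
    ]
    events = assign_frequency_classes(events, n_cohort)
    if known_numts:
        events = flag_known(events, known_numts)
    return events
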