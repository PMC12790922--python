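"""Readers and writers for the external formats the pipeline touches.

Conventions enforced at the I/O boundary and nowhere else:

* mtDNA positions are 1-based inclusive on rCRS; the mitochondrial
  contig is unified to ``chrM`` (``MT`` accepted on input).
* BED is 0-based half-open; conversion to/from 1-based happens here.
* Multi-allelic VCF records are split into one record per ALT allele
  before anything downstream sees them.

Malformed coordinates are rejected with an error naming the offending
record; nothing is silently coerced.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from cyvcf2 import VCF

# known WGS artifact / low-complexity sites on rCRS (1-based)
ARTIFACT_POSITIONS: frozenset[int] = frozenset(
    set(range(66, 72))
    | {301, 302, 310, 316, 3107}
    | set(range(12418, 12426))
    | set(range(16182, 16195))
)

_MT_NAMES = {"chrM", "MT", "chrMT", "M"}


def normalize_chrom(chrom: str) -> str:
    """Unify mitochondrial contig names to ``chrM``; others pass through."""
    return "chrM" if chrom in _MT_NAMES else chrom


def is_mito(chrom: str) -> bool:
    return chrom in _MT_NAMES


@dataclass(frozen=True)
class VcfRecordLite:
    """One bi-allelic per-sample variant call with allele-depth evidence."""

    chrom: str
    pos: int          # 1-based
    ref: str
    alt: str
    filter: frozenset[str]
    ad: int           # alt-supporting reads
    dp: int           # total depth at site
    is_artifact_site: bool = False

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"position {self.pos} < 1 at {self.chrom}:{self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")
        if self.dp <= 0:
            raise ValueError(f"non-positive DP at {self.chrom}:{self.pos}")
        if not 0 <= self.ad <= self.dp:
            raise ValueError(f"AD {self.ad} outside [0, DP={self.dp}] at {self.chrom}:{self.pos}")

    @property
    def passed(self) -> bool:
        return "PASS" in self.filter


@dataclass(frozen=True)
class BedInterval:
    """Half-open 0-based genomic interval (BED convention)."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    feature_class: str | None = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} (need 0 <= start < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class AlignmentRecordLite:
    """Minimal paired-end alignment record carrying NUMT evidence."""

    read_id: str
    sample_id: str
    chrom: str
    pos: int                      # 1-based leftmost
    strand: str                   # '+' or '-'
    mate_chrom: str
    mate_pos: int
    is_split: bool
    cigar_or_segments: str        # CIGAR, or "chrom:start-end;chrom:start-end" segments
    mapq: int

    def __post_init__(self):
        if self.strand not in {"+", "-"}:
            raise ValueError(f"bad strand {self.strand!r} for read {self.read_id}")
        if self.pos < 1:
            raise ValueError(f"bad position {self.pos} for read {self.read_id}")


def read_mt_vcf(
    path: str | Path,
    artifact_positions: Iterable[int] = ARTIFACT_POSITIONS,
    sample: str | None = None,
) -> list[VcfRecordLite]:
    """Read a single-sample mtDNA VCF into bi-allelic lite records.

    Multi-allelic sites are split into one record per ALT, taking the
    per-allele AD for each. Records at artifact positions are retained
    but flagged, so downstream filters can drop them with a reason.

    Raises
    ------
    ValueError
        If AD or DP FORMAT fields are missing for a record, or a
        position is malformed.
    """
    artifact = frozenset(artifact_positions)
    vcf = VCF(str(path))
    samples = vcf.samples
    if not samples:
        raise ValueError(f"{path}: VCF has no sample columns (need per-sample AD/DP)")
    if sample is None:
        sidx = 0
    else:
        try:
            sidx = samples.index(sample)
        except ValueError:
            raise ValueError(f"{path}: sample {sample!r} not in VCF") from None

    out: list[VcfRecordLite] = []
    for var in vcf:
        chrom = normalize_chrom(var.CHROM)
        pos = var.POS
        filt = frozenset((var.FILTER or "PASS").split(";"))
        ad_arr = var.format("AD")
        dp_arr = var.format("DP")
        if ad_arr is None:
            raise ValueError(f"{path}: record {chrom}:{pos} lacks FORMAT/AD")
        ad_row = ad_arr[sidx]
        if dp_arr is not None:
            dp = int(dp_arr[sidx][0] if hasattr(dp_arr[sidx], "__len__") else dp_arr[sidx])
        else:
            raise ValueError(f"{path}: record {chrom}:{pos} lacks FORMAT/DP")
        alts = var.ALT
        if len(ad_row) < len(alts) + 1:
            raise ValueError(
                f"{path}: record {chrom}:{pos} AD has {len(ad_row)} values for "
                f"{len(alts)} ALT alleles; per-allele AD required"
            )
        for i, alt in enumerate(alts):
            out.append(
                VcfRecordLite(
                    chrom=chrom,
                    pos=pos,
                    ref=var.REF.upper(),
                    alt=alt.upper(),
                    filter=filt,
                    ad=int(ad_row[i + 1]),
                    dp=dp,
                    is_artifact_site=pos in artifact,
                )
            )
    out.sort(key=lambda r: (r.chrom, r.pos, r.ref, r.alt))
    return out


def read_bed(path: str | Path) -> list[BedInterval]:
    """Read a BED3+ file; columns 4 and 5+ map to name / feature_class."""
    out: list[BedInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from None
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start {start} >= end {end}")
            out.append(
                BedInterval(
                    chrom=cols[0],
                    start=start,
                    end=end,
                    name=cols[3] if len(cols) > 3 and cols[3] != "." else None,
                    feature_class=cols[4] if len(cols) > 4 and cols[4] != "." else None,
                )
            )
    return out


def write_bed(intervals: Iterable[BedInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.feature_class is not None:
                cols.append(iv.name if iv.name is not None else ".")
            if iv.feature_class is not None:
                cols.append(iv.feature_class)
            fh.write("\t".join(cols) + "\n")


_CLIP_RE = re.compile(r"(\d+)([SH])")


def _cigar_has_clip(cigar: str) -> bool:
    return bool(_CLIP_RE.search(cigar))


def read_alignment_records(
    path: str | Path,
    dialect: str,
    sample_id: str | None = None,
) -> list[AlignmentRecordLite]:
    """Read paired-end alignment evidence records.

    Parameters
    ----------
    dialect : {"sam-text", "tsv"}
        ``sam-text`` is headerless minimal SAM (QNAME FLAG RNAME POS
        MAPQ CIGAR RNEXT PNEXT ...); ``tsv`` is a header-rowed table
        with columns read_id, sample_id, chrom, pos, strand, mate_chrom,
        mate_pos, is_split, cigar_or_segments, mapq.
    sample_id : str, optional
        Sample label for SAM input (SAM rows carry none); defaults to
        the file stem.

    Records with unmapped mates are dropped. MAPQ thresholds are NOT
    applied here (that belongs to NUMT detection).
    """
    path = Path(path)
    if dialect == "sam-text":
        return _read_sam_text(path, sample_id or path.stem)
    if dialect == "tsv":
        return _read_alignment_tsv(path)
    raise ValueError(f"unknown alignment dialect {dialect!r} (expected 'sam-text' or 'tsv')")


def _read_sam_text(path: Path, sample_id: str) -> list[AlignmentRecordLite]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("@"):
                continue
            cols = line.split("\t")
            if len(cols) < 8:
                raise ValueError(f"{path}:{lineno}: fewer than 8 SAM columns")
            qname, flag_s, rname, pos_s, mapq_s, cigar, rnext, pnext_s = cols[:8]
            try:
                flag, pos, mapq, pnext = int(flag_s), int(pos_s), int(mapq_s), int(pnext_s)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: malformed integer field") from None
            if flag & 0x8 or rnext == "*":  # mate unmapped
                continue
            mate_chrom = rname if rnext == "=" else rnext
            out.append(
                AlignmentRecordLite(
                    read_id=qname,
                    sample_id=sample_id,
                    chrom=normalize_chrom(rname),
                    pos=pos,
                    strand="-" if flag & 0x10 else "+",
                    mate_chrom=normalize_chrom(mate_chrom),
                    mate_pos=pnext,
                    is_split=_cigar_has_clip(cigar),
                    cigar_or_segments=cigar,
                    mapq=mapq,
                )
            )
    return out


_TSV_COLUMNS = [
    "read_id", "sample_id", "chrom", "pos", "strand",
    "mate_chrom", "mate_pos", "is_split", "cigar_or_segments", "mapq",
]


def _read_alignment_tsv(path: Path) -> list[AlignmentRecordLite]:
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {}
        for col in _TSV_COLUMNS:
            if col not in header:
                raise ValueError(f"{path}: missing column {col!r}")
            idx[col] = header.index(col)
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            g = lambda c: cols[idx[c]]
            mate_chrom = g("mate_chrom")
            if mate_chrom in {"*", ""}:
                continue
            try:
                pos, mate_pos, mapq = int(g("pos")), int(g("mate_pos")), int(g("mapq"))
            except ValueError:
                raise ValueError(f"{path}:{lineno}: malformed integer field") from None
            out.append(
                AlignmentRecordLite(
                    read_id=g("read_id"),
                    sample_id=g("sample_id"),
                    chrom=normalize_chrom(g("chrom")),
                    pos=pos,
                    strand=g("strand"),
                    mate_chrom=normalize_chrom(mate_chrom),
                    mate_pos=mate_pos,
                    is_split=g("is_split").lower() in {"1", "true", "yes"},
                    cigar_or_segments=g("cigar_or_segments"),
                    mapq=mapq,
                )
            )
    return out


def write_alignment_tsv(records: Iterable[AlignmentRecordLite], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    [
                        r.read_id, r.sample_id, r.chrom, str(r.pos), r.strand,
                        r.mate_chrom, str(r.mate_pos),
                        "1" if r.is_split else "0",
                        r.cigar_or_segments, str(r.mapq),
                    ]
                )
                + "\n"
            )
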