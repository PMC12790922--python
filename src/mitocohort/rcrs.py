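"""rCRS (NC_012920.1) feature annotation and the flattened region table.

Coordinates are 1-based inclusive on the 16,569 bp revised Cambridge
Reference Sequence. ``RCRS_REGIONS`` lists the canonical genes and the
control region; ``build_region_table`` flattens them into a
non-overlapping tiling of the whole genome, assigning every position a
single region label. Where features overlap (e.g., MT-ATP8/MT-ATP6,
MT-ND4L/MT-ND4, adjacent tRNAs), precedence is

    tRNA > rRNA > protein_coding > D-loop > intergenic,

ties within a class going to the feature that starts first. Uncovered
positions become ``intergenic`` (label ``MT-IG-<n>``, the non-coding
spacers including the light-strand replication origin).
"""

from __future__ import annotations

from dataclasses import dataclass

from mitocohort.circular import MT_GENOME_LENGTH

# region_class precedence, highest first
_CLASS_RANK = {
    "tRNA": 0,
    "rRNA": 1,
    "protein_coding": 2,
    "D-loop": 3,
    "intergenic": 4,
}

# (name, start, end, region_class), 1-based inclusive.
# The D-loop wraps the origin and is listed as its two linear pieces.
RCRS_REGIONS: list[tuple[str, int, int, str]] = [
    ("MT-DLOOP", 1, 576, "D-loop"),
    ("MT-TF", 577, 647, "tRNA"),
    ("MT-RNR1", 648, 1601, "rRNA"),
    ("MT-TV", 1602, 1670, "tRNA"),
    ("MT-RNR2", 1671, 3229, "rRNA"),
    ("MT-TL1", 3230, 3304, "tRNA"),
    ("MT-ND1", 3307, 4262, "protein_coding"),
    ("MT-TI", 4263, 4331, "tRNA"),
    ("MT-TQ", 4329, 4400, "tRNA"),
    ("MT-TM", 4402, 4469, "tRNA"),
    ("MT-ND2", 4470, 5511, "protein_coding"),
    ("MT-TW", 5512, 5579, "tRNA"),
    ("MT-TA", 5587, 5655, "tRNA"),
    ("MT-TN", 5657, 5729, "tRNA"),
    ("MT-TC", 5761, 5826, "tRNA"),
    ("MT-TY", 5826, 5891, "tRNA"),
    ("MT-CO1", 5904, 7445, "protein_coding"),
    ("MT-TS1", 7446, 7514, "tRNA"),
    ("MT-TD", 7518, 7585, "tRNA"),
    ("MT-CO2", 7586, 8269, "protein_coding"),
    ("MT-TK", 8295, 8364, "tRNA"),
    ("MT-ATP8", 8366, 8572, "protein_coding"),
    ("MT-ATP6", 8527, 9207, "protein_coding"),
    ("MT-CO3", 9207, 9990, "protein_coding"),
    ("MT-TG", 9991, 10058, "tRNA"),
    ("MT-ND3", 10059, 10404, "protein_coding"),
    ("MT-TR", 10405, 10469, "tRNA"),
    ("MT-ND4L", 10470, 10766, "protein_coding"),
    ("MT-ND4", 10760, 12137, "protein_coding"),
    ("MT-TH", 12138, 12206, "tRNA"),
    ("MT-TS2", 12207, 12265, "tRNA"),
    ("MT-TL2", 12266, 12336, "tRNA"),
    ("MT-ND5", 12337, 14148, "protein_coding"),
    ("MT-ND6", 14149, 14673, "protein_coding"),
    ("MT-TE", 14674, 14742, "tRNA"),
    ("MT-CYB", 14747, 15887, "protein_coding"),
    ("MT-TT", 15888, 15953, "tRNA"),
    ("MT-TP", 15956, 16023, "tRNA"),
    ("MT-DLOOP", 16024, 16569, "D-loop"),
]


@dataclass(frozen=True)
class Region:
    """One segment of the flattened region tiling, 1-based inclusive."""

    name: str
    start: int
    end: int
    region_class: str

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def build_region_table(
    regions: list[tuple[str, int, int, str]] | None = None,
    genome_len: int = MT_GENOME_LENGTH,
) -> list[Region]:
    """Flatten possibly-overlapping features into a complete tiling.

    Every position in 1..genome_len gets exactly one (name, class) by
    the class precedence above; adjacent positions with the same
    assignment are merged into one :class:`Region`.
    """
    if regions is None:
        regions = RCRS_REGIONS
    # per-position winner (rank, listed order, name, class)
    assign: list[tuple[int, int, str, str] | None] = [None] * (genome_len + 1)
    for order, (name, start, end, rclass) in enumerate(regions):
        if not (1 <= start <= end <= genome_len):
            raise ValueError(f"feature {name} outside 1..{genome_len}")
        rank = _CLASS_RANK[rclass]
        for pos in range(start, end + 1):
            cur = assign[pos]
            if cur is None or (rank, order) < (cur[0], cur[1]):
                assign[pos] = (rank, order, name, rclass)

    out: list[Region] = []
    ig_counter = 0
    cur_name = cur_class = None
    cur_start = 1
    for pos in range(1, genome_len + 1):
        entry = assign[pos]
        if entry is None:
            name, rclass = None, "intergenic"
        else:
            name, rclass = entry[2], entry[3]
        if (name, rclass) != (cur_name, cur_class):
            if pos > 1:
                out.append(_mk_region(cur_name, cur_start, pos - 1, cur_class, ig_counter))
                if cur_name is None:
                    ig_counter += 1
            cur_name, cur_class, cur_start = name, rclass, pos
    out.append(_mk_region(cur_name, cur_start, genome_len, cur_class, ig_counter))
    return out


def _mk_region(name, start, end, rclass, ig_counter) -> Region:
    if name is None:
        name = f"MT-IG-{ig_counter + 1}"
    return Region(name=name, start=start, end=end, region_class=rclass)
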