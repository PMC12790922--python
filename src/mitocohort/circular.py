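"""Circular mtDNA coordinate arithmetic.

The human mitochondrial genome (rCRS, NC_012920.1) is a circle of
16,569 bp with 1-based positions. Arcs between two breakpoints are
measured going "forward" (increasing position, wrapping 16569 -> 1).
A zero-length forward arc is interpreted as the full circle, which
spans 16,568 bases: the junction base is not duplicated, so a
whole-genome insertion carries one base fewer than the genome length.
"""

from __future__ import annotations

MT_GENOME_LENGTH = 16_569


def _check_pos(pos: int, genome_len: int) -> None:
    if not 1 <= pos <= genome_len:
        raise ValueError(f"mtDNA position {pos} outside 1..{genome_len}")


def arc_length(
    start: int,
    end: int,
    orientation: str = "shorter",
    genome_len: int = MT_GENOME_LENGTH,
) -> int:
    """Number of mtDNA bases on the arc between two breakpoints.

    Parameters
    ----------
    start, end : int
        1-based breakpoint positions.
    orientation : {"forward", "reverse", "shorter", "full_circle"}
        Which arc to measure. "forward" walks from ``start`` to ``end``
        in increasing coordinates (wrapping the origin); "reverse" walks
        the complementary arc; "shorter" (default, used when orientation
        evidence is absent) picks the smaller of the two; "full_circle"
        always returns the whole-genome size ``genome_len - 1``.
    """
    _check_pos(start, genome_len)
    _check_pos(end, genome_len)
    if orientation == "full_circle":
        return genome_len - 1
    fwd = (end - start) % genome_len
    if fwd == 0:
        # identical breakpoints: the only non-degenerate arc is the full circle
        return genome_len - 1
    if orientation == "forward":
        return fwd
    if orientation == "reverse":
        return genome_len - fwd
    if orientation == "shorter":
        return min(fwd, genome_len - fwd)
    raise ValueError(f"unknown orientation {orientation!r}")


def arc_positions(
    start: int, end: int, genome_len: int = MT_GENOME_LENGTH
) -> list[int]:
    """1-based positions on the forward arc [start, end], origin-wrapping.

    ``start == end`` yields the single position, not the full circle.
    """
    _check_pos(start, genome_len)
    _check_pos(end, genome_len)
    if end >= start:
        return list(range(start, end + 1))
    return list(range(start, genome_len + 1)) + list(range(1, end + 1))


def wrap_position(pos: int, genome_len: int = MT_GENOME_LENGTH) -> int:
    """Map an arbitrary integer offset onto 1..genome_len."""
    return (pos - 1) % genome_len + 1
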