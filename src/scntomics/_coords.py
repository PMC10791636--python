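"""Coordinate-convention conversions, centralized so off-by-one logic lives once.

Conventions used throughout the package:

* VCF and SAM positions are 1-based, fully closed.
* BED intervals and all internal array indices are 0-based, half-open.
"""

from __future__ import annotations


def one_to_zero(pos_1based: int) -> int:
    """1-based position -> 0-based index."""
    if pos_1based < 1:
        raise ValueError(f"1-based position must be >= 1, got {pos_1based}")
    return pos_1based - 1


def zero_to_one(idx_0based: int) -> int:
    """0-based index -> 1-based position."""
    if idx_0based < 0:
        raise ValueError(f"0-based index must be >= 0, got {idx_0based}")
    return idx_0based + 1


def point_to_bed(pos_1based: int) -> tuple[int, int]:
    """A single 1-based position as a 0-based half-open BED interval."""
    return pos_1based - 1, pos_1based


def bed_to_point(start: int, end: int) -> int:
    """A single-base BED interval as its 1-based position."""
    if end != start + 1:
        raise ValueError(f"not a single-base interval: [{start}, {end})")
    return start + 1
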