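"""Multiscale continuous regions from an n-bit binary segment code.

A sequence is split into ``n_segments`` near-equal segments S_1..S_n.  An
n-bit inclusion code selects a subset of segments; only codes whose set
bits are consecutive (continuous regions) are used, and the full-sequence
run (all bits set) is excluded because whole-sequence information is
carried by the global composition descriptor.  For n=7 this yields 27
regions out of the 2^7 - 2 = 126 admissible non-trivial codes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoding import GroupSequence

DEFAULT_SEGMENTS = 7


@dataclass(frozen=True)
class RegionScheme:
    """The ordered continuous regions of an n-segment split.

    Regions are inclusive 1-based ``(start_segment, end_segment)`` pairs,
    ascending by start then end, excluding the full run ``(1, n_segments)``.
    """

    n_segments: int
    regions: tuple[tuple[int, int], ...]

    @property
    def n_regions(self) -> int:
        return len(self.regions)


def enumerate_regions(n_segments: int = DEFAULT_SEGMENTS) -> RegionScheme:
    """All contiguous segment runs except the full run.

    Count is n(n+1)/2 - 1 (27 for the default 7-segment scheme).
    """
    if n_segments < 2:
        raise ValueError("n_segments must be at least 2")
    regions = tuple(
        (start, end)
        for start in range(1, n_segments + 1)
        for end in range(start, n_segments + 1)
        if not (start == 1 and end == n_segments)
    )
    return RegionScheme(n_segments, regions)


def n_admissible_codes(n_segments: int) -> int:
    """Number of admissible n-bit inclusion codes, 2^n - 2 (excluding the
    all-zeros and all-ones codes)."""
    return 2 ** n_segments - 2


def segment_boundaries(length: int, n_segments: int = DEFAULT_SEGMENTS) -> np.ndarray:
    """0-based half-open cut points splitting ``length`` residues into
    ``n_segments`` near-equal segments; remainder residues go to the
    earliest segments.

    Segment i (1-based) has length floor(L/n)+1 for i <= L mod n, else
    floor(L/n).
    """
    if length < n_segments:
        raise ValueError(
            f"sequence too short for scheme: length {length} < "
            f"{n_segments} segments"
        )
    base, rem = divmod(length, n_segments)
    lengths = np.full(n_segments, base, dtype=np.int64)
    lengths[:rem] += 1
    return np.concatenate(([0], np.cumsum(lengths)))


def slice_region(gs: GroupSequence, boundaries: np.ndarray,
                 region: tuple[int, int]) -> np.ndarray:
    """Symbols of the contiguous run from the start of segment ``region[0]``
    through the end of segment ``region[1]`` (1-based inclusive)."""
    start, end = region
    n_segments = len(boundaries) - 1
    if not (1 <= start <= end <= n_segments):
        raise ValueError(f"invalid region {region} for {n_segments} segments")
    return gs.symbols[boundaries[start - 1]:boundaries[end]]
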