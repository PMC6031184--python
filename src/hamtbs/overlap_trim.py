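"""Overlap trimming of paired amplicon reads.

With 2 x 300 bp chemistry, any amplicon shorter than 600 bp yields mates
that overlap in the middle.  Counting both mates over the overlap would
double-count each template molecule and over-weight the lower-quality
read-end bases, so before methylation calling the overlapping stretch is
removed from one mate: the mate whose mean base quality over the overlap
is lower loses its overlapping bases (hard trim), with ties trimming
mate 2 (read-end 2 is empirically the lower-quality mate).  After trimming,
every reference position is covered at most once per pair.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np

from .reads import AlignedPair, Mate


def _cut_overlap(mate: Mate, ov_start: int, ov_end: int) -> Mate:
    """Remove the bases of ``mate`` covering [ov_start, ov_end] (1-based).

    If the overlap touches the mate's start, the prefix is removed;
    otherwise everything from the overlap start onward is removed, so the
    remaining bases are always one contiguous block.
    """
    if ov_start <= mate.start:
        keep_from = ov_end - mate.start + 1  # array offset of first kept base
        return Mate(
            start=ov_end + 1,
            bases=mate.bases[keep_from:],
            quals=mate.quals[keep_from:],
        )
    keep_to = ov_start - mate.start  # array offset one past last kept base
    return Mate(
        start=mate.start,
        bases=mate.bases[:keep_to],
        quals=mate.quals[:keep_to],
    )


def trim_overlap(pair: AlignedPair) -> AlignedPair:
    """Trim the lower-quality mate over the mates' overlapping interval.

    Non-overlapping pairs (and pairs with a missing or empty mate) are
    returned unchanged.  The returned pair shares base/quality storage with
    the input where possible; the input is never mutated.
    """
    m1, m2 = pair.mate1, pair.mate2
    if m1 is None or m2 is None or len(m1) == 0 or len(m2) == 0:
        return pair
    ov_start = max(m1.start, m2.start)
    ov_end = min(m1.end, m2.end)
    if ov_start > ov_end:
        return pair

    def mean_q(m: Mate) -> float:
        lo = ov_start - m.start
        hi = ov_end - m.start + 1
        return float(m.quals[lo:hi].mean())

    if mean_q(m2) <= mean_q(m1):  # tie trims mate 2
        return AlignedPair(pair.amplicon, pair.name, m1, _cut_overlap(m2, ov_start, ov_end))
    return AlignedPair(pair.amplicon, pair.name, _cut_overlap(m1, ov_start, ov_end), m2)


def trim_pairs(pairs: Iterable[AlignedPair]) -> list[AlignedPair]:
    """Trim every pair of an iterable."""
    return [trim_overlap(p) for p in pairs]


def pair_position_coverage(pair: AlignedPair, length: int) -> np.ndarray:
    """Per-position coverage contributed by one pair (diagnostic helper)."""
    cov = np.zeros(length, dtype=np.int64)
    for m in pair.mates():
        cov[m.start - 1 : m.end] += 1
    return cov
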