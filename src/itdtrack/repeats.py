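"""Maximal tandem-repeat detection inside individual reads.

A tandem repeat with period ``p`` is a maximal run of positions ``i``
where ``seq[i] == seq[i + p]``, tolerating at most ``resolution``
mismatching comparisons per run. The repeat occupies the half-open
interval ``[start, start + span)`` with ``span = run_length + p``; a
span of at least ``2 * p`` means the duplicated unit is fully contained
(copies >= 2), which is what nominates an ITD: partially spanned
duplications are not reported.

A run at period ``p`` is reported with its minimal period: when a
maximal run at some smaller period covers the same sequence interval
(e.g. a homopolymer, which repeats at every period), the larger-period
report is suppressed. With ``min_period`` at its default of 15 bp this
makes simple sequence (homopolymers, microsatellites) invisible while
keeping every biologically plausible ITD.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_MIN_PERIOD = 15
DEFAULT_MAX_PERIOD = 150
DEFAULT_RESOLUTION = 1


@dataclass(frozen=True)
class TandemRepeat:
    start: int
    period: int
    span: int
    mismatches: int

    @property
    def copies(self) -> float:
        return self.span / self.period

    @property
    def end(self) -> int:
        return self.start + self.span


def _maximal_windows(
    m: np.ndarray, resolution: int, min_len: int
) -> list[tuple[int, int, int]]:
    """Maximal windows of the boolean match array with <= resolution zeros
    and at least ``min_len`` positions.

    Returns (a, b, zeros) triples where [a, b) indexes ``m``. A window is
    maximal when extending it on either side would exceed the budget or
    run off the array; every maximal window away from the array ends
    contains exactly ``resolution`` zeros.
    """
    L = len(m)
    if L == 0:
        return []
    z = np.flatnonzero(~m)
    k = len(z)
    if k <= resolution:
        return [(0, L, k)] if L >= min_len else []
    zs = np.concatenate([[-1], z, [L]])
    a = zs[: k - resolution + 1] + 1
    b = zs[resolution + 1 :]
    sel = np.flatnonzero(b - a >= min_len)
    return [(int(a[i]), int(b[i]), resolution) for i in sel]


def find_tandem_repeats(
    seq: str,
    min_period: int = DEFAULT_MIN_PERIOD,
    max_period: int = DEFAULT_MAX_PERIOD,
    resolution: int = DEFAULT_RESOLUTION,
) -> list[TandemRepeat]:
    """All maximal, minimal-period tandem repeats with copies >= 2.

    Sorted by (start, period). A sequence shorter than ``2 * min_period``
    yields an empty list.
    """
    n = len(seq)
    if min_period < 1:
        raise ValueError("min_period must be >= 1")
    if n < 2 * min_period:
        return []
    s = np.frombuffer(seq.upper().encode(), np.uint8)

    # Candidate reports in the allowed period range.
    candidates: list[TandemRepeat] = []
    for p in range(min_period, min(max_period, n // 2) + 1):
        m = s[:-p] == s[p:]
        # window length >= p means span >= 2p: full second copy present
        for a, b, zeros in _maximal_windows(m, resolution, p):
            candidates.append(TandemRepeat(a, p, b - a + p, zeros))
    if not candidates:
        return []

    # Suppress non-minimal periods: a report is dropped when a maximal
    # window at a smaller period covers its whole sequence interval.
    # Smaller-period windows only matter when long enough to contain a
    # candidate, so short ones are filtered out immediately.
    min_candidate_span = min(c.span for c in candidates)
    covers: list[tuple[int, int, int]] = []  # (period, a, end_in_seq)
    for q in range(1, min(max(c.period for c in candidates) - 1, n // 2) + 1):
        m = s[:-q] == s[q:]
        for a, b, _zeros in _maximal_windows(m, resolution, max(q, min_candidate_span - q)):
            covers.append((q, a, b + q))

    out = []
    for c in candidates:
        if any(
            q < c.period and a <= c.start and e >= c.end for q, a, e in covers
        ):
            continue
        out.append(c)
    out.sort(key=lambda r: (r.start, r.period))
    return out


def best_repeat(repeats: list[TandemRepeat]) -> TandemRepeat | None:
    """Dominant repeat of a read: largest span, ties broken by smaller start."""
    if not repeats:
        return None
    return max(repeats, key=lambda r: (r.span, -r.start))
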