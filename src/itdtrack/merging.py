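"""Overlap-merging of amplicon mate pairs into single contiguous reads.

Mate 2 is reverse-complemented and every candidate overlap of at least
``min_overlap`` bases is evaluated; the overlap with the smallest
mismatch fraction wins, ties going to the longer overlap. Selecting by
mismatch *fraction* rather than raw match score matters on this locus:
a read carrying a tandem duplication of length p is self-similar at lag
p, so the overlap shifted by p aligns the two copies of the duplicated
unit and can out-score a short true overlap on matches minus mismatches
— collapsing the ITD. The true overlap is mismatch-free on clean data
and therefore always wins under the fraction rule. Overlapped positions
take the base with the higher Phred quality (ties go to mate 1). A pair
whose best overlap still exceeds ``max_mismatch_frac`` is left
unmerged; that is a counted outcome, not an error.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np

from .amplicon_io import ReadPair, revcomp

DEFAULT_MIN_OVERLAP = 10
DEFAULT_MAX_MISMATCH_FRAC = 0.1


@dataclass(eq=False)
class MergedRead:
    read_id: str
    seq: str
    qual: np.ndarray
    overlap_len: int
    n_overlap_mismatches: int


def merge_pair(
    pair: ReadPair,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC,
) -> MergedRead | None:
    """Merge one mate pair, or return None when no acceptable overlap exists.

    Candidate overlaps run over lengths ``min_overlap .. min(len1, len2)``;
    the smallest mismatch fraction wins, ties prefer the longer overlap.
    """
    s1 = np.frombuffer(pair.seq1.encode(), np.uint8)
    rc2 = revcomp(pair.seq2)
    s2 = np.frombuffer(rc2.encode(), np.uint8)
    q1 = pair.qual1
    q2 = pair.qual2[::-1]
    L1, L2 = len(s1), len(s2)
    vmax = min(L1, L2)
    if min_overlap < 1 or vmax < min_overlap:
        return None

    best_frac, best_v, best_mm = None, 0, 0
    for v in range(min_overlap, vmax + 1):
        mm = int(np.count_nonzero(s1[L1 - v :] != s2[:v]))
        frac = mm / v
        if best_frac is None or frac < best_frac or (frac == best_frac and v > best_v):
            best_frac, best_v, best_mm = frac, v, mm
    if best_frac > max_mismatch_frac:
        return None

    v = best_v
    a, b = s1[L1 - v :], s2[:v]
    qa, qb = q1[L1 - v :], q2[:v]
    agree = a == b
    take_a = qa >= qb  # quality tie -> mate 1
    ov_seq = np.where(agree | take_a, a, b)
    ov_qual = np.where(agree, np.maximum(qa, qb), np.where(take_a, qa, qb))
    seq = pair.seq1[: L1 - v] + ov_seq.tobytes().decode() + rc2[v:]
    qual = np.concatenate([q1[: L1 - v], ov_qual.astype(np.uint8), q2[v:]])
    return MergedRead(pair.read_id, seq, qual, v, best_mm)


def merge_pairs(
    pairs: Iterable[ReadPair],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC,
    max_pairs: int | None = None,
) -> tuple[list[MergedRead], dict]:
    """Merge a stream of pairs; returns (merged reads, QC tallies).

    ``max_pairs`` caps how many pairs are consumed (used for discovery
    subsampling on very deep samples).
    """
    merged: list[MergedRead] = []
    n_pairs = 0
    for pair in pairs:
        if max_pairs is not None and n_pairs >= max_pairs:
            break
        n_pairs += 1
        m = merge_pair(pair, min_overlap, max_mismatch_frac)
        if m is not None:
            merged.append(m)
    qc = {
        "pairs_seen": n_pairs,
        "merged": len(merged),
        "unmerged": n_pairs - len(merged),
        "merge_rate": (len(merged) / n_pairs) if n_pairs else None,
    }
    return merged, qc
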