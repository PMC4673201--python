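"""Independent brute-force oracles used to validate the implementation.

These deliberately recompute results by exhaustive enumeration or exact
combinatorics rather than sharing any code path with the package.
"""
from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np

from itdtrack.amplicon_io import revcomp


def oracle_tandem_repeats(seq, min_period, max_period, resolution):
    """Enumerate all (start, period, span) windows, keep the maximal ones
    within the mismatch budget, then drop non-minimal periods.

    Returns (start, period, span, mismatches) tuples sorted like the
    implementation's output.
    """
    n = len(seq)
    if n < 2 * min_period:
        return []

    def maximal_windows(p):
        m = np.array([seq[i] == seq[i + p] for i in range(n - p)], dtype=bool)
        L = len(m)
        zero_prefix = np.concatenate([[0], np.cumsum(~m)])
        wins = []
        for a in range(L):
            for b in range(a + 1, L + 1):
                zeros = int(zero_prefix[b] - zero_prefix[a])
                if zeros > resolution:
                    continue
                left_ok = a == 0 or (not m[a - 1] and zeros == resolution)
                right_ok = b == L or (not m[b] and zeros == resolution)
                if left_ok and right_ok and b - a >= p:
                    wins.append((a, b, zeros))
        return wins

    candidates = []
    for p in range(min_period, min(max_period, n // 2) + 1):
        for a, b, zeros in maximal_windows(p):
            candidates.append((a, p, b - a + p, zeros))

    covers = []
    if candidates:
        for q in range(1, min(max(c[1] for c in candidates), n // 2) + 1):
            for a, b, _ in maximal_windows(q):
                covers.append((q, a, b + q))

    out = []
    for a, p, span, zeros in candidates:
        if any(q < p and a2 <= a and e2 >= a + span for q, a2, e2 in covers):
            continue
        out.append((a, p, span, zeros))
    return sorted(out)


def oracle_best_overlap(seq1, seq2, min_overlap, max_mismatch_frac):
    """Brute-force overlap choice: scan every overlap length, pick the
    smallest mismatch fraction (ties -> longer), or None if unacceptable."""
    s2 = revcomp(seq2)
    best = None  # (frac, -v, mm)
    for v in range(min_overlap, min(len(seq1), len(seq2)) + 1):
        mm = sum(a != b for a, b in zip(seq1[len(seq1) - v :], s2[:v]))
        key = (mm / v, -v)
        if best is None or key < best[:2]:
            best = (mm / v, -v, mm)
    if best is None or best[0] > max_mismatch_frac:
        return None
    return (-best[1], best[2])  # (overlap, mismatches)


def oracle_fisher_greater(a, b, c, d):
    """Exact one-sided hypergeometric tail P(X >= a) for the 2x2 table
    [[a, b], [c, d]], computed with integer combinatorics."""
    n1, K, N = a + b, a + c, a + b + c + d
    denom = comb(N, K)
    total = Fraction(0)
    for k in range(a, min(n1, K) + 1):
        total += Fraction(comb(n1, k) * comb(N - n1, K - k), denom)
    return float(total)
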