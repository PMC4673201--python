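"""Reference-anchored ITD clone discovery and breakpoint counting.

Discovery is alignment-free: a merged read nominates an ITD when it
contains a fully-spanned tandem repeat; the read is anchored to the
amplicon by exact match of its first and last ``anchor_len`` bases, the
junction (where the second copy of the duplicated unit begins) is
located from the longest common prefix of the read with the reference,
and the insertion site is canonicalized to its left-most equivalent
position so that every read of the same allele reports the same
coordinates.

Counting is exact substring matching of two signatures over a sample's
reads: the junction signature (present only on the ITD allele) and the
wild-type signature (the reference context across the insertion site).
Because the ITD allele regenerates the wild-type context at the distal
end of the duplication, a read is counted as wild type only when it
carries the WT signature and *not* the junction signature; the two
tallies are therefore disjoint and their ratio can exceed 1 when the
mutant allele dominates (e.g. loss of the wild-type allele).
"""
from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

from .amplicon_io import AmpliconReference, ReadPair, revcomp
from .merging import MergedRead
from .repeats import (
    DEFAULT_MAX_PERIOD,
    DEFAULT_MIN_PERIOD,
    DEFAULT_RESOLUTION,
    best_repeat,
    find_tandem_repeats,
)

DEFAULT_K_FLANK = 12
DEFAULT_ANCHOR_LEN = 20
DEFAULT_MIN_SUPPORT = 5
DEFAULT_MIN_COPIES = 2.0


@dataclass(frozen=True)
class ITDClone:
    """A duplication allele: length, canonical insertion site and junction."""

    itd_length: int
    insertion_site: int
    junction_signature: str
    duplicated_seq: str
    support: int = 0

    @property
    def clone_id(self) -> str:
        return f"ITD{self.itd_length}@{self.insertion_site}"


@dataclass(frozen=True)
class WTSignature:
    site: int
    signature: str


@dataclass(frozen=True)
class CloneCounts:
    sample_id: str
    clone: ITDClone
    itd_reads: int
    wt_reads: int
    total_merged: int

    def __post_init__(self) -> None:
        if min(self.itd_reads, self.wt_reads, self.total_merged) < 0:
            raise ValueError("counts must be non-negative")
        if self.itd_reads + self.wt_reads > self.total_merged:
            raise ValueError("itd_reads + wt_reads exceeds total reads")


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance needs equal lengths")
    return sum(x != y for x, y in zip(a, b))


def same_clone(a: ITDClone, b: ITDClone) -> bool:
    """Clone identity across samples/runs: same length and site, junction
    signatures within one substitution."""
    return (
        a.itd_length == b.itd_length
        and a.insertion_site == b.insertion_site
        and len(a.junction_signature) == len(b.junction_signature)
        and hamming(a.junction_signature, b.junction_signature) <= 1
    )


def canonical_site(refseq: str, period: int, site: int) -> int:
    """Left-most equivalent insertion site of a tandem duplication.

    Duplicating ``ref[site-p:site]`` at ``site`` and ``ref[site-p-1:site-1]``
    at ``site - 1`` produce the same mutant sequence whenever
    ``ref[site-1] == ref[site-1-p]``; the left-most representative is the
    canonical one.
    """
    while site > period and refseq[site - 1] == refseq[site - 1 - period]:
        site -= 1
    return site


def wt_signature(
    reference: AmpliconReference, site: int, k_flank: int = DEFAULT_K_FLANK
) -> WTSignature:
    seq = reference.sequence
    if site - k_flank < 0 or site + k_flank > len(seq):
        raise ValueError(f"site {site}: WT signature flanks leave the amplicon")
    sig = seq[site - k_flank : site + k_flank]
    if seq.count(sig) != 1:
        raise ValueError(f"WT signature at site {site} is not unique on the amplicon")
    return WTSignature(site=site, signature=sig)


def clone_from_reference(
    reference: AmpliconReference,
    itd_length: int,
    insertion_site: int,
    k_flank: int = DEFAULT_K_FLANK,
) -> ITDClone:
    """Construct the clone a given duplication would produce (e.g. from a
    simulator truth record)."""
    seq = reference.sequence
    site = canonical_site(seq, itd_length, insertion_site)
    if site - itd_length < 0:
        raise ValueError("duplicated unit would start before the amplicon")
    unit = seq[site - itd_length : site]
    mutant = seq[:site] + unit + seq[site:]
    sig = mutant[site - k_flank : site + k_flank]
    if sig in seq:
        raise ValueError("junction signature occurs on the wild-type amplicon")
    return ITDClone(
        itd_length=itd_length,
        insertion_site=site,
        junction_signature=sig,
        duplicated_seq=unit,
    )


def _lcp_len(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(n):
        if a[i] != b[i]:
            return i
    return n


def discover_clones(
    merged_reads: Iterable[MergedRead],
    reference: AmpliconReference,
    min_period: int = DEFAULT_MIN_PERIOD,
    max_period: int = DEFAULT_MAX_PERIOD,
    resolution: int = DEFAULT_RESOLUTION,
    min_support: int = DEFAULT_MIN_SUPPORT,
    k_flank: int = DEFAULT_K_FLANK,
    anchor_len: int = DEFAULT_ANCHOR_LEN,
    min_copies: float = DEFAULT_MIN_COPIES,
) -> tuple[list[ITDClone], dict]:
    """Pool per-read tandem repeats into reference-anchored ITD clones.

    Returns the clones (descending read support) and a tally dict of why
    reads were or were not informative.
    """
    ref = reference.sequence
    lo, hi = reference.itd_window
    tallies = Counter()
    pools: dict[tuple[int, int], Counter] = defaultdict(Counter)
    dups: dict[tuple[int, int], Counter] = defaultdict(Counter)

    for read in merged_reads:
        tallies["reads"] += 1
        seq = read.seq
        reps = [
            r
            for r in find_tandem_repeats(seq, min_period, max_period, resolution)
            if r.copies >= min_copies
        ]
        rep = best_repeat(reps)
        if rep is None:
            tallies["no_repeat"] += 1
            continue
        p = rep.period
        if len(seq) < 2 * anchor_len:
            tallies["too_short"] += 1
            continue
        o1 = ref.find(seq[:anchor_len])
        if o1 < 0:
            tallies["unanchored"] += 1
            continue
        # Tail anchor: for a clean ITD read the read maps p bases further
        # left on the reference than its length suggests.
        tail_at = o1 + len(seq) - p - anchor_len
        if tail_at < 0 or ref[tail_at : tail_at + anchor_len] != seq[-anchor_len:]:
            tallies["unanchored"] += 1
            continue
        # Right-most junction from the longest common prefix, then
        # canonicalize to the left-most equivalent site.
        site = canonical_site(ref, p, o1 + _lcp_len(seq, ref[o1:]))
        if not (lo <= site < hi):
            tallies["outside_window"] += 1
            continue
        jr = site - o1  # junction position in read coordinates
        if jr - k_flank < 0 or jr + k_flank > len(seq) or jr - p < 0 or jr + p > len(seq):
            tallies["junction_unflanked"] += 1
            continue
        if hamming(seq[jr - p : jr], seq[jr : jr + p]) > resolution:
            tallies["inconsistent_repeat"] += 1
            continue
        sig = seq[jr - k_flank : jr + k_flank]
        if sig in ref:
            tallies["signature_in_reference"] += 1
            continue
        tallies["itd_reads"] += 1
        pools[(p, site)][sig] += 1
        dups[(p, site)][seq[jr : jr + p]] += 1

    clones: list[ITDClone] = []
    for (p, site), sigs in pools.items():
        majority = min(sigs, key=lambda s: (-sigs[s], s))
        support = sum(c for s, c in sigs.items() if hamming(s, majority) <= 1)
        tallies["signature_outliers"] += sum(sigs.values()) - support
        if support < min_support:
            tallies["below_min_support"] += sum(sigs.values())
            continue
        dup = min(dups[(p, site)], key=lambda s: (-dups[(p, site)][s], s))
        clones.append(
            ITDClone(
                itd_length=p,
                insertion_site=site,
                junction_signature=majority,
                duplicated_seq=dup,
                support=support,
            )
        )
    clones.sort(key=lambda c: (-c.support, c.itd_length, c.insertion_site))
    return clones, dict(tallies)


def count_breakpoints(
    merged_reads: Sequence[MergedRead],
    clone: ITDClone,
    reference: AmpliconReference,
    sample_id: str = "",
) -> CloneCounts:
    """Count ITD-junction and WT-breakpoint reads among merged reads.

    A read counts at most once per signature; reads carrying the junction
    are excluded from the WT tally (see module docstring).
    """
    ref = reference.sequence
    if clone.junction_signature in ref:
        raise ValueError(
            f"clone {clone.clone_id}: junction signature occurs on the reference"
        )
    k = len(clone.junction_signature) // 2
    wt = wt_signature(reference, clone.insertion_site, k).signature
    itd = 0
    wt_n = 0
    total = 0
    for read in merged_reads:
        total += 1
        if clone.junction_signature in read.seq:
            itd += 1
        elif wt in read.seq:
            wt_n += 1
    return CloneCounts(
        sample_id=sample_id,
        clone=clone,
        itd_reads=itd,
        wt_reads=wt_n,
        total_merged=total,
    )


def _rows_containing(flat: bytes, row_len: int, pattern: bytes) -> set[int]:
    """Row indices of a flattened fixed-width read matrix containing a
    pattern; matches straddling row boundaries are rejected."""
    rows: set[int] = set()
    w = len(pattern)
    pos = flat.find(pattern)
    while pos != -1:
        r, off = divmod(pos, row_len)
        if off + w <= row_len:
            rows.add(r)
        pos = flat.find(pattern, pos + 1)
    return rows


def count_breakpoints_flat(
    flat1: bytes,
    flat2: bytes,
    n_pairs: int,
    read_len: int,
    clone: ITDClone,
    reference: AmpliconReference,
    sample_id: str = "",
) -> CloneCounts:
    """Junction-signature fast path: count breakpoints on raw mate pairs.

    Signatures (2*k_flank bases, 24 by default) always fit inside one
    mate, so very deep samples can be counted without merging; mate 2 is
    searched for the reverse complement. Each pair counts once per
    signature; ``total`` is the pair count.
    """
    ref = reference.sequence
    if clone.junction_signature in ref:
        raise ValueError(
            f"clone {clone.clone_id}: junction signature occurs on the reference"
        )
    k = len(clone.junction_signature) // 2
    wt = wt_signature(reference, clone.insertion_site, k).signature
    jsig = clone.junction_signature
    itd_rows = _rows_containing(flat1, read_len, jsig.encode()) | _rows_containing(
        flat2, read_len, revcomp(jsig).encode()
    )
    wt_rows = (
        _rows_containing(flat1, read_len, wt.encode())
        | _rows_containing(flat2, read_len, revcomp(wt).encode())
    ) - itd_rows
    return CloneCounts(
        sample_id=sample_id,
        clone=clone,
        itd_reads=len(itd_rows),
        wt_reads=len(wt_rows),
        total_merged=n_pairs,
    )


def count_breakpoints_pairs(
    pairs: Iterable[ReadPair],
    clone: ITDClone,
    reference: AmpliconReference,
    sample_id: str = "",
) -> CloneCounts:
    """Fast-path counting over a stream of ReadPairs (e.g. from FASTQ)."""
    ref = reference.sequence
    if clone.junction_signature in ref:
        raise ValueError(
            f"clone {clone.clone_id}: junction signature occurs on the reference"
        )
    k = len(clone.junction_signature) // 2
    wt = wt_signature(reference, clone.insertion_site, k).signature
    jsig = clone.junction_signature
    jsig_rc = revcomp(jsig)
    wt_rc = revcomp(wt)
    itd = 0
    wt_n = 0
    total = 0
    for pair in pairs:
        total += 1
        if jsig in pair.seq1 or jsig_rc in pair.seq2:
            itd += 1
        elif wt in pair.seq1 or wt_rc in pair.seq2:
            wt_n += 1
    return CloneCounts(
        sample_id=sample_id,
        clone=clone,
        itd_reads=itd,
        wt_reads=wt_n,
        total_merged=total,
    )
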