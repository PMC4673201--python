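"""Reproducible validation experiments for the whole pipeline.

These functions regenerate, from scratch and at full scale, the studies
that characterize the method on synthetic data with known truth:

* a serial-dilution ladder of a strongly positive sample into a negative
  background, establishing the detection limit and the linearity of the
  estimated ITD/WT ratio;
* exact recovery of duplication length and insertion site across the
  biologically observed ITD size range;
* the fragmentation failure mode (a duplication too long for any read to
  span is never called);
* the false-positive rate of the Fisher positivity call over a cohort of
  negative samples.

Each function takes an explicit seed and is deterministic given it.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .amplicon_io import AmpliconReference
from .calling import (
    clone_from_reference,
    count_breakpoints_flat,
    discover_clones,
)
from .merging import merge_pairs
from .simulate import (
    CloneSpec,
    SimConfig,
    child_seed,
    dilution_series,
    simulate_sample,
    synthetic_reference,
)
from .stats import fisher_positivity, compute_sensitivity

#: Allele fraction whose allele-level ITD/WT odds are 1.19 (f / (1 - f)),
#: matching a diagnosis sample with an ITD/WT ratio x 100 of 119%.
SOURCE_ALLELE_FRACTION = 1.19 / 2.19

DEFAULT_DILUTIONS = (1e-1, 1e-2, 1e-3, 1e-4)
TABLE_ITD_LENGTHS = (15, 21, 39, 48, 60, 75, 90)


@dataclass
class DilutionResult:
    clone_length: int
    clone_site: int
    source_itd_reads: int
    source_wt_reads: int
    source_ratio: float
    dilutions: list[float] = field(default_factory=list)
    itd_reads: list[int] = field(default_factory=list)
    wt_reads: list[int] = field(default_factory=list)
    ratios: list[float] = field(default_factory=list)
    p_values: list[float] = field(default_factory=list)
    positive: list[bool] = field(default_factory=list)
    min_detectable_ratio: list[float | None] = field(default_factory=list)
    slope: float = math.nan
    n_pairs: int = 0

    @property
    def detected_inverse_limit(self) -> int:
        """Largest 1/d still called positive (0 when nothing is)."""
        inv = [round(1 / d) for d, pos in zip(self.dilutions, self.positive) if pos]
        return max(inv, default=0)


def dilution_experiment(
    seed: int,
    n_pairs: int = 1_000_000,
    dilutions: tuple[float, ...] = DEFAULT_DILUTIONS,
    itd_length: int = 48,
    insertion_site: int = 200,
    allele_fraction: float = SOURCE_ALLELE_FRACTION,
    error_rate: float = 1e-3,
    discovery_pairs: int = 3000,
    alpha: float = 0.05,
    reference: AmpliconReference | None = None,
) -> DilutionResult:
    """Serial dilution of a positive diagnosis sample into a negative
    background, at follow-up depth.

    The clone is discovered de novo on a merged subsample of the source,
    then each dilution is counted with the junction-signature fast path
    and tested against the in-run negative control (another patient).
    """
    ref = reference or synthetic_reference()
    source_cfg = SimConfig(
        reference=ref,
        clones=[CloneSpec(itd_length, insertion_site, allele_fraction)],
        n_pairs=n_pairs,
        substitution_error_rate=error_rate,
        seed=child_seed(seed, 0),
    )
    source = simulate_sample(source_cfg, "source")

    merged, _ = merge_pairs(source.iter_pairs(limit=discovery_pairs))
    clones, _ = discover_clones(merged, ref)
    if not clones:
        raise RuntimeError("no clone discovered in the source sample")
    clone = clones[0]
    truth = clone_from_reference(ref, itd_length, insertion_site)
    if (clone.itd_length, clone.insertion_site) != (
        truth.itd_length,
        truth.insertion_site,
    ):
        raise RuntimeError(
            f"discovered {clone.clone_id}, expected {truth.clone_id}"
        )

    src_counts = count_breakpoints_flat(
        source.flat1, source.flat2, source.n_pairs, source_cfg.read_length,
        clone, ref, "source",
    )
    res = DilutionResult(
        clone_length=clone.itd_length,
        clone_site=clone.insertion_site,
        source_itd_reads=src_counts.itd_reads,
        source_wt_reads=src_counts.wt_reads,
        source_ratio=src_counts.itd_reads / src_counts.wt_reads,
        n_pairs=n_pairs,
    )
    del source

    negative_cfg = SimConfig(
        reference=ref,
        clones=[],
        n_pairs=n_pairs,
        substitution_error_rate=error_rate,
        seed=child_seed(seed, 1),
    )
    negative = simulate_sample(negative_cfg, "negative")
    neg_counts = count_breakpoints_flat(
        negative.flat1, negative.flat2, negative.n_pairs,
        negative_cfg.read_length, clone, ref, "negative",
    )
    del negative

    for d, cfg in dilution_series(source_cfg, list(dilutions)):
        sample = simulate_sample(cfg, f"dil_{d:g}")
        cc = count_breakpoints_flat(
            sample.flat1, sample.flat2, sample.n_pairs, cfg.read_length,
            clone, ref, sample.sample_id,
        )
        del sample
        pos = fisher_positivity(
            cc, neg_counts.itd_reads, neg_counts.total_merged, alpha=alpha
        )
        mdr = compute_sensitivity(
            cc.total_merged, cc.wt_reads, neg_counts.itd_reads,
            neg_counts.total_merged, alpha=alpha,
        )
        res.dilutions.append(d)
        res.itd_reads.append(cc.itd_reads)
        res.wt_reads.append(cc.wt_reads)
        res.ratios.append(cc.itd_reads / cc.wt_reads if cc.wt_reads else math.nan)
        res.p_values.append(pos.p_value)
        res.positive.append(pos.positive)
        res.min_detectable_ratio.append(mdr)

    usable = [
        (math.log10(d), math.log10(r))
        for d, r, k in zip(res.dilutions, res.ratios, res.itd_reads)
        if k > 0 and r > 0
    ]
    if len(usable) >= 2:
        x, y = zip(*usable)
        res.slope = float(np.polyfit(x, y, 1)[0])
    return res


@dataclass
class RecoveryResult:
    lengths: tuple[int, ...]
    replicates: int
    n_exact_length: int = 0
    n_exact_site: int = 0
    n_total: int = 0

    @property
    def length_recovery(self) -> float:
        return self.n_exact_length / self.n_total

    @property
    def site_recovery(self) -> float:
        return self.n_exact_site / self.n_total


def length_site_recovery(
    seed: int,
    lengths: tuple[int, ...] = TABLE_ITD_LENGTHS,
    replicates: int = 15,
    n_pairs: int = 400,
    allele_fraction: float = 0.5,
    error_rate: float = 1e-3,
    reference: AmpliconReference | None = None,
) -> RecoveryResult:
    """Exact duplication length/site recovery across the observed ITD size
    range, with random insertion sites per replicate.

    Sites are drawn so the full duplication plus its anchors fits inside
    the amplicon with a read-length margin on both sides — discovery
    requires a read spanning both copies, so a duplication jammed against
    a primer is geometrically undetectable regardless of depth (the same
    containment constraint behind the long-ITD failure mode).
    """
    ref = reference or synthetic_reference()
    lo, hi = ref.itd_window
    rng = np.random.default_rng(child_seed(seed, 100))
    res = RecoveryResult(lengths=tuple(lengths), replicates=replicates)
    pad = 20  # anchor length
    for length in lengths:
        site_lo = max(lo + 1, length + pad)
        site_hi = min(hi - 1, len(ref) - length - pad)
        for rep in range(replicates):
            site = int(rng.integers(site_lo, site_hi))
            cfg = SimConfig(
                reference=ref,
                clones=[CloneSpec(length, site, allele_fraction)],
                n_pairs=n_pairs,
                substitution_error_rate=error_rate,
                seed=int(rng.integers(0, 2**31)),
            )
            sample = simulate_sample(cfg, f"rec{length}_{rep}")
            merged, _ = merge_pairs(sample.iter_pairs())
            clones, _ = discover_clones(merged, ref)
            res.n_total += 1
            if clones and clones[0].itd_length == length:
                res.n_exact_length += 1
                if clones[0].insertion_site == cfg.clones[0].insertion_site:
                    res.n_exact_site += 1
    return res


def fragmentation_cliff(
    seed: int,
    itd_length: int = 183,
    insertion_site: int = 290,
    n_pairs: int = 3000,
    allele_fraction: float = 0.5,
    reference: AmpliconReference | None = None,
) -> int:
    """Clone calls for a duplication longer than any sequenced fragment
    can span (expected: zero, the tagmentation failure mode)."""
    ref = reference or synthetic_reference()
    cfg = SimConfig(
        reference=ref,
        clones=[CloneSpec(itd_length, insertion_site, allele_fraction)],
        n_pairs=n_pairs,
        substitution_error_rate=0.0,
        seed=child_seed(seed, 200),
    )
    sample = simulate_sample(cfg, "longitd")
    merged, _ = merge_pairs(sample.iter_pairs())
    clones, _ = discover_clones(merged, ref)
    return len(clones)


@dataclass
class FprResult:
    n_samples: int
    n_positive: int
    alpha: float

    @property
    def rate(self) -> float:
        return self.n_positive / self.n_samples


def negative_cohort_fpr(
    seed: int,
    n_samples: int = 500,
    n_pairs: int = 1000,
    error_rate: float = 1e-3,
    alpha: float = 0.05,
    itd_length: int = 48,
    insertion_site: int = 200,
    reference: AmpliconReference | None = None,
) -> FprResult:
    """Type-I control: Fisher positivity rate across a cohort of negative
    samples, each tested against the pooled remainder of the cohort."""
    ref = reference or synthetic_reference()
    clone = clone_from_reference(ref, itd_length, insertion_site)
    counts = []
    for i in range(n_samples):
        cfg = SimConfig(
            reference=ref,
            clones=[],
            n_pairs=n_pairs,
            substitution_error_rate=error_rate,
            seed=child_seed(seed, 300 + i),
        )
        s = simulate_sample(cfg, f"neg{i}")
        counts.append(
            count_breakpoints_flat(
                s.flat1, s.flat2, s.n_pairs, cfg.read_length, clone, ref, f"neg{i}"
            )
        )
    total_itd = sum(c.itd_reads for c in counts)
    total_reads = sum(c.total_merged for c in counts)
    n_pos = 0
    for c in counts:
        pos = fisher_positivity(
            c, total_itd - c.itd_reads, total_reads - c.total_merged, alpha=alpha
        )
        n_pos += bool(pos.positive)
    return FprResult(n_samples=n_samples, n_positive=n_pos, alpha=alpha)
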