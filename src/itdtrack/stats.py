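"""MRD statistics: ratios, Fisher-exact positivity, per-sample sensitivity
and longitudinal log-reduction timelines.

The ITD/WT ratio is the number of reads carrying the ITD junction
breakpoint divided by the number carrying the wild-type breakpoint; it
can exceed 1 when the mutant allele outnumbers the wild type. Positivity
is a one-sided Fisher exact test of the sample's junction-read rate
against the pooled rate in the same run's control samples (samples from
other patients) — low-level cross-sample contamination thus raises the
bar rather than producing false positives. Per-sample sensitivity is the
smallest ratio that would still test positive at the sample's depth.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

from scipy.stats import fisher_exact

from .calling import CloneCounts, ITDClone

DEFAULT_ALPHA = 0.05
DEFAULT_MIN_SUPPORT_FLOOR = 5


def compute_ratio(counts: CloneCounts) -> float:
    """ITD reads / WT reads. Returns inf (with a warning) when only ITD
    reads were seen, and nan when neither breakpoint was covered."""
    if counts.wt_reads == 0:
        if counts.itd_reads == 0:
            return math.nan
        warnings.warn(
            f"{counts.sample_id}: {counts.itd_reads} ITD reads but no WT "
            "breakpoint reads; ratio is infinite",
            stacklevel=2,
        )
        return math.inf
    return counts.itd_reads / counts.wt_reads


@dataclass(frozen=True)
class PositivityResult:
    sample_id: str
    clone: ITDClone
    p_value: float
    positive: bool
    alpha: float
    min_detectable_ratio: float | None = None
    control_itd: int = 0
    control_total: int = 0
    note: str = ""


def _fisher_greater(a: int, total_a: int, c: int, total_c: int) -> float:
    """One-sided (sample rate greater) Fisher exact p-value for the table
    [[a, total_a - a], [c, total_c - c]]."""
    table = [[a, total_a - a], [c, total_c - c]]
    return float(fisher_exact(table, alternative="greater")[1])


def fisher_positivity(
    sample: CloneCounts,
    control_itd: int,
    control_total: int,
    alpha: float = DEFAULT_ALPHA,
    min_support_floor: int = DEFAULT_MIN_SUPPORT_FLOOR,
) -> PositivityResult:
    """Call a sample positive for a clone against pooled in-run controls.

    ``control_itd``/``control_total`` are the clone's junction-read count
    and read total pooled over the other patients' samples in the same
    run. With no control depth at all (single-patient run) the call falls
    back to requiring ``min_support_floor`` junction reads, flagged in
    the result's note.
    """
    if control_total <= 0:
        positive = sample.itd_reads >= min_support_floor
        return PositivityResult(
            sample_id=sample.sample_id,
            clone=sample.clone,
            p_value=math.nan,
            positive=positive,
            alpha=alpha,
            control_itd=0,
            control_total=0,
            note=(
                "no in-run control depth; positivity floor of "
                f"{min_support_floor} junction reads applied"
            ),
        )
    p = _fisher_greater(sample.itd_reads, sample.total_merged, control_itd, control_total)
    return PositivityResult(
        sample_id=sample.sample_id,
        clone=sample.clone,
        p_value=p,
        positive=p < alpha,
        alpha=alpha,
        control_itd=control_itd,
        control_total=control_total,
    )


def min_positive_itd_reads(
    sample_total: int,
    control_itd: int,
    control_total: int,
    alpha: float = DEFAULT_ALPHA,
) -> int | None:
    """Smallest junction-read count that tests positive at this depth.

    The one-sided p-value is non-increasing in the count at fixed totals,
    so an exponential search bracketing followed by bisection equals the
    exhaustive scan.
    """
    if sample_total <= 0 or control_total <= 0:
        return None
    if _fisher_greater(sample_total, sample_total, control_itd, control_total) >= alpha:
        return None  # not even an all-ITD sample would be called
    hi = 1
    while _fisher_greater(hi, sample_total, control_itd, control_total) >= alpha:
        hi = min(hi * 2, sample_total)
    lo = hi // 2  # p(lo) >= alpha (or lo == 0)
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if _fisher_greater(mid, sample_total, control_itd, control_total) < alpha:
            hi = mid
        else:
            lo = mid
    return hi


def compute_sensitivity(
    sample_total: int,
    wt_denominator: int,
    control_itd: int,
    control_total: int,
    alpha: float = DEFAULT_ALPHA,
) -> float | None:
    """Minimal detectable ITD/WT ratio at this sample's depth.

    ``wt_denominator`` is the sample's WT-breakpoint read count (the
    ratio's denominator), which is observable even in negative samples.
    Returns None when the sample has no depth or no WT coverage.
    """
    k = min_positive_itd_reads(sample_total, control_itd, control_total, alpha)
    if k is None or wt_denominator <= 0:
        return None
    return k / wt_denominator


@dataclass(frozen=True)
class TimelinePoint:
    timepoint: int
    role: str
    itd_reads: int
    wt_reads: int
    ratio: float
    positive: bool
    p_value: float
    min_detectable_ratio: float | None
    log_reduction: float | None  # None: baseline, or below sensitivity


@dataclass(frozen=True)
class MRDTimeline:
    """Per-patient, per-clone trajectory of the ITD/WT ratio.

    ``emergent`` flags clones not called at diagnosis but positive later
    (mutational shift); ``lost`` flags diagnosis-positive clones that are
    negative at the last assessed timepoint.
    """

    patient_id: str
    clone: ITDClone
    points: tuple[TimelinePoint, ...]
    baseline_ratio: float
    emergent: bool
    lost: bool

    @property
    def log_reductions(self) -> list[float | None]:
        return [p.log_reduction for p in self.points]


def build_timeline(
    patient_id: str,
    clone: ITDClone,
    observations: Sequence[tuple[int, str, CloneCounts, PositivityResult]],
) -> MRDTimeline:
    """Assemble a clone's MRD trajectory from per-timepoint counts.

    ``observations`` are (timepoint, role, counts, positivity) tuples; a
    diagnosis timepoint must be present and provides the baseline ratio.
    Follow-up points with zero junction reads carry no log reduction
    (they are below the sample's sensitivity, not measured zeros).
    """
    obs = sorted(observations, key=lambda o: o[0])
    diag = [o for o in obs if o[1] == "diagnosis"]
    if not diag:
        raise ValueError(f"patient {patient_id}: no diagnosis timepoint")
    baseline_tp = diag[0][0]
    baseline_ratio = compute_ratio(diag[0][2])

    points = []
    for tp, role, counts, pos in obs:
        ratio = compute_ratio(counts)
        if tp == baseline_tp and role == "diagnosis":
            lr = None
        elif counts.itd_reads == 0 or not math.isfinite(ratio) or ratio <= 0:
            lr = None
        elif not math.isfinite(baseline_ratio) or baseline_ratio <= 0:
            lr = None
        else:
            lr = math.log10(baseline_ratio / ratio)
        points.append(
            TimelinePoint(
                timepoint=tp,
                role=role,
                itd_reads=counts.itd_reads,
                wt_reads=counts.wt_reads,
                ratio=ratio,
                positive=pos.positive,
                p_value=pos.p_value,
                min_detectable_ratio=pos.min_detectable_ratio,
                log_reduction=lr,
            )
        )

    baseline_positive = next(
        p.positive for p in points if p.timepoint == baseline_tp and p.role == "diagnosis"
    )
    later = [p for p in points if p.timepoint > baseline_tp]
    emergent = (not baseline_positive) and any(p.positive for p in later)
    lost = baseline_positive and bool(later) and not later[-1].positive
    return MRDTimeline(
        patient_id=patient_id,
        clone=clone,
        points=tuple(points),
        baseline_ratio=baseline_ratio,
        emergent=emergent,
        lost=lost,
    )


def plot_timelines(timelines: Sequence[MRDTimeline], path) -> None:
    """Per-clone log10 ratio trajectories; points below sensitivity are
    drawn as open markers at the sample's minimal detectable ratio."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for tl in timelines:
        xs, ys = [], []
        for p in tl.points:
            if p.itd_reads > 0 and math.isfinite(p.ratio) and p.ratio > 0:
                xs.append(p.timepoint)
                ys.append(math.log10(p.ratio))
        label = f"{tl.patient_id} {tl.clone.clone_id}"
        (line,) = ax.plot(xs, ys, marker="o", label=label)
        neg = [
            (p.timepoint, p.min_detectable_ratio)
            for p in tl.points
            if p.itd_reads == 0 and p.min_detectable_ratio
        ]
        if neg:
            ax.plot(
                [t for t, _ in neg],
                [math.log10(r) for _, r in neg],
                marker="v",
                linestyle="none",
                markerfacecolor="none",
                color=line.get_color(),
            )
    ax.set_xlabel("timepoint")
    ax.set_ylabel("log10(ITD/WT ratio)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
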