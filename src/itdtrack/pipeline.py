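"""Run-level orchestration: merge -> repeat finding -> clone discovery ->
breakpoint counting -> Fisher positivity, plus cross-run MRD timelines.

Clone discovery only ever sees diagnosis-role samples; follow-up samples
are counted against the discovered catalog but never nominate clones,
mirroring the separation of diagnosis and follow-up sequencing runs.
Controls for the Fisher test are the pooled counts over the same run's
samples from *other* patients.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import calling, merging, stats
from .amplicon_io import (
    AmpliconReference,
    RunManifest,
    SampleEntry,
    read_fastq_pair,
)
from .calling import CloneCounts, ITDClone, same_clone


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class DetectParams:
    min_overlap: int = merging.DEFAULT_MIN_OVERLAP
    max_mismatch_frac: float = merging.DEFAULT_MAX_MISMATCH_FRAC
    min_period: int = calling.DEFAULT_MIN_PERIOD
    max_period: int = calling.DEFAULT_MAX_PERIOD
    resolution: int = calling.DEFAULT_RESOLUTION
    min_support: int = calling.DEFAULT_MIN_SUPPORT
    k_flank: int = calling.DEFAULT_K_FLANK
    anchor_len: int = calling.DEFAULT_ANCHOR_LEN
    alpha: float = stats.DEFAULT_ALPHA
    bonferroni: bool = False
    max_discovery_reads: int = 8000
    counting: str = "merged"  # or "pairs" (junction-signature fast path)
    dump_repeats: bool = False  # debug: per-read repeat calls TSV


def save_params(params: DetectParams, path: str | Path) -> None:
    with open(path, "w") as h:
        yaml.safe_dump(asdict(params), h, sort_keys=False)


def load_params(path: str | Path) -> DetectParams:
    """Load stage parameters from YAML; round-trips :func:`save_params`
    losslessly and rejects unknown keys."""
    with open(path) as h:
        doc = yaml.safe_load(h) or {}
    known = {f.name for f in DetectParams.__dataclass_fields__.values()}
    unknown = set(doc) - known
    if unknown:
        raise ValueError(f"{path}: unknown parameter(s) {sorted(unknown)}")
    return DetectParams(**doc)


@dataclass
class DetectResult:
    run_id: str
    catalog: list[ITDClone]
    report: pd.DataFrame
    qc: dict
    log: list[dict] = field(default_factory=list)
    repeat_calls: pd.DataFrame | None = None  # debug dump

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        if self.repeat_calls is not None:
            self.repeat_calls.to_csv(outdir / "repeat_calls.tsv", sep="\t", index=False)
        cat = pd.DataFrame(
            [
                {
                    "clone_id": c.clone_id,
                    "itd_length": c.itd_length,
                    "insertion_site": c.insertion_site,
                    "junction_signature": c.junction_signature,
                    "duplicated_seq": c.duplicated_seq,
                    "support": c.support,
                }
                for c in self.catalog
            ]
        )
        cat.to_csv(outdir / "clone_catalog.tsv", sep="\t", index=False)
        self.report.to_csv(outdir / "mrd_report.tsv", sep="\t", index=False)
        self.report.to_json(outdir / "mrd_report.json", orient="records", indent=2)
        with open(outdir / "qc.json", "w") as h:
            json.dump(self.qc, h, indent=2)
        with open(outdir / "log.jsonl", "w") as h:
            for entry in self.log:
                h.write(json.dumps(entry) + "\n")


def _merge_catalogs(per_sample: list[list[ITDClone]]) -> list[ITDClone]:
    catalog: list[ITDClone] = []
    for clones in per_sample:
        for c in clones:
            match = next((i for i, k in enumerate(catalog) if same_clone(k, c)), None)
            if match is None:
                catalog.append(c)
            else:
                kept = catalog[match]
                rep = kept if kept.support >= c.support else c
                catalog[match] = ITDClone(
                    itd_length=rep.itd_length,
                    insertion_site=rep.insertion_site,
                    junction_signature=rep.junction_signature,
                    duplicated_seq=rep.duplicated_seq,
                    support=kept.support + c.support,
                )
    catalog.sort(key=lambda c: (-c.support, c.itd_length, c.insertion_site))
    return catalog


def load_catalog(path: str | Path) -> list[ITDClone]:
    """Read a clone catalog TSV written by :meth:`DetectResult.write`."""
    df = pd.read_csv(path, sep="\t")
    return [
        ITDClone(
            itd_length=int(r["itd_length"]),
            insertion_site=int(r["insertion_site"]),
            junction_signature=str(r["junction_signature"]),
            duplicated_seq=str(r["duplicated_seq"]),
            support=int(r["support"]),
        )
        for _, r in df.iterrows()
    ]


def detect_run(
    reference: AmpliconReference,
    manifest: RunManifest,
    params: DetectParams | None = None,
    fastq_root: str | Path | None = None,
    catalog: list[ITDClone] | None = None,
) -> DetectResult:
    """Full detection pass over one sequencing run.

    ``catalog`` supplies clones discovered elsewhere (the diagnosis run)
    so that follow-up runs, which contribute no reads to discovery, can
    still be counted against them.
    """
    params = params or DetectParams()
    root = Path(fastq_root) if fastq_root else None
    log: list[dict] = []
    qc: dict = {}

    def fastq_paths(s: SampleEntry) -> tuple[Path, Path]:
        p1, p2 = Path(s.fastq1), Path(s.fastq2)
        if root is not None:
            p1 = p1 if p1.is_absolute() else root / p1
            p2 = p2 if p2.is_absolute() else root / p2
        return p1, p2

    # Stage 1: merge (+ discovery on diagnosis samples).
    merged_by_sample: dict[str, list] = {}
    per_sample_clones: list[list[ITDClone]] = []
    repeat_rows: list[dict] = []
    for s in manifest.samples:
        p1, p2 = fastq_paths(s)
        try:
            cap = params.max_discovery_reads if params.counting == "pairs" else None
            merged, mqc = merging.merge_pairs(
                read_fastq_pair(p1, p2),
                params.min_overlap,
                params.max_mismatch_frac,
                max_pairs=cap,
            )
        except (OSError, ValueError) as e:
            raise PipelineError("merge", f"sample {s.sample_id}: {e}") from e
        merged_by_sample[s.sample_id] = merged
        qc[s.sample_id] = {"merge": mqc}
        log.append({"stage": "merge", "sample": s.sample_id, **mqc})
        if s.role == "diagnosis":
            try:
                clones, tallies = calling.discover_clones(
                    merged[: params.max_discovery_reads],
                    reference,
                    min_period=params.min_period,
                    max_period=params.max_period,
                    resolution=params.resolution,
                    min_support=params.min_support,
                    k_flank=params.k_flank,
                    anchor_len=params.anchor_len,
                )
            except ValueError as e:
                raise PipelineError("discover", f"sample {s.sample_id}: {e}") from e
            per_sample_clones.append(clones)
            if params.dump_repeats:
                from .repeats import find_tandem_repeats

                for read in merged[: params.max_discovery_reads]:
                    for rep in find_tandem_repeats(
                        read.seq, params.min_period, params.max_period, params.resolution
                    ):
                        repeat_rows.append(
                            {
                                "sample_id": s.sample_id,
                                "read_id": read.read_id,
                                "start": rep.start,
                                "period": rep.period,
                                "span": rep.span,
                                "mismatches": rep.mismatches,
                            }
                        )
            qc[s.sample_id]["discovery"] = tallies
            log.append(
                {
                    "stage": "discover",
                    "sample": s.sample_id,
                    "clones": [c.clone_id for c in clones],
                    **tallies,
                }
            )

    if catalog:
        per_sample_clones.append(list(catalog))
    catalog = _merge_catalogs(per_sample_clones)
    log.append({"stage": "catalog", "clones": [c.clone_id for c in catalog]})

    # Stage 2: breakpoint counting for every sample x clone.
    counts: dict[tuple[str, str], CloneCounts] = {}
    for s in manifest.samples:
        for clone in catalog:
            try:
                if params.counting == "pairs":
                    p1, p2 = fastq_paths(s)
                    cc = calling.count_breakpoints_pairs(
                        read_fastq_pair(p1, p2), clone, reference, s.sample_id
                    )
                else:
                    cc = calling.count_breakpoints(
                        merged_by_sample[s.sample_id], clone, reference, s.sample_id
                    )
            except (OSError, ValueError) as e:
                raise PipelineError("count", f"sample {s.sample_id}: {e}") from e
            counts[(s.sample_id, clone.clone_id)] = cc
            log.append(
                {
                    "stage": "count",
                    "sample": s.sample_id,
                    "clone": clone.clone_id,
                    "itd_reads": cc.itd_reads,
                    "wt_reads": cc.wt_reads,
                    "total": cc.total_merged,
                }
            )

    # Stage 3: Fisher positivity against pooled other-patient controls.
    alpha = params.alpha / max(len(catalog), 1) if params.bonferroni else params.alpha
    rows = []
    for s in manifest.samples:
        for clone in catalog:
            cc = counts[(s.sample_id, clone.clone_id)]
            others = [
                counts[(o.sample_id, clone.clone_id)]
                for o in manifest.samples
                if o.patient_id != s.patient_id
            ]
            ctrl_itd = sum(o.itd_reads for o in others)
            ctrl_total = sum(o.total_merged for o in others)
            pos = stats.fisher_positivity(cc, ctrl_itd, ctrl_total, alpha=alpha)
            sens = stats.compute_sensitivity(
                cc.total_merged,
                cc.wt_reads,
                ctrl_itd,
                ctrl_total,
                alpha=alpha,
            )
            rows.append(
                {
                    "run_id": manifest.run_id,
                    "sample_id": s.sample_id,
                    "patient_id": s.patient_id,
                    "timepoint": s.timepoint,
                    "role": s.role,
                    "clone_id": clone.clone_id,
                    "itd_length": clone.itd_length,
                    "insertion_site": clone.insertion_site,
                    "itd_reads": cc.itd_reads,
                    "wt_reads": cc.wt_reads,
                    "total_reads": cc.total_merged,
                    "ratio": stats.compute_ratio(cc) if cc.itd_reads or cc.wt_reads else math.nan,
                    "p_value": pos.p_value,
                    "positive": pos.positive,
                    "min_detectable_ratio": sens,
                    "control_itd": ctrl_itd,
                    "control_total": ctrl_total,
                    "note": pos.note,
                }
            )
    report = pd.DataFrame(
        rows,
        columns=[
            "run_id", "sample_id", "patient_id", "timepoint", "role",
            "clone_id", "itd_length", "insertion_site", "itd_reads",
            "wt_reads", "total_reads", "ratio", "p_value", "positive",
            "min_detectable_ratio", "control_itd", "control_total", "note",
        ],
    )
    return DetectResult(
        run_id=manifest.run_id,
        catalog=catalog,
        report=report,
        qc=qc,
        log=log,
        repeat_calls=pd.DataFrame(repeat_rows) if params.dump_repeats else None,
    )


def _clone_from_row(row) -> ITDClone:
    return ITDClone(
        itd_length=int(row["itd_length"]),
        insertion_site=int(row["insertion_site"]),
        junction_signature="",
        duplicated_seq="",
    )


def mrd_timelines(reports: list[pd.DataFrame]) -> tuple[list[stats.MRDTimeline], pd.DataFrame]:
    """Cross-run MRD timelines from detect reports.

    Rows are matched into per-patient, per-clone trajectories by
    (itd_length, insertion_site); a patient without a diagnosis row is an
    error. Returns the timeline objects and a flat report table.
    """
    df = pd.concat(reports, ignore_index=True)
    if df.empty:
        raise PipelineError("mrd", "no detect report rows")
    timelines = []
    rows = []
    for (patient, length, site), grp in df.groupby(
        ["patient_id", "itd_length", "insertion_site"], sort=True
    ):
        obs = []
        for _, r in grp.sort_values("timepoint").iterrows():
            clone = _clone_from_row(r)
            cc = CloneCounts(
                sample_id=r["sample_id"],
                clone=clone,
                itd_reads=int(r["itd_reads"]),
                wt_reads=int(r["wt_reads"]),
                total_merged=int(r["total_reads"]),
            )
            mdr = r["min_detectable_ratio"]
            pos = stats.PositivityResult(
                sample_id=r["sample_id"],
                clone=clone,
                p_value=float(r["p_value"]),
                positive=bool(r["positive"]),
                alpha=math.nan,
                min_detectable_ratio=None if pd.isna(mdr) else float(mdr),
            )
            obs.append((int(r["timepoint"]), str(r["role"]), cc, pos))
        if not any(role == "diagnosis" for _, role, _, _ in obs):
            continue  # background/control patients have no timeline
        tl = stats.build_timeline(str(patient), _clone_from_row(grp.iloc[0]), obs)
        timelines.append(tl)
        for pt in tl.points:
            rows.append(
                {
                    "patient_id": tl.patient_id,
                    "clone_id": tl.clone.clone_id,
                    "timepoint": pt.timepoint,
                    "role": pt.role,
                    "itd_reads": pt.itd_reads,
                    "wt_reads": pt.wt_reads,
                    "ratio": pt.ratio,
                    "positive": pt.positive,
                    "baseline_ratio": tl.baseline_ratio,
                    "log_reduction": (
                        pt.log_reduction
                        if pt.log_reduction is not None
                        else ("" if pt.role == "diagnosis" else "below sensitivity")
                    ),
                    "min_detectable_ratio": pt.min_detectable_ratio,
                    "emergent": tl.emergent,
                    "lost": tl.lost,
                }
            )
    if not timelines:
        raise PipelineError("mrd", "no patient has a diagnosis timepoint")
    return timelines, pd.DataFrame(rows)
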