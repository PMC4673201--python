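"""Amplicon reference handling, paired FASTQ streaming and run manifests.

Coordinates are 0-based, half-open, on the amplicon forward strand,
everywhere in this package.
"""
from __future__ import annotations

import gzip
import re
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator

import numpy as np
import yaml
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

REFERENCE_ALPHABET = frozenset("ACGT")
READ_ALPHABET = frozenset("ACGTN")

#: FLT3 exon 14-15 amplicon primers, kept as printed on the assay sheet
#: (FAM label and hyphens are stripped before any sequence matching).
FLT3_FORWARD_PRIMER = "5' FAM_GCA-ATT-TAG-GTA-TGA-AAG-CCA-GC_3'"
FLT3_REVERSE_PRIMER = "5'-CTT-TCA-GCA-TTT-TGA-CGG-CAA-CC-3'"

_RC_TABLE = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_RC_TABLE)[::-1]


def normalize_primer(primer: str) -> str:
    """Strip fluorophore labels, hyphens and 5'/3' decorations from a primer.

    ``"5' FAM_GCA-ATT...GC_3'"`` becomes ``"GCAATT...GC"``.
    """
    letters = re.sub(r"[^A-Za-z]", "", primer).upper()
    if letters.startswith("FAM"):
        letters = letters[3:]
    if not letters or set(letters) - REFERENCE_ALPHABET:
        raise ValueError(f"primer {primer!r} does not normalize to a DNA string")
    return letters


@dataclass(frozen=True)
class AmpliconReference:
    """The wild-type PCR product and its coordinate frame.

    ``itd_window`` is the half-open interval of insertion sites that are
    considered reportable; by default the region strictly between the primers.
    Primer fields hold the strings as printed; use :func:`normalize_primer`
    to obtain the matching form.
    """

    name: str
    sequence: str
    forward_primer: str = FLT3_FORWARD_PRIMER
    reverse_primer: str = FLT3_REVERSE_PRIMER
    itd_window: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        seq = self.sequence
        if not seq or set(seq) - REFERENCE_ALPHABET:
            raise ValueError("reference sequence must be non-empty A/C/G/T")
        fwd = normalize_primer(self.forward_primer)
        rev = normalize_primer(self.reverse_primer)
        if not seq.startswith(fwd):
            raise ValueError("reference does not begin with the forward primer")
        if not seq.endswith(revcomp(rev)):
            raise ValueError(
                "reference does not end with the reverse complement of the reverse primer"
            )
        if self.itd_window == (0, 0):
            object.__setattr__(self, "itd_window", (len(fwd), len(seq) - len(rev)))
        lo, hi = self.itd_window
        if not (0 <= lo <= hi <= len(seq)):
            raise ValueError(f"itd_window {self.itd_window} outside [0, {len(seq)})")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(eq=False)
class ReadPair:
    """One mate pair; qualities are decoded Phred scores (uint8 arrays)."""

    read_id: str
    seq1: str
    seq2: str
    qual1: np.ndarray
    qual2: np.ndarray

    def __post_init__(self) -> None:
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError(f"{self.read_id}: sequence/quality length mismatch")


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _strip_mate_suffix(title: str) -> str:
    name = title.split()[0]
    if name.endswith("/1") or name.endswith("/2"):
        name = name[:-2]
    return name


def read_fastq_pair(path1: str | Path, path2: str | Path) -> Iterator[ReadPair]:
    """Stream mate pairs from two FASTQ files (plain or gzipped).

    Mates must be in matching order. Mismatched mate counts or malformed
    records raise ``ValueError`` naming the offending record.
    """
    with _open_text(path1) as h1, _open_text(path2) as h2:
        it1 = FastqGeneralIterator(h1)
        it2 = FastqGeneralIterator(h2)
        i = 0
        while True:
            i += 1
            try:
                rec1 = next(it1, None)
            except ValueError as e:
                raise ValueError(
                    f"{path1}: malformed FASTQ at record {i} (near line {4 * i - 3}): {e}"
                ) from e
            try:
                rec2 = next(it2, None)
            except ValueError as e:
                raise ValueError(
                    f"{path2}: malformed FASTQ at record {i} (near line {4 * i - 3}): {e}"
                ) from e
            if rec1 is None and rec2 is None:
                return
            if rec1 is None or rec2 is None:
                short = path1 if rec1 is None else path2
                raise ValueError(
                    f"mate count mismatch: {short} ended before record {i}"
                )
            (t1, s1, q1), (t2, s2, q2) = rec1, rec2
            n1, n2 = _strip_mate_suffix(t1), _strip_mate_suffix(t2)
            if n1 != n2:
                raise ValueError(f"record {i}: mate ids differ ({n1!r} vs {n2!r})")
            yield ReadPair(
                n1,
                s1.upper(),
                s2.upper(),
                np.frombuffer(q1.encode(), np.uint8) - 33,
                np.frombuffer(q2.encode(), np.uint8) - 33,
            )


def _format_record(name: str, seq: str, qual: np.ndarray) -> str:
    return f"@{name}\n{seq}\n+\n{(qual + 33).tobytes().decode()}\n"


def write_fastq_pair(
    pairs: Iterable[ReadPair], path1: str | Path, path2: str | Path
) -> int:
    """Write mate pairs to two FASTQ files (gzipped if the path ends in .gz)."""
    n = 0
    opener = lambda p: gzip.open(p, "wt") if str(p).endswith(".gz") else open(p, "w")
    with opener(path1) as h1, opener(path2) as h2:
        for pair in pairs:
            h1.write(_format_record(pair.read_id, pair.seq1, pair.qual1))
            h2.write(_format_record(pair.read_id, pair.seq2, pair.qual2))
            n += 1
    return n


def write_fastq(reads, path: str | Path) -> int:
    """Write single-end records (anything with read_id/seq/qual) to FASTQ."""
    n = 0
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as h:
        for r in reads:
            h.write(_format_record(r.read_id, r.seq, r.qual))
            n += 1
    return n


def load_reference(
    fasta_path: str | Path,
    primer_fwd: str = FLT3_FORWARD_PRIMER,
    primer_rev: str = FLT3_REVERSE_PRIMER,
) -> AmpliconReference:
    """Load the amplicon reference from a single-record FASTA.

    Both primers must match the sequence exactly (after normalization);
    any sequence outside the primer pair is trimmed away so the stored
    amplicon begins with the forward primer and ends with the reverse
    complement of the reverse primer.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise ValueError(
            f"{fasta_path}: expected exactly one FASTA record, found {len(records)}"
        )
    rec = records[0]
    seq = str(rec.seq).upper()
    fwd = normalize_primer(primer_fwd)
    rev_rc = revcomp(normalize_primer(primer_rev))
    i = seq.find(fwd)
    if i < 0:
        raise ValueError(f"forward primer not found on {rec.id}")
    j = seq.rfind(rev_rc)
    if j < 0:
        raise ValueError(f"reverse primer not found on {rec.id}")
    end = j + len(rev_rc)
    if end <= i:
        raise ValueError(f"primers in unexpected orientation on {rec.id}")
    return AmpliconReference(
        name=rec.id,
        sequence=seq[i:end],
        forward_primer=primer_fwd,
        reverse_primer=primer_rev,
    )


VALID_ROLES = frozenset({"diagnosis", "followup", "control", "negative"})


@dataclass(frozen=True)
class SampleEntry:
    sample_id: str
    patient_id: str
    timepoint: int
    fastq1: str
    fastq2: str
    role: str

    def __post_init__(self) -> None:
        if self.role not in VALID_ROLES:
            raise ValueError(
                f"sample {self.sample_id}: role {self.role!r} not in {sorted(VALID_ROLES)}"
            )


@dataclass(frozen=True)
class RunManifest:
    """One sequencing run: which samples were pooled together and their roles."""

    run_id: str
    samples: tuple[SampleEntry, ...]

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"run {self.run_id}: duplicate sample ids {dup}")

    def diagnosis_samples(self) -> list[SampleEntry]:
        return [s for s in self.samples if s.role == "diagnosis"]


def load_manifest(path: str | Path) -> RunManifest:
    """Read a run manifest from YAML."""
    with open(path) as h:
        doc = yaml.safe_load(h)
    if not isinstance(doc, dict) or "run_id" not in doc or "samples" not in doc:
        raise ValueError(f"{path}: manifest needs 'run_id' and 'samples' keys")
    samples = []
    for row in doc["samples"] or []:
        samples.append(
            SampleEntry(
                sample_id=str(row["sample_id"]),
                patient_id=str(row["patient_id"]),
                timepoint=int(row.get("timepoint", 0)),
                fastq1=str(row["fastq1"]),
                fastq2=str(row["fastq2"]),
                role=str(row["role"]),
            )
        )
    if not samples:
        raise ValueError(f"{path}: manifest lists no samples")
    return RunManifest(run_id=str(doc["run_id"]), samples=tuple(samples))


def write_manifest(manifest: RunManifest, path: str | Path) -> None:
    doc = {
        "run_id": manifest.run_id,
        "samples": [
            {
                "sample_id": s.sample_id,
                "patient_id": s.patient_id,
                "timepoint": s.timepoint,
                "fastq1": s.fastq1,
                "fastq2": s.fastq2,
                "role": s.role,
            }
            for s in manifest.samples
        ],
    }
    with open(path, "w") as h:
        yaml.safe_dump(doc, h, sort_keys=False)
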