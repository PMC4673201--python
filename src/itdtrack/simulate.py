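"""Synthetic paired-end amplicon reads with known ITD truth.

The generator emulates the focused-PCR + tagmentation library: each
template is the wild-type amplicon or an ITD allele (the duplicated unit
inserted so that it appears twice in tandem), a fragment is drawn with a
truncated-normal length and uniform start, and the two mates are read
from the fragment ends with iid substitution errors. Fragmentation caps
the detectable duplication length: an ITD longer than half the fragment
span is never fully contained in a read and is invisible to repeat-based
discovery, which reproduces the failure mode of very long duplications
under tagmentation.

Everything is deterministic given the seed: the same config produces
byte-identical FASTQ output.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
import yaml

from .amplicon_io import (
    FLT3_FORWARD_PRIMER,
    FLT3_REVERSE_PRIMER,
    AmpliconReference,
    ReadPair,
    normalize_primer,
    revcomp,
)
from .calling import canonical_site

_BASES = np.frombuffer(b"ACGT", np.uint8)
_CODE = np.zeros(256, np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i

DEFAULT_READ_LENGTH = 150
DEFAULT_FRAGMENT_MEAN = 250.0
DEFAULT_FRAGMENT_SD = 60.0
DEFAULT_ERROR_RATE = 1e-3
DEFAULT_BASE_QUALITY = 37


@dataclass(frozen=True)
class CloneSpec:
    """One simulated ITD clone. ``insertion_site`` is where the second copy
    of the duplicated unit begins, in amplicon coordinates (canonicalized
    to the left-most equivalent position at validation)."""

    itd_length: int
    insertion_site: int
    allele_fraction: float


@dataclass
class SimConfig:
    reference: AmpliconReference
    clones: list[CloneSpec] = field(default_factory=list)
    n_pairs: int = 10_000
    read_length: int = DEFAULT_READ_LENGTH
    fragment_mean: float = DEFAULT_FRAGMENT_MEAN
    fragment_sd: float = DEFAULT_FRAGMENT_SD
    substitution_error_rate: float = DEFAULT_ERROR_RATE
    seed: int = 0
    min_fragment: int | None = None
    max_fragment: int | None = None
    base_quality: int = DEFAULT_BASE_QUALITY

    def validate(self) -> None:
        """Check geometry and canonicalize clone insertion sites."""
        ref = self.reference
        fracs = [c.allele_fraction for c in self.clones]
        if any(f < 0 or f > 1 for f in fracs) or sum(fracs) > 1 + 1e-9:
            raise ValueError("clone allele fractions must lie in [0,1] and sum to <= 1")
        lo, hi = ref.itd_window
        canon = []
        for c in self.clones:
            if c.itd_length < 1:
                raise ValueError("itd_length must be positive")
            if c.insertion_site - c.itd_length < 0:
                raise ValueError(
                    f"clone {c.itd_length}@{c.insertion_site}: duplicated unit "
                    "would start before the amplicon"
                )
            site = canonical_site(ref.sequence, c.itd_length, c.insertion_site)
            if not (lo <= site < hi):
                raise ValueError(
                    f"clone {c.itd_length}@{c.insertion_site}: canonical site "
                    f"{site} outside itd_window {ref.itd_window}"
                )
            canon.append(replace(c, insertion_site=site))
        self.clones = canon
        if self.min_fragment is None:
            self.min_fragment = self.read_length
        if self.max_fragment is None:
            # Cap fragments so that mates always overlap by >= 10 bases
            # and every error-free pair is mergeable.
            self.max_fragment = 2 * self.read_length - 10
        if self.min_fragment < self.read_length:
            raise ValueError("min_fragment shorter than the read length")
        if self.min_fragment > len(ref):
            raise ValueError("min_fragment exceeds the amplicon length")
        if self.max_fragment < self.min_fragment:
            raise ValueError("max_fragment below min_fragment")
        if self.n_pairs < 0:
            raise ValueError("n_pairs must be non-negative")


def mutant_sequence(reference: AmpliconReference, clone: CloneSpec) -> str:
    """ITD allele: the p bases ending at the insertion site, duplicated."""
    seq = reference.sequence
    p, site = clone.itd_length, clone.insertion_site
    return seq[:site] + seq[site - p : site] + seq[site:]


@dataclass
class SimulatedSample:
    """In-memory simulated sample: read matrices (ASCII uint8), truth table."""

    sample_id: str
    config: SimConfig
    reads1: np.ndarray  # (n, read_length) uint8 ASCII
    reads2: np.ndarray
    truth: pd.DataFrame  # allele (0 = WT, i = clone i), frag_start, frag_len
    allele_names: list[str]

    @property
    def n_pairs(self) -> int:
        return len(self.truth)

    @property
    def flat1(self) -> bytes:
        return self.reads1.tobytes()

    @property
    def flat2(self) -> bytes:
        return self.reads2.tobytes()

    def read_id(self, i: int) -> str:
        return f"{self.sample_id}:{i}"

    def iter_pairs(self, limit: int | None = None) -> Iterator[ReadPair]:
        q = np.full(self.config.read_length, self.config.base_quality, np.uint8)
        n = self.n_pairs if limit is None else min(limit, self.n_pairs)
        for i in range(n):
            yield ReadPair(
                self.read_id(i),
                self.reads1[i].tobytes().decode(),
                self.reads2[i].tobytes().decode(),
                q.copy(),
                q.copy(),
            )

    def write_fastq(self, path1: str | Path, path2: str | Path) -> None:
        import gzip

        qline = chr(self.config.base_quality + 33) * self.config.read_length
        opener = lambda p: gzip.open(p, "wt") if str(p).endswith(".gz") else open(p, "w")
        with opener(path1) as h1, opener(path2) as h2:
            for i in range(self.n_pairs):
                rid = self.read_id(i)
                h1.write(f"@{rid}\n{self.reads1[i].tobytes().decode()}\n+\n{qline}\n")
                h2.write(f"@{rid}\n{self.reads2[i].tobytes().decode()}\n+\n{qline}\n")

    def write_truth(self, path: str | Path) -> None:
        df = self.truth.copy()
        df.insert(0, "read_id", [self.read_id(i) for i in range(len(df))])
        df["allele_name"] = [self.allele_names[a] for a in df["allele"]]
        df.to_csv(path, sep="\t", index=False)

    def expected_junction_pairs(self, clone_index: int, k_flank: int = 12) -> int:
        """Truth-implied junction-read count for merged-read counting:
        pairs of this clone whose fragment fully contains the junction
        signature window [site - k, site + k)."""
        clone = self.config.clones[clone_index]
        c = clone.insertion_site
        t = self.truth
        mask = (
            (t["allele"] == clone_index + 1)
            & (t["frag_start"] <= c - k_flank)
            & (t["frag_start"] + t["frag_len"] >= c + k_flank)
        )
        return int(mask.sum())

    def expected_junction_mate_pairs(self, clone_index: int, k_flank: int = 12) -> int:
        """Truth-implied junction-read count for pair counting: the
        signature window must fit entirely inside one of the two mates
        (a window straddling the unsequenced middle of a long fragment is
        invisible without merging)."""
        clone = self.config.clones[clone_index]
        c = clone.insertion_site
        R = self.config.read_length
        t = self.truth
        s = t["frag_start"]
        e = t["frag_start"] + t["frag_len"]
        in_mate1 = (s <= c - k_flank) & (c + k_flank <= s + R)
        in_mate2 = (e - R <= c - k_flank) & (c + k_flank <= e)
        mask = (t["allele"] == clone_index + 1) & (in_mate1 | in_mate2)
        return int(mask.sum())


def simulate_sample(config: SimConfig, sample_id: str = "sim") -> SimulatedSample:
    """Generate one sample's mate pairs and truth table (vectorized)."""
    config.validate()
    cfg = config
    ref = cfg.reference
    rng = np.random.default_rng(cfg.seed)
    R = cfg.read_length
    n = cfg.n_pairs

    allele_seqs = [ref.sequence] + [mutant_sequence(ref, c) for c in cfg.clones]
    allele_names = ["WT"] + [
        f"ITD{c.itd_length}@{c.insertion_site}" for c in cfg.clones
    ]
    arrs = [_CODE[np.frombuffer(s.encode(), np.uint8)] for s in allele_seqs]
    lens = np.array([len(s) for s in allele_seqs])

    fracs = np.array([c.allele_fraction for c in cfg.clones])
    cum = np.cumsum(np.concatenate([[1.0 - fracs.sum()], fracs]))
    allele = np.searchsorted(cum, rng.random(n), side="right").astype(np.int8)
    allele = np.minimum(allele, len(arrs) - 1)

    alen = lens[allele]
    frag = np.rint(rng.normal(cfg.fragment_mean, cfg.fragment_sd, n)).astype(np.int64)
    frag = np.clip(frag, cfg.min_fragment, np.minimum(cfg.max_fragment, alen))
    start = np.floor(rng.random(n) * (alen - frag + 1)).astype(np.int64)

    reads1 = np.empty((n, R), np.uint8)
    reads2 = np.empty((n, R), np.uint8)
    offs = np.arange(R, dtype=np.int64)
    for ai, arr in enumerate(arrs):
        rows = np.flatnonzero(allele == ai)
        if rows.size == 0:
            continue
        reads1[rows] = arr[start[rows][:, None] + offs]
        end = start[rows] + frag[rows]
        # mate 2: reverse complement of the fragment's last R bases
        reads2[rows] = (3 - arr[(end - R)[:, None] + offs])[:, ::-1]

    e = cfg.substitution_error_rate
    if e > 0 and n > 0:
        for mat in (reads1, reads2):
            flat = mat.reshape(-1)
            n_err = rng.binomial(flat.size, e)
            if n_err:
                pos = rng.integers(0, flat.size, n_err)
                flat[pos] = (flat[pos] + rng.integers(1, 4, n_err)) % 4

    truth = pd.DataFrame(
        {
            "allele": allele,
            "frag_start": start.astype(np.int32),
            "frag_len": frag.astype(np.int32),
        }
    )
    return SimulatedSample(
        sample_id=sample_id,
        config=cfg,
        reads1=_BASES[reads1],
        reads2=_BASES[reads2],
        truth=truth,
        allele_names=allele_names,
    )


def child_seed(seed: int, index: int) -> int:
    """Deterministic per-sample seed derived from a parent seed."""
    return int(np.random.SeedSequence([seed, index]).generate_state(1)[0] % (2**31))


def dilution_series(
    positive: SimConfig, dilutions: list[float]
) -> list[tuple[float, SimConfig]]:
    """Configs for serial dilutions of a positive sample into a negative
    background: clone allele fractions scaled by each dilution factor,
    depth preserved, per-dilution seeds derived from the parent seed."""
    positive.validate()
    if not positive.clones:
        raise ValueError("dilution series needs at least one clone")
    out = []
    for i, d in enumerate(dilutions):
        if d < 0 or d > 1:
            raise ValueError(f"dilution {d} outside [0, 1]")
        cfg = replace(
            positive,
            clones=[
                replace(c, allele_fraction=c.allele_fraction * d)
                for c in positive.clones
            ],
            seed=child_seed(positive.seed, i + 1),
        )
        out.append((d, cfg))
    return out


def synthetic_reference(core_length: int = 284, seed: int = 101) -> AmpliconReference:
    """A synthetic stand-in for the FLT3 exon 14-15 amplicon.

    The real PCR-product sequence is taken as input in production use;
    this deterministic surrogate keeps the printed primers at its ends
    and fills the core with random bases, re-drawn until the wild-type
    amplicon contains no tandem repeat of period >= 15 (so every repeat
    call on simulated data is a true duplication).
    """
    from .repeats import find_tandem_repeats

    fwd = normalize_primer(FLT3_FORWARD_PRIMER)
    rev = normalize_primer(FLT3_REVERSE_PRIMER)
    rng = np.random.default_rng(seed)
    for _ in range(100):
        core = _BASES[rng.integers(0, 4, core_length)].tobytes().decode()
        seq = fwd + core + revcomp(rev)
        if not find_tandem_repeats(seq, min_period=15, resolution=1):
            return AmpliconReference(name="FLT3_amplicon_synthetic", sequence=seq)
    raise RuntimeError("could not draw a repeat-free synthetic amplicon")


def config_to_yaml(config: SimConfig, path: str | Path) -> None:
    """Dump the simulation parameters (for provenance alongside FASTQ)."""
    doc = {
        "reference": config.reference.name,
        "amplicon_length": len(config.reference),
        "clones": [
            {
                "itd_length": c.itd_length,
                "insertion_site": c.insertion_site,
                "allele_fraction": c.allele_fraction,
            }
            for c in config.clones
        ],
        "n_pairs": config.n_pairs,
        "read_length": config.read_length,
        "fragment_mean": config.fragment_mean,
        "fragment_sd": config.fragment_sd,
        "min_fragment": config.min_fragment,
        "max_fragment": config.max_fragment,
        "substitution_error_rate": config.substitution_error_rate,
        "base_quality": config.base_quality,
        "seed": config.seed,
    }
    with open(path, "w") as h:
        yaml.safe_dump(doc, h, sort_keys=False)
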