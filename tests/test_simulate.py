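import math

import numpy as np
import pytest

from itdtrack import (
    CloneSpec,
    SimConfig,
    clone_from_reference,
    count_breakpoints_flat,
    dilution_series,
    simulate_sample,
)
from itdtrack.repeats import find_tandem_repeats
from itdtrack.simulate import mutant_sequence, synthetic_reference


def test_synthetic_reference_is_deterministic_and_repeat_free():
    a = synthetic_reference()
    b = synthetic_reference()
    assert a.sequence == b.sequence
    assert find_tandem_repeats(a.sequence, min_period=15, resolution=1) == []
    assert a.sequence.startswith("GCAATTTAGGTATGAAAGCCAGC")


def test_mutant_sequence_duplicates_unit_in_tandem(reference):
    clone = CloneSpec(48, 200, 1.0)
    mut = mutant_sequence(reference, clone)
    assert len(mut) == len(reference) + 48
    assert mut[152:200] == mut[200:248]  # the two copies
    assert mut[:200] == reference.sequence[:200]
    assert mut[248:] == reference.sequence[200:]


def test_zero_fraction_yields_all_wt_truth(reference):
    cfg = SimConfig(reference=reference, clones=[CloneSpec(48, 200, 0.0)],
                    n_pairs=300, seed=2)
    s = simulate_sample(cfg)
    assert (s.truth["allele"] == 0).all()


def test_same_seed_gives_byte_identical_fastq(reference, tmp_path):
    for d in ("a", "b"):
        cfg = SimConfig(reference=reference, clones=[CloneSpec(48, 200, 0.3)],
                        n_pairs=400, seed=99)
        s = simulate_sample(cfg, "rep")
        (tmp_path / d).mkdir()
        s.write_fastq(tmp_path / d / "R1.fastq", tmp_path / d / "R2.fastq")
    assert (tmp_path / "a/R1.fastq").read_bytes() == (tmp_path / "b/R1.fastq").read_bytes()
    assert (tmp_path / "a/R2.fastq").read_bytes() == (tmp_path / "b/R2.fastq").read_bytes()


def test_fragments_respect_bounds_and_alphabet(reference):
    cfg = SimConfig(reference=reference, clones=[CloneSpec(48, 200, 0.5)],
                    n_pairs=500, seed=4)
    s = simulate_sample(cfg)
    assert int(s.truth["frag_len"].min()) >= 150
    assert int(s.truth["frag_len"].max()) <= 290
    assert set(s.flat1) <= set(b"ACGT")
    ends = s.truth["frag_start"] + s.truth["frag_len"]
    lens = np.where(s.truth["allele"] == 0, len(reference), len(reference) + 48)
    assert (s.truth["frag_start"] >= 0).all() and (ends <= lens).all()


def test_invalid_geometry_rejected(reference):
    with pytest.raises(ValueError, match="amplicon"):
        SimConfig(reference=reference, n_pairs=10, read_length=400).validate()
    with pytest.raises(ValueError, match="fractions"):
        SimConfig(reference=reference,
                  clones=[CloneSpec(48, 200, 0.7), CloneSpec(21, 100, 0.7)],
                  n_pairs=10).validate()
    with pytest.raises(ValueError, match="before the amplicon"):
        SimConfig(reference=reference, clones=[CloneSpec(48, 30, 0.5)],
                  n_pairs=10).validate()


def test_error_rate_perturbs_expected_base_count(reference):
    cfg = SimConfig(reference=reference, clones=[], n_pairs=2000,
                    substitution_error_rate=5e-3, seed=12)
    s = simulate_sample(cfg)
    clean = simulate_sample(
        SimConfig(reference=reference, clones=[], n_pairs=2000,
                  substitution_error_rate=0.0, seed=12)
    )
    diff = np.count_nonzero(s.reads1 != clean.reads1) + np.count_nonzero(
        s.reads2 != clean.reads2
    )
    expected = 2 * 2000 * 150 * 5e-3
    assert abs(diff - expected) <= 3 * math.sqrt(expected)


def test_counted_junction_reads_match_error_model(reference):
    """With errors, junction hits thin by ~(1-e)^24; observed within 3 SD."""
    e = 1e-3
    cfg = SimConfig(reference=reference, clones=[CloneSpec(48, 200, 0.5)],
                    n_pairs=20_000, substitution_error_rate=e, seed=21)
    s = simulate_sample(cfg)
    clone = clone_from_reference(reference, 48, 200)
    cc = count_breakpoints_flat(s.flat1, s.flat2, s.n_pairs, 150, clone, reference)
    # per-pair survival: one shot if the window sits in one mate, two if in both
    t = s.truth
    c, R = 200, 150
    start, end = t["frag_start"], t["frag_start"] + t["frag_len"]
    in1 = (start <= c - 12) & (c + 12 <= start + R)
    in2 = (end - R <= c - 12) & (c + 12 <= end)
    mut = t["allele"] == 1
    n_both = int((mut & in1 & in2).sum())
    n_single = int((mut & (in1 ^ in2)).sum())
    q = (1 - e) ** 24
    q2 = 1 - (1 - q) ** 2
    expected = n_single * q + n_both * q2
    sd = math.sqrt(n_single * q * (1 - q) + n_both * q2 * (1 - q2))
    assert abs(cc.itd_reads - expected) <= 3 * sd + 1


def test_dilution_scales_fractions_and_preserves_depth(reference):
    base = SimConfig(reference=reference, clones=[CloneSpec(48, 200, 0.54)],
                     n_pairs=1000, seed=7)
    series = dilution_series(base, [1.0, 1e-2, 0.0])
    assert [d for d, _ in series] == [1.0, 1e-2, 0.0]
    assert series[0][1].clones[0].allele_fraction == pytest.approx(0.54)
    assert series[1][1].clones[0].allele_fraction == pytest.approx(0.0054)
    assert all(cfg.n_pairs == 1000 for _, cfg in series)
    # distinct but deterministic per-dilution seeds
    again = dilution_series(base, [1.0, 1e-2, 0.0])
    assert [c.seed for _, c in series] == [c.seed for _, c in again]
    assert len({c.seed for _, c in series}) == 3
    # d = 0: all-WT sample
    s0 = simulate_sample(series[2][1])
    assert (s0.truth["allele"] == 0).all()


def test_diluted_allele_counts_follow_binomial_expectation(reference):
    f, d, n = 0.54, 1e-3, 200_000
    base = SimConfig(reference=reference, clones=[CloneSpec(48, 200, f)],
                     n_pairs=n, substitution_error_rate=0.0, seed=13)
    (_, cfg), = dilution_series(base, [d])
    s = simulate_sample(cfg)
    observed = int((s.truth["allele"] == 1).sum())
    expected = n * f * d
    assert abs(observed - expected) <= 3 * math.sqrt(expected)


def test_long_itd_fragments_never_contain_full_duplication(reference):
    cfg = SimConfig(reference=reference, clones=[CloneSpec(183, 290, 0.5)],
                    n_pairs=2000, substitution_error_rate=0.0, seed=6)
    s = simulate_sample(cfg)
    assert int(s.truth["frag_len"].max()) < 2 * 183
    assert s.expected_junction_pairs(0, 12) > 0  # junction is covered...
    clone_cfg = cfg.clones[0]
    # ...but no fragment spans both copies plus anchors
    c, p = clone_cfg.insertion_site, 183
    spans_both = (
        (s.truth["frag_start"] <= c - p)
        & (s.truth["frag_start"] + s.truth["frag_len"] >= c + p)
        & (s.truth["allele"] == 1)
    )
    assert int(spans_both.sum()) == 0
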