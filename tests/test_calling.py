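import numpy as np
import pytest

from itdtrack import (
    CloneSpec,
    SimConfig,
    clone_from_reference,
    count_breakpoints,
    count_breakpoints_flat,
    count_breakpoints_pairs,
    discover_clones,
    simulate_sample,
    wt_signature,
)
from itdtrack.calling import ITDClone, canonical_site, same_clone
from itdtrack.merging import merge_pairs
from itdtrack.simulate import mutant_sequence
from conftest import make_pair


def _merged(sample, limit=None):
    merged, _ = merge_pairs(sample.iter_pairs(limit))
    return merged


def test_single_clone_recovered_exactly(reference):
    cfg = SimConfig(
        reference=reference,
        clones=[CloneSpec(48, 200, 0.30)],
        n_pairs=1000,
        substitution_error_rate=0.0,
        seed=5,
    )
    sample = simulate_sample(cfg, "pos")
    clones, tallies = discover_clones(_merged(sample), reference)
    assert len(clones) == 1
    truth = clone_from_reference(reference, 48, 200)
    assert clones[0].itd_length == 48
    assert clones[0].insertion_site == truth.insertion_site
    assert clones[0].junction_signature == truth.junction_signature
    assert clones[0].support == tallies["itd_reads"] > 100


def test_all_wt_sample_yields_no_clones(reference):
    cfg = SimConfig(reference=reference, clones=[], n_pairs=500, seed=1)
    clones, _ = discover_clones(_merged(simulate_sample(cfg, "neg")), reference)
    assert clones == []


def test_two_clone_sample_recovers_both_lengths(reference):
    """Dominant + minor clone in one sample, as seen in multiclonal AML."""
    cfg = SimConfig(
        reference=reference,
        clones=[CloneSpec(39, 150, 0.25), CloneSpec(60, 240, 0.10)],
        n_pairs=2000,
        substitution_error_rate=0.0,
        seed=10,
    )
    sample = simulate_sample(cfg, "mc")
    clones, _ = discover_clones(_merged(sample), reference)
    assert [(c.itd_length) for c in clones[:2]] == [39, 60]  # support-ordered
    sites = {c.itd_length: c.insertion_site for c in clones}
    assert sites[39] == clone_from_reference(reference, 39, 150).insertion_site
    assert sites[60] == clone_from_reference(reference, 60, 240).insertion_site


@pytest.mark.parametrize("length", [15, 21, 39, 48, 60, 75, 90])
def test_length_and_site_recovery_across_sizes(reference, length):
    rng = np.random.default_rng(length)
    lo, hi = reference.itd_window
    # leave anchor room on both sides so a fragment can span the repeat
    site = int(rng.integers(max(lo + 1, length + 20), min(hi - 1, len(reference) - length - 20)))
    cfg = SimConfig(
        reference=reference,
        clones=[CloneSpec(length, site, 0.5)],
        n_pairs=500,
        substitution_error_rate=1e-3,
        seed=int(rng.integers(0, 2**31)),
    )
    sample = simulate_sample(cfg, f"len{length}")
    clones, _ = discover_clones(_merged(sample), reference)
    assert clones, f"no clone recovered for {length} bp"
    truth_site = cfg.clones[0].insertion_site  # canonicalized by validate()
    assert (clones[0].itd_length, clones[0].insertion_site) == (length, truth_site)


def test_fragmentation_cliff_long_itd_invisible(reference):
    """A duplication longer than any read span yields zero clone calls:
    tagmentation fragments the allele inside the ITD."""
    cfg = SimConfig(
        reference=reference,
        clones=[CloneSpec(183, 290, 0.5)],
        n_pairs=3000,
        substitution_error_rate=0.0,
        seed=77,
    )
    sample = simulate_sample(cfg, "long")
    clones, _ = discover_clones(_merged(sample), reference)
    assert clones == []


def test_counts_by_construction(reference):
    clone = clone_from_reference(reference, 48, 200)
    mut = mutant_sequence(reference, CloneSpec(48, 200, 1.0))
    wt = reference.sequence

    class R:  # minimal merged-read stand-in
        def __init__(self, seq):
            self.seq = seq

    reads = [R(mut[100:330]) for _ in range(20)]  # junction at 200 covered
    reads += [R(wt[60:320]) for _ in range(170)]  # WT breakpoint covered
    reads += [R(wt[:40]) for _ in range(10)]  # covers neither signature
    cc = count_breakpoints(reads, clone, reference, "s")
    assert (cc.itd_reads, cc.wt_reads, cc.total_merged) == (20, 170, 200)
    # count conservation: itd + wt + other == total
    other = sum(
        clone.junction_signature not in r.seq
        and wt_signature(reference, 200).signature not in r.seq
        for r in reads
    )
    assert cc.itd_reads + cc.wt_reads + other == cc.total_merged


def test_mutant_reads_not_double_counted_as_wt(reference):
    """The distal end of the duplication recreates the WT context; such
    reads must not inflate the WT tally."""
    clone = clone_from_reference(reference, 48, 200)
    mut = mutant_sequence(reference, CloneSpec(48, 200, 1.0))

    class R:
        def __init__(self, seq):
            self.seq = seq

    # whole mutant allele: contains both the junction and the WT context
    cc = count_breakpoints([R(mut)], clone, reference, "s")
    assert (cc.itd_reads, cc.wt_reads) == (1, 0)
    assert wt_signature(reference, 200).signature in mut


def test_clone_counted_in_other_patients_negative_sample_is_zero(reference):
    clone = clone_from_reference(reference, 48, 200)
    cfg = SimConfig(reference=reference, clones=[], n_pairs=2000,
                    substitution_error_rate=0.0, seed=3)
    sample = simulate_sample(cfg, "neg")
    cc = count_breakpoints_flat(
        sample.flat1, sample.flat2, sample.n_pairs, 150, clone, reference, "neg"
    )
    assert cc.itd_reads == 0
    assert cc.wt_reads > 0


def test_sequencing_errors_do_not_fabricate_junctions(reference):
    """Converting a WT read into a 24-base junction match needs many
    simultaneous specific substitutions; at 1e-3/base the expected count
    is ~0."""
    clone = clone_from_reference(reference, 48, 200)
    cfg = SimConfig(reference=reference, clones=[], n_pairs=20_000,
                    substitution_error_rate=1e-3, seed=19)
    sample = simulate_sample(cfg, "neg")
    cc = count_breakpoints_flat(
        sample.flat1, sample.flat2, sample.n_pairs, 150, clone, reference, "neg"
    )
    assert cc.itd_reads == 0


def test_itd_counts_increase_with_allele_fraction(reference):
    counts = []
    for frac in (0.05, 0.15, 0.35):
        cfg = SimConfig(
            reference=reference,
            clones=[CloneSpec(48, 200, frac)],
            n_pairs=4000,
            substitution_error_rate=0.0,
            seed=55,  # same seed structure across fractions
        )
        s = simulate_sample(cfg, f"f{frac}")
        clone = clone_from_reference(reference, 48, 200)
        cc = count_breakpoints_flat(s.flat1, s.flat2, s.n_pairs, 150, clone, reference)
        counts.append(cc.itd_reads)
    assert counts[0] < counts[1] < counts[2]


def test_flat_and_pair_counting_agree(reference):
    cfg = SimConfig(
        reference=reference,
        clones=[CloneSpec(48, 200, 0.2)],
        n_pairs=800,
        substitution_error_rate=1e-3,
        seed=8,
    )
    s = simulate_sample(cfg, "x")
    clone = clone_from_reference(reference, 48, 200)
    a = count_breakpoints_flat(s.flat1, s.flat2, s.n_pairs, 150, clone, reference, "x")
    b = count_breakpoints_pairs(s.iter_pairs(), clone, reference, "x")
    assert (a.itd_reads, a.wt_reads, a.total_merged) == (
        b.itd_reads,
        b.wt_reads,
        b.total_merged,
    )


def test_truth_consistency_error_free(reference):
    """On error-free data the counted junction reads equal the truth table's
    containment counts exactly, for both counting routes."""
    cfg = SimConfig(
        reference=reference,
        clones=[CloneSpec(48, 200, 0.5)],
        n_pairs=5000,
        substitution_error_rate=0.0,
        seed=31,
    )
    s = simulate_sample(cfg, "t")
    clone = clone_from_reference(reference, 48, 200)
    # pair counting: signature must fit inside one mate
    flat = count_breakpoints_flat(s.flat1, s.flat2, s.n_pairs, 150, clone, reference)
    assert flat.itd_reads == s.expected_junction_mate_pairs(0, 12)
    # merged counting: signature anywhere on the reconstructed fragment
    merged = count_breakpoints(_merged(s), clone, reference)
    assert merged.itd_reads == s.expected_junction_pairs(0, 12)


def test_signature_on_reference_is_rejected(reference):
    bogus = ITDClone(
        itd_length=48,
        insertion_site=200,
        junction_signature=reference.sequence[100:124],
        duplicated_seq="A" * 48,
    )
    with pytest.raises(ValueError, match="reference"):
        count_breakpoints([], bogus, reference, "s")
    with pytest.raises(ValueError, match="reference"):
        count_breakpoints_flat(b"", b"", 0, 150, bogus, reference, "s")


def test_canonical_site_is_leftmost_equivalent(reference):
    seq = reference.sequence
    p = 30
    # find a site where the base one left of the junction repeats at lag p
    site = next(
        s
        for s in range(max(reference.itd_window[0], p) + 2, reference.itd_window[1])
        if seq[s - 1] == seq[s - 1 - p]
    )
    c = canonical_site(seq, p, site)
    assert c < site
    assert mutant_sequence(reference, CloneSpec(p, site, 1.0)) == mutant_sequence(
        reference, CloneSpec(p, c, 1.0)
    )


def test_same_clone_tolerates_one_substitution(reference):
    a = clone_from_reference(reference, 48, 200)
    sig = list(a.junction_signature)
    sig[5] = {"A": "C", "C": "G", "G": "T", "T": "A"}[sig[5]]
    b = ITDClone(48, a.insertion_site, "".join(sig), a.duplicated_seq)
    assert same_clone(a, b)
    sig[6] = {"A": "C", "C": "G", "G": "T", "T": "A"}[sig[6]]
    c = ITDClone(48, a.insertion_site, "".join(sig), a.duplicated_seq)
    assert not same_clone(a, c)
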