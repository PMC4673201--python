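# Methods

## Problem and approach

An FLT3 internal tandem duplication (ITD) inserts a second copy of a
segment of the gene immediately after the original. On an amplicon
covering the locus, the mutant allele differs from wild type by one
diagnostic feature that no amount of substitution noise can imitate: a
*junction* where the end of the duplicated unit is followed by its own
beginning. `itdtrack` detects and quantifies ITDs purely from that
junction, on merged reads, without alignment. All coordinates are
0-based, half-open, on the amplicon forward strand.

## Read merging

Mate 2 is reverse-complemented and all overlap lengths from
`min_overlap` (default 10) up to the read length are scored; the overlap
with the smallest mismatch fraction is chosen, ties going to the longer
overlap, and the pair is left unmerged (a counted QC outcome) when the
best fraction exceeds `max_mismatch_frac` (default 0.1). Fraction-based
selection rather than a raw match-minus-mismatch score is deliberate: an
ITD-bearing read is self-similar at lag p (the duplication length), so
the overlap shifted by p aligns the two copies of the duplicated unit
against each other and can accumulate more raw score than a short true
overlap — merging there would silently delete the duplication. The true
overlap is mismatch-free on clean data and always wins on fraction.
Overlapped positions take the base with the higher Phred quality, ties
to mate 1. Indel-aware overlap alignment is out of scope; the error
model of the target instrument is substitution-dominated.

## Tandem-repeat finding

For each period p (default 15–150 bp) the read is compared against
itself at lag p; a repeat is a maximal run of agreeing positions
tolerating at most `resolution` mismatches (default 1, absorbing one
sequencing error or minor duplication impurity), occupying
`[start, start + span)` with `span = run + p`. Two constraints shape the
output:

* **Full containment (copies ≥ 2):** only runs with `span ≥ 2p` are
  reported, so the read must contain the entire duplication. This is not
  an optimization but a property of the assay: a fragment that breaks
  inside the ITD carries no junction and is indistinguishable from wild
  type locally (see the failure mode below).
* **Minimal period:** a run whose sequence interval is covered by a
  maximal run at a smaller period is suppressed. A homopolymer repeats
  at every period; without suppression a 30 bp poly-A tract would be
  reported as a period-15 "duplication". With `min_period = 15` simple
  sequence (homopolymers, di-/trinucleotide microsatellites) is
  therefore invisible while every plausible ITD, whose unit is
  effectively random, is untouched.

The scan is O(n·P) per read with vectorized window extraction, entirely
adequate at amplicon read lengths; asymptotically optimal
maximal-repetition algorithms are deliberately not used. The
implementation is validated against a brute-force oracle that enumerates
every (start, period, span) window and checks budget and maximality
exhaustively.

## Clone calling

A read nominates a clone from its dominant repeat (largest span, ties to
the smaller start). The read is anchored by exact match of its first and
last 20 bases to the amplicon (reads whose ends disagree with the
implied duplication length are tallied as unanchored, never guessed).
The junction is located as the end of the longest common prefix of the
read with the reference at its anchor — the right-most equivalent
junction — and then canonicalized leftward: duplicating
`ref[s-p:s]` at `s` and `ref[s-p-1:s-1]` at `s-1` yield the identical
mutant sequence whenever `ref[s-1] == ref[s-1-p]`, so every tandem
duplication has an equivalence class of coordinate representations and
both the caller and the simulator's truth use the left-most one. This
makes "exact insertion-site recovery" well defined; deriving the site
from the raw repeat-window start instead would drift left whenever the
mismatch budget lets the window absorb a flanking mismatch.

Reads are pooled by (length, site); junction signatures within one
substitution of the pool majority are merged into it, and pools with
fewer than `min_support` reads (default 5) are dropped at discovery.
Follow-up counting has no support floor — positivity is governed by the
Fisher test. The junction signature is the 24 bp (2 × `k_flank`,
default 12) window centered on the junction; a random 24-mer match has
probability ~4⁻²⁴, and a signature that occurs on the wild-type amplicon
is rejected outright. Clone identity across samples and runs is same
(length, site) with signatures within one substitution.

## Breakpoint counting and the ITD/WT ratio

Counting is exact substring search over a sample's reads: the junction
signature for the ITD allele and the wild-type signature (the reference
24-mer centered on the insertion site) for the WT allele; each read
counts at most once per signature, and the ratio is
`itd_reads / wt_reads` (infinite with a warning when `wt_reads = 0`,
undefined when both are 0).

One subtlety is load-bearing: the mutant allele contains *every*
substring of the wild-type amplicon — at the distal end of the second
copy the sequence re-enters the reference and recreates the wild-type
breakpoint context exactly. Naively counting the WT signature would
therefore count most mutant reads too, and the ratio could never
meaningfully exceed ~1, contradicting the ratios > 1 seen when the
mutant allele dominates (e.g. loss of the wild-type allele). A read is
consequently counted as WT only if it carries the WT signature and *not*
the junction signature. Mutant reads that cover the distal context but
break before the junction still land in the WT tally — an irreducible
ambiguity of alignment-free counting — so the read-level ratio of a
50/50 sample runs some 10–15% below the allele-level odds f/(1−f). The
effect is allele-fraction-proportional and cancels in dilution slopes
and log reductions. No read-length bias correction is applied for the
longer mutant allele.

For very deep samples a fast path counts signatures directly on the raw
mate pairs (mate 2 searched via reverse complement, one count per pair,
totals are pair counts): a 24 bp signature always fits inside one 150 bp
mate, so merging is unnecessary for counting — it is only required for
discovery, which subsamples (default 8000 pairs). A signature window
falling in the unsequenced interior of a fragment longer than
`2·read_length − 24` is invisible to the fast path; this affects ITD and
WT windows symmetrically and leaves the ratio unbiased.

## Positivity, sensitivity, MRD

Positivity of sample s for clone c is a one-sided Fisher exact test
(alternative: sample rate greater) on
`[[itd_s, total_s − itd_s], [itd_ctrl, total_ctrl − itd_ctrl]]`, where
the control row pools all samples of *other patients in the same
sequencing run*. Pooling by run turns the test into a per-run
contamination control: ambient cross-sample bleed-through raises the
control rate and the bar for positivity with it. Diagnosis and follow-up
samples are sequenced in separate runs precisely so that a patient's own
diagnosis material cannot poison the follow-up controls; the pipeline
mirrors this by restricting clone discovery to diagnosis-role samples.
Alpha defaults to 0.05, one-sided, uncorrected; a Bonferroni switch
(alpha / number of clones) is available. With no other-patient depth in
the run the call falls back to a support floor of 5 junction reads and
is flagged in the output.

Per-sample sensitivity is the smallest junction-read count k* that would
test positive at the sample's depth against its controls (found by
bisection, equivalent to an exhaustive scan since the one-sided p-value
is non-increasing in the count), reported as the ratio
`k* / wt_reads` — the denominator is observable even in negative
samples. Follow-up levels are `log10(baseline_ratio / ratio)` with the
diagnosis ratio as baseline; points with zero junction reads are
reported as below the sample's minimal detectable ratio, never as a
measured zero. A clone negative at diagnosis but positive later is
flagged *emergent*, one positive at diagnosis but negative at the last
timepoint *lost* — together these express diagnosis/relapse mutational
shifts.

## Simulator

Each template is the wild-type amplicon or a mutant allele
(`ref[:site] + ref[site-p:site] + ref[site:]`, insertion sites
canonicalized); fragments are truncated-normal (mean 250 bp, sd 60,
emulating ~150 bp-spaced tagmentation on a short amplicon) with uniform
start; mates of 150 bp are read from the fragment ends; substitutions
are iid per base (default 10⁻³, the dominant instrument error mode; no
indels, no PCR chimeras, no learned quality profiles). Base qualities
are a constant (default Q37). Output is deterministic given the seed,
including byte-identical FASTQ; derived samples (dilutions, cohorts) use
seeds spawned deterministically from the parent seed.

Two geometry choices matter:

* The fragment-length upper bound defaults to
  `2·read_length − min_overlap` (290 bp) rather than the amplicon
  length, so every error-free pair is mergeable; with an unbounded upper
  tail ~25% of pairs would fall in an unmergeable gap and silently
  vanish from all counts. The amplicon cap still applies where shorter.
* Fragmentation enforces the detectability cliff: a duplication with
  `2p` exceeding the maximal fragment (e.g. 183 bp) is never fully
  contained in a read, reproducing the known failure of tagmentation
  libraries on very long ITDs — the simulator and caller agree that such
  clones yield zero calls.

The synthetic default reference keeps the real assay primers at its ends
and fills the interior with random bases, re-drawn until the wild-type
amplicon is free of period-≥15 repeats; it is a labelled synthetic
stand-in (the true PCR-product sequence is an input in production use).
Because the simulator omits indel errors, coverage bias, PCR duplicates
and primer artifacts, passing tests demonstrate algorithmic correctness
under the stated error model, not robustness to every artifact of real
libraries.

## Validation experiments

`itdtrack.experiments` regenerates the characterization studies at full
scale (all sizes are the package's own defaults): a 10⁻¹…10⁻⁴ serial
dilution of a 48 bp-ITD source with allele fraction 1.19/2.19 (allele
odds 1.19) into a negative background at 10⁶ read pairs per dilution,
tested against an in-run negative control of the same depth; exact
length/site recovery over ITD sizes {15, 21, 39, 48, 60, 75, 90} bp × 15
replicates at 400 pairs and 10⁻³ error rate, with insertion sites drawn
from the geometrically detectable region (duplication plus 20 bp anchors
inside the amplicon — a duplication jammed against a primer cannot be
spanned by any fragment and is undetectable by construction, the same
containment constraint as the 183 bp cliff); the 183 bp cliff itself; and
a 500-sample negative cohort for type-I control. `scripts/acceptance.py`
runs all of them from a single seed and writes the numbers as JSON.

## Known limitations

* ITDs longer than the merged-read span are undetectable by design.
* Mutant distal-breakpoint reads depress the read-level ratio relative
  to allele odds (see counting section); no correction is applied.
* Reads are assumed in fixed orientation (mate 1 forward), as produced
  by the simulator; real libraries with mixed fragment orientation
  would need an orientation-detection pass before merging.
* Insertions with novel non-templated junction bases are detected only
  insofar as the duplicated copies still match within the mismatch
  budget.
* Discovery anchors read ends by exact match; heavily degraded read
  ends reduce discovery support (counting is unaffected).
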