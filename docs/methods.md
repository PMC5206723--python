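# Methods

## Problem setting and model

`splicescope` analyses splicing of **one** multi-exon transcript isoform at
a time.  The transcript model is an ordered list of exons in transcription
direction with 0-based half-open genomic coordinates; a splice junction is
identified by its excised intron interval on the genomic plus strand
(`donor_pos < acceptor_pos` always), with donor/acceptor *roles* resolved
through the strand.  This matches SAM/BED tooling and keeps minus-strand
transcripts (the dystrophin case) free of per-junction special cases.  The
canonical junction set of an *n*-exon model is exactly the *n* − 1
junctions joining consecutive exons; single-exon models are legal and have
none.

## Event classification

A novel junction is resolved against the canonical donor/acceptor maps
into exactly one category:

* both ends canonical with ≥ 1 exon omitted → **exon skip** (labelled
  `del{k}` or `del{k}+{k+1}` for consecutive blocks);
* canonical donor, acceptor displaced **within the adjacent exon** →
  **alt 3′ss**; the symmetric case → **alt 5′ss**.  Offsets carry the sign
  convention that exonic truncation is negative (−3 means the exon loses
  its first 3 nt).  Because the alternative rendering that counts the new
  acceptor's position inside the exon differs by one (a −60 truncation is
  an acceptor at exonic position 59), both renderings are exposed
  (`offset_nt` and `alt_site_exonic_position`) rather than conflated;
* canonical donor joined to a point **strictly inside the same intron** →
  pseudoexon half-junction (acceptor side), and symmetrically for the
  donor side.  Halves are paired per host intron — each acceptor half with
  the nearest donor half downstream in transcription — into a
  **pseudoexon** whose interval the two junctions delimit.  Pairs crossed
  by at least one single read (junction co-occurrence, natural for
  ≥ 300 nt reads over ≤ 162 nt cryptic exons) get a
  `single_read_verified` flag;
* anything else is unclassified.  Composite events (e.g. a skip combined
  with an alternative site on a non-adjacent exon) are deliberately not
  guessed at.

**Misalignment safeguard.**  A junction whose flanking sequence repeats
allow the same spliced sequence under a shifted intron placement is a
known artifact source at homopolymers (the basis for excluding apparent
events at two junction pairs in the motivating study).  For shifts
|s| ≤ `max_shift` (default 10 nt, covering typical 454 homopolymer runs)
the junction is flagged `ambiguous_alignment` and excluded from the final
inventory — reported separately — whenever a shifted placement coincides
with a canonical junction or another candidate.  Unclassifiable junctions
that are shift-equivalent to a canonical junction are likewise diverted to
the exclusion list rather than left as mysteries.

**Reading frame.**  The frame call is length-based: Δnt ≢ 0 (mod 3) is out
of frame.  Frame-neutral insertions (pseudoexons) are additionally
screened for stop codons in the transcript frame when the inserted
sequence is available (codons fully inside the insertion, phase taken from
the CDS offset of the insertion point); without sequence the call is
length-only and flagged `frame_no_sequence`.  Events entirely upstream of
the CDS start are non-coding (`unknown`).

## Quantification

PSI is intron-centric, computed from junction-spanning read counts only.
Single-junction events use `i/(i+e)` against the competing canonical
junction; exon skips and pseudoexons use the balanced two-junction form
`(i₁+i₂)/(i₁+i₂+2e)` so both inclusion junctions weigh equally against the
exclusion junction.  For multi-exon skips only the two junctions flanking
the skipped block are used, matching the competing-junction logic.  A zero
denominator leaves PSI undefined for that replicate; undefined replicates
are excluded from the mean ± SD (sample SD, n−1; 0 for a single value),
never imputed as 0.  ASE% is `(1−PSI)×100` for skips/alt sites and
`PSI×100` for pseudoexons.  Reporting rounds to 2 decimals; internal
computation is full precision.

The replicate-consistency filter passes an event iff its novel junction
has ≥ `min_reads` (default 5, inclusive) in ≥ `min_samples` (default 2)
replicates.  For pseudoexons the per-replicate support is the **minimum**
of the two junction counts — the conservative reading, since the rule's
per-junction vs per-event application is not otherwise determined; the
choice is visible in the output (`support` column).

Validation arithmetic mirrors fluorescent fragment analysis: per
replicate, an isoform's ratio is its peak area over the total area of the
detected isoforms (×100; ratios sum to 100 exactly), summarized as
mean ± SD over ≥ 3 assays, and laid side by side with the sequencing
estimates (`nd` where an assay did not detect the event).

## Splice-site scoring

Site strength uses the classical weight-matrix consensus value: raw score
= Σ per-position weights of the observed bases, rescaled between the
worst and best achievable windows to 0–100.  Bundled matrices are
Shapiro–Senapathy-style percentage tables over a −3..+6 donor window and a
−13..+1 acceptor window, shipped as editable YAML: published web scorers
do not fully document their matrices and windows, so reproducing their
printed values is explicitly **not** claimed, and the scaled score is
invariant to affine rescaling of any matrix a user supplies.  Maximum-
entropy scoring is out of scope.  The NAGNAG scan tests the 6-mer spanning
−3..+3 around every canonical acceptor for two AG dinucleotides 3 nt
apart.

## Synthetic data: what it emulates

The generator's defaults are the study conditions of a targeted 454
protocol on skeletal muscle: 4 replicate libraries, 69,060 reads per
library, read length truncated-normal with mean 387 nt and SD 120 nt
(only the mean is published; 120 is typical for the chemistry), minimum
40 nt (the trimming floor), giving ≈ 2,300× mean depth on the ~11.5 kb
mRNA (≈ 1,340× at 40,000 reads, the published depth regime).  Reads start
uniformly over the isoform mRNA and are truncated at the 3′ end of the
molecule.  Errors default to 0.1% substitutions plus single-base
insertion/deletion errors at homopolymer runs ≥ 4 with probability 1% per
run — a modest 454-like regime; flow-space simulation is not attempted.
Truth SAM alignments carry an `N` operation per crossed intron, mapping
quality 60, and minimal mandatory fields.

The bundled 79-exon model pins only the published structural facts: the
39 nt and 32 nt microexons (ordinals 71 and 78), frame-neutral lengths
for the exons whose in-frame skipping is modelled (9, 73, 74), room for
the −2/−3/−60/−4 alternative acceptors (exons 20, 54, 76, 78), and
pseudoexon sizes 162/66/84 nt in introns 1, 21 and 51.  All other exon
lengths are drawn reproducibly (uniform 60–229 nt, total ≈ 11.4 kb) and
the genome sequence is random with splice-site features planted: GT..AG
boundaries and pyrimidine acceptor tracts everywhere, a CAGCAG tandem at
the exon-54 acceptor only (all other acceptors are kept NAGNAG-free), a
near-consensus alternative acceptor inside exon 76 with a deliberately
weak natural one, stop-free {C,A} interiors for the in-frame pseudoexons
and one in-frame TAA inside the 162 nt pseudoexon.  The twelve reference
events are simulated at their published mean ASE rates (0.18%–3.06%).

**Mixture approximation.**  Each simulated molecule carries at most one
event: the mixture is the canonical isoform at weight 1 − Σ rates plus one
isoform per event at its rate.  At rates ≤ 3.06% the neglected
co-occurrence terms are O(rᵢrⱼ) ≤ 9 × 10⁻⁴ and below the resolution of
every downstream statistic; per-locus rate sums > 1 are rejected.

The count-level fast path draws each event's alternative junction count
Binomial(depth, rate) per replicate and debits it from the competing
canonical junction(s); a pseudoexon's two junctions share one draw (long
reads span the whole cryptic exon).  Read-level and count-level paths
agree to within binomial sampling error, which is tested.

**What passing tests do not show.**  The simulator does not emulate
aligner behaviour (soft-clipping, mismatch tolerance near junctions),
library-preparation coverage bias, PCR chimeras, or the empirical
per-junction depth profile of real data (depth is a single knob).
Recovery results on synthetic data therefore validate the pipeline's
arithmetic and bookkeeping, not the upstream alignment quality of any
particular dataset.

## Problem sizes and determinism

Everything is deterministic under a fixed seed; per-replicate RNG streams
are derived from (seed, replicate ordinal), and identical configurations
produce byte-identical FASTA/SAM/reports.  The test suite exercises
read-level simulations at 0.3–10 k reads per library and count-level
simulations at depth 2,000 (the per-junction depth regime of the
motivating data), with 20-seed replicate-filter runs and 800-sample
parameter-recovery runs; these sizes keep the suite in well under a
minute while leaving Monte-Carlo standard errors small enough for 3-SE
assertions.  At depth 2,000 the two rarest reference events (0.18% and
0.21%) sit at the 5-read filter threshold (expected support 3.6 and 4.2
reads), so the typical filtered inventory is 11 of 12 events — the
detection-limit arithmetic made visible.

## Known limitations

* One isoform model at a time; multi-isoform gene models and the short
  dystrophin isoforms are out of scope.
* Composite events and recursive-splicing inference are not attempted.
* PWM scores are consensus values on the package's own matrices; they are
  comparable within a run, not to third-party web-server printouts.
* The replicate filter is a hard threshold, not a statistical test; no
  between-condition differential splicing is provided (none is defined
  for a single-condition inventory).
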