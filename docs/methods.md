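# Methods

## The error model

`gemsim` models sequencing errors empirically rather than parametrically.
From a SAM alignment of control reads against a known reference, every
aligned base is classified as a correct call, a mismatch, or as carrying an
insertion/deletion event after it, and the classification is conditioned
on:

* **read position** (sequencing cycle), because error rates climb toward
  the end of reads on both Illumina and pyrosequencing platforms;
* the **sequence-context word**: up to three bases preceding the current
  base, the current base itself, and one following base. The preceding
  window captures the known upstream-sequence dependence of substitution
  errors; the single following base exists specifically so that
  homopolymer indels can be placed correctly (see below);
* the **mate** (first or second read of a pair), since paired-end runs
  routinely show very different error rates on the two mates.

The current base of a word is the *true* (reference, strand-adjusted)
base; the preceding and following bases are taken from the read as
sequenced. A mismatch is therefore an observation in the true base's cell
recording which wrong base was called — this is what makes each cell's
mismatch count a clean binomial draw and what a rendering such as
`GGG**T**A -> GGG**G**A` means: at a true T in context GGG_A, a G was
called.

Each (mate, position, word) cell holds seven integer counts: correct,
mismatch→A/C/G/T, insertion events, deletion events. Alongside the cells
the model stores, per mate: insertion detail (counts of inserted strings
per word), deletion length counts per word, quality-score histograms per
(position, call class) for the classes correct/mismatch/insertion, and the
read-length histogram. Paired models add the insert-size histogram (|TLEN|
of properly paired first mates; insert size is outer end to outer end) and
the properly-paired pair counts. Quality histograms are deliberately *not*
conditioned on the context word: quality tracks the call class and cycle
well, and full conditioning would multiply memory by the word-space size
for marginal gain.

### Homopolymer indels

Aligners place an indel inside a homopolymer run arbitrarily — at its
start, middle, end, or even just before it. All placements are
normalized to the run's **last base** (the base whose following base
differs), using the indel's own base identity to decide which run it
belongs to: an indel recorded after base *p* is pulled into the run
starting at *p*+1 when its inserted/deleted base matches that run. Each
run therefore contributes at most one indel context, and simulation
mirrors the convention by drawing indel outcomes only at run-end words —
a simulated run receives at most one indel, at its end, rather than
potentially one per base.

### Sparse-context backoff

A 5-base word may simply be too rare in the control genome for its cell to
be estimable. After accumulation, every full-length word whose contiguous
5-mer occurs fewer than `x` times (default `x = 4`) in the control
reference — counted on both strands, since reads sample both — has its
cell replaced by the aggregate over all cells sharing the longest
*suffix* of the context that does occur at least `x` times. The oldest
preceding base is dropped first (`AACTG → ACTG → CTG → TG → T`); the
following base is retained as long as possible because it drives
homopolymer indel placement. The degenerate end of the chain is the
current base alone. Backoff aggregates are materialized at build time and
stored in the model file, so simulation never needs the control genome;
at simulation time a cell with zero support falls through the same chain
of stored suffix marginals.

Raw observation cells are never modified by the fill — summary statistics
are always computed from the raw counts, and well-supported cells are used
as observed.

### Known polymorphic sites

True SNPs in the control sample would otherwise be counted as recurrent
mismatches. A user-supplied list of reference positions reclassifies
mismatches at those sites as correct calls.

## Simulation

Reads are generated by the following per-read procedure (all randomness
from one seeded `numpy` generator, in this fixed order, which is the
package's byte-reproducibility contract): source genome (metagenomics
mode: probability ∝ abundance × genome length), haplotype (∝ frequency),
read length(s) and insert size (empirical histograms, or a static length),
strand (fair coin), start (uniform over starts that fit a linear genome;
uniform over all positions for circular genomes, slices wrapping the
origin), then per mate the error walk and the quality draw, with the
unaligned-mate coin flipped after placement.

The error walk visits each template base, looks up the (position, word)
cell through the backoff chain, normalizes the seven counts to
probabilities, and draws the outcome. Mismatches substitute the drawn
base; insertions append a string drawn from the word's insertion detail
(backing off along the word chain, then pooling); deletions skip template
bases with a length drawn from the deletion detail. Indel outcomes are
suppressed except at homopolymer run ends, matching model building. A
consequence worth knowing when hand-specifying flat models: the realized
genome-wide indel rate is the cell rate multiplied by the fraction of
positions that are run ends (≈ 3/4 for a uniform-composition genome).

Quality values are drawn per output base from the (position, class)
histogram, falling back to the position's correct-class histogram and
then to the pooled histogram; positions beyond the model's deepest
recorded cycle reuse the last cycle. With probability
1 − properly-paired-fraction the second mate is replaced by an
unalignable read: all Ns, every quality 2 (`#` at offset 33, `B` at
offset 64). The event never strikes the first mate.

Every read carries a truth record (genome, haplotype index, forward-strand
start of the consumed span, strand, alignment-op trace, error tokens)
written to a sidecar TSV; read names stay standard-clean
(`sim:<genome>:<i>[/1|/2]`).

## Haplotype mixtures

A haplotype set is a list of (frequency, SNP list) pairs over one genome;
frequencies must sum to 1 and each SNP's reference base is validated
against the genome, catching 0/1-based coordinate mistakes in user files
early. Generated haplotypes draw SNP positions uniformly without
replacement per haplotype (different haplotypes may collide on a site) and
alternate bases uniformly over the three non-reference bases.

## Coordinates and formats

All internal coordinates are 0-based half-open; SAM positions and the
haplotype/known-SNP dialects are converted at the I/O boundary. Soft-clipped
bases carry no model signal and are excluded; bases where read or reference
has N are excluded from all counts; IUPAC ambiguity codes other than N are
normalized to N on input and never counted as mismatches. Insert size is
read from TLEN rather than recomputed from mate positions. FASTQ output is
never wrapped. Insertions preceding the first read base are folded onto
position 0. Insertion-class quality values are recorded at the event's
attributed position rather than at each inserted base's own offset (the
offsets shift under homopolymer reattribution; the histogram is coarse in
position so the difference is at most a few cycles).

The haplotype and abundance file layouts are this package's own
definitions (the formats have no community standard): one tab-delimited
SNP per line `hap-id  frequency  pos(1-based)  ref  alt` with `.` columns
for a SNP-free haplotype, and `genome-name  abundance` respectively.

## Synthetic data and what tests show

The fixtures module generates random genomes of chosen GC content,
planted-error SAM alignments whose every introduced event is returned as
an exact truth table, and hand-specified flat-rate models. Planted
alignments place indels only at run ends so that rebuilt models recover
the generating rates; truth-perfect SAMs for simulated reads are written
directly from truth records, so round-trip tests exercise the real
builder code without an aligner. These fixtures emulate alignment
*geometry* faithfully but not real instrument profiles: no
position-dependent rate ramps unless requested, no quality-rate coupling,
no GC or coverage bias, no PCR/optical duplicates or adapter
read-through. Passing round-trips demonstrate that the accounting is
self-consistent and unbiased, not that any particular instrument is
reproduced.

## Numerical and degenerate-input choices

Counts are exact integers end to end; the model file round-trips with no
floating drift. Discrete draws use a single uniform variate against a
cumulative table (ties impossible; the last bin absorbs boundary hits).
Paired insert sizes are resampled up to 100 times until the insert fits
both the mates and a linear genome, then the run aborts with a clear
error. An empty model (no mapped reads) is fatal. Genomes shorter than k
contain no k-mers, so all 4^k are reported low-frequency. Outlier-word
scans require at least two eligible words and a nonzero standard
deviation, else return empty.

## Known limitations

* Preceding context is capped at three bases; platforms with longer-range
  effects (documented up to 10 bases upstream for some chemistries) are
  only partially captured.
* Flow-space (per-flow) signal modelling is out of scope; pyrosequencing
  homopolymer behaviour is represented only through the run-end indel
  convention and context conditioning.
* Quality values are independent of the context word given position and
  class.
* Indel length/identity detail is pooled over positions (per word only).
* Circular-genome reads that wrap the origin cannot be exported to the
  truth-perfect SAM (SAM cannot represent them as a single record).

## Problem sizes used in the shipped checks

The test suite and the reproduction script run on synthetic genomes of
1–50 kb with 10^2–10^5 reads of 40–100 bp, sizes chosen so every
statistical check has the power its tolerance needs (e.g. ≥500
observations per word for 3-SE rate checks, 10^5 reads for 4-SE fraction
checks on a 1 % haplotype).
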