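# gemsim

Empirical, sequence-context error-model based simulation of next-generation
sequencing reads.

Benchmarking an NGS analysis pipeline — a SNP caller on deep-sequenced
mixed populations, a metagenomic profiler, an assembler — needs simulated
reads whose errors look like *your* sequencing run, not like a textbook
uniform rate. Error profiles differ between platforms, between chemistry
versions, and even between runs on the same machine. `gemsim` learns an
error model directly from a SAM alignment of control reads (e.g. a PhiX
control lane) and replays it onto any genome, haplotype mixture, or
metagenome, emitting FASTQ with realistic quality scores and an exact
per-read truth record for scoring.

## The model

For every read base the model records the outcome — correct call, mismatch
to a specific base, or an insertion/deletion following the base —
conditioned on the read position *p* and the **sequence-context word**
*w*: up to three preceding bases, the current (true) base, and one
following base. Simulation draws each base's outcome from the empirical
cell distribution

> P(outcome | p, w, mate) = counts(p, w, mate) / Σ counts(p, w, mate),

with quality scores drawn from per-(position, call-class) histograms and
read lengths / insert sizes from their empirical distributions. Words
rarer than *x* times (default 4) in the control genome are *backed off*
onto the longest sufficiently frequent suffix of their context, dropping
the oldest preceding base first (AACTG → ACTG → …). The following base is
tracked so that indels inside a homopolymer are attributed — and
simulated — exactly once, at the run's last base. See
[docs/methods.md](docs/methods.md) for the full account and
[docs/model_format.md](docs/model_format.md) for the model-file layout.

## Worked example

Build a model from a (here: synthetic, planted-error) control alignment,
inspect it, and simulate reads from a 5 % / 95 % haplotype mixture:

```sh
gemsim-fixtures -o fx --length 20000 --n-reads 4000 --read-len 60 --mismatch 0.01 --seed 7
gemerr -s fx/reads.sam -r fx/genome.fa -o model.gem
gemstats -m model.gem -o report.txt
gemhaps -r fx/genome.fa -g "0.05,50 0.95,0" --seed 7 -o haps.tsv
gemreads -r fx/genome.fa -m model.gem -n 2000 -l 60 --seed 7 -g haps.tsv -o sim
```

`gemstats` reports, per mate, the overall and per-nucleotide mismatch
rates, indel rates, a per-cycle rate table, and context words whose rate
is more than 2 SD above the mean:

```
== Error model statistics (reads) ==
Overall mismatch rate (%):	0.975417
A mismatch rate (%):	0.938491
C mismatch rate (%):	0.958525
G mismatch rate (%):	0.97652
T mismatch rate (%):	1.02799
Insertion rate (%):	0
Deletion rate (%):	0
Outlier 1:	GCT**G**A -> GCT**A**A (3.59)
```

The planted generating rate was 1 % per base; the rebuilt model reads it
back as 0.975 % overall (4000 × 60 bp ≈ 2.4 × 10⁵ observations, so the
deviation is within binomial noise). `GCT**G**A -> GCT**A**A (3.59)`
means: at a true G in context GCT_A, the most frequent wrong call was A,
at a 3.59 % mismatch rate for that word.

`gemreads` writes `sim.fastq` plus a truth sidecar:

```
# seed=7
name	genome	haplotype	start	strand	aligned	cigar	errors
sim:synthetic:0	synthetic	1	11531	-	1	60M	mm:46:A>G
sim:synthetic:1	synthetic	1	15467	-	1	60M	mm:18:C>T;mm:36:C>A
```

— read 0 came from haplotype 1 (the 95 % major), maps reverse-strand at
0-based position 11531, and carries one simulated mismatch (true A read
as G at cycle 46). Paired-end mode (`-p`) writes `sim_1.fastq` /
`sim_2.fastq`, applies each mate's own sub-model, and replaces second
mates with all-N, quality-2 reads at the model's not-properly-paired
rate. Metagenomics mode (`-R genomes/ -a abundances.tsv`) picks the
source genome per read with probability ∝ abundance × genome length.

The haplotype file dialect (this package's own definition) is one
tab-delimited SNP per line — `hap-id  frequency  pos(1-based)  ref  alt`,
with `.` columns for a SNP-free haplotype; the abundance file is
`genome-name  abundance`.

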