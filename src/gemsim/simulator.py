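"""Simulate single- or paired-end FASTQ reads under an empirical error model.

Each read is produced by: drawing a read length (and, for pairs, an insert
size) from the model's empirical distributions; choosing a source genome
(metagenomics mode: probability proportional to abundance x genome size), a
haplotype (proportional to haplotype frequency), a strand and a uniform
start position; copying the template from the genome and substituting
haplotype SNPs; introducing errors base by base from the (position,
sequence-context word) cells of the model; and assigning quality scores
from the per-(position, call class) empirical histograms.  Paired-end
simulation applies the two mate sub-models to the two mates and, with
probability 1 - properly_paired_fraction, replaces the second mate with an
unalignable all-N read at quality 2.

Every read carries a truth record (source genome, haplotype, position,
strand, introduced errors, and an alignment-op trace) written to a sidecar
TSV, so downstream benchmarks can score calls exactly.

Determinism: all randomness flows through one seeded generator; the draw
order per read is fixed (genome, haplotype, read length(s) and insert,
strand, start, unaligned-mate coin, mate-1 errors, mate-1 qualities,
mate-2 errors, mate-2 qualities), so a fixed seed reproduces output byte
for byte.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .error_model import (
    BASES,
    CORRECT,
    DELETION,
    INSERTION,
    ErrorModel,
    MateModel,
)
from .haplotypes import Haplotype, HaplotypeSet, apply_haplotype
from .io_formats import (
    AbundanceTable,
    ReferenceGenome,
    reverse_complement,
    write_fastq_record,
)

#: Quality given to every base of a simulated unalignable mate
#: ('B' at offset 64, '#' at offset 33).
UNALIGNED_MATE_QUALITY = 2


@dataclass
class SimulationConfig:
    n_reads: int
    paired: bool = False
    static_read_length: int | None = None
    quality_offset: int = 33
    circular: bool = False
    seed: int = 0
    metagenomics: bool = False
    truth_output: str | Path | None = None

    def __post_init__(self) -> None:
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")
        if self.quality_offset not in (33, 64):
            raise ValueError("quality offset must be 33 or 64")


@dataclass
class ReadTruth:
    """Hidden provenance of one simulated read.

    ``start`` is the 0-based forward-strand start of the genome span the
    read consumed (modulo genome length for circular genomes); ``ops`` is
    the alignment trace in sequencing direction as (op, length) with op in
    M/I/D; ``errors`` are tokens ``mm:<pos>:<ref>><alt>``,
    ``ins:<pos>:<bases>``, ``del:<pos>:<len>`` in read coordinates.
    """

    genome: str
    haplotype: int
    start: int
    strand: str
    consumed: int
    ops: list[tuple[str, int]] = field(default_factory=list)
    errors: list[str] = field(default_factory=list)
    aligned: bool = True


@dataclass
class SimulatedRead:
    name: str
    sequence: str
    qualities: list[int]
    truth: ReadTruth


class _Discrete:
    """Sampler over a histogram, deterministic given the rng stream."""

    __slots__ = ("values", "cum")

    def __init__(self, hist: dict):
        items = sorted(hist.items())
        self.values = [v for v, _ in items]
        weights = np.array([w for _, w in items], dtype=float)
        self.cum = list(np.cumsum(weights / weights.sum()))

    def draw(self, rng: np.random.Generator):
        return self.values[min(bisect_right(self.cum, rng.random()), len(self.values) - 1)]


class _MateSampler:
    """Cached outcome/quality samplers over one mate sub-model."""

    def __init__(self, mate: MateModel):
        self.mate = mate
        self._cells: dict[tuple[int, str], _Discrete | None] = {}
        self._quals: dict[tuple[int, str], _Discrete | None] = {}
        self._global_qual: _Discrete | None = None
        g = mate.global_quality()
        if g:
            self._global_qual = _Discrete(g)
        self.max_pos = mate.max_position()
        self.length_sampler = (
            _Discrete(mate.read_length_hist) if mate.read_length_hist else None
        )

    def outcome(self, pos: int, key: str, rng: np.random.Generator) -> int:
        cache_key = (pos, key)
        s = self._cells.get(cache_key, False)
        if s is False:
            vec = self.mate.lookup(pos, key)
            s = None
            if vec is not None and vec.sum() > 0:
                s = _Discrete({i: int(n) for i, n in enumerate(vec) if n > 0})
            self._cells[cache_key] = s
        if s is None:
            return CORRECT
        return s.draw(rng)

    def quality(self, pos: int, cls: str, rng: np.random.Generator) -> int:
        pos = min(pos, self.max_pos) if self.max_pos >= 0 else pos
        cache_key = (pos, cls)
        s = self._quals.get(cache_key, False)
        if s is False:
            h = self.mate.quality_hist.get(pos, {}).get(cls)
            if not h and cls != "correct":
                h = self.mate.quality_hist.get(pos, {}).get("correct")
            s = _Discrete(h) if h else None
            self._quals[cache_key] = s
        if s is not None:
            return s.draw(rng)
        if self._global_qual is not None:
            return self._global_qual.draw(rng)
        return 0


def _insert_sampler_cache(model: ErrorModel) -> _Discrete:
    s = getattr(model, "_insert_sampler", None)
    if s is None:
        s = _Discrete(model.insert_size_hist)
        model._insert_sampler = s
    return s


def choose_genome(
    table: AbundanceTable,
    genomes: Sequence[ReferenceGenome],
    rng: np.random.Generator,
) -> ReferenceGenome:
    """Pick a genome with probability proportional to abundance x length."""
    by_name = {g.name: g for g in genomes}
    missing = [n for n, _ in table.entries if n not in by_name]
    if missing:
        raise ValueError(f"abundance table names genomes with no FASTA: {missing}")
    weights = np.array([a * len(by_name[n]) for n, a in table.entries], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("all abundance x length weights are zero")
    cum = np.cumsum(weights / weights.sum())
    idx = int(np.searchsorted(cum, rng.random(), side="right"))
    return by_name[table.entries[min(idx, len(cum) - 1)][0]]


def draw_fragment(
    genome: ReferenceGenome,
    model: ErrorModel,
    config: SimulationConfig,
    rng: np.random.Generator,
    samplers: list[_MateSampler] | None = None,
    _lengths: tuple[int, ...] | None = None,
    _insert: int | None = None,
) -> list[tuple[int, int, str]]:
    """Choose the genomic placement of one read (or read pair).

    Returns one (start, length, strand) per mate; ``start`` is the 0-based
    forward-strand start (may exceed genome length minus read length only
    for circular genomes, where slices wrap).  The mate pair spans an
    insert measured outer end to outer end; read 2 sits on the opposite
    strand, sequenced inward.
    """
    G = len(genome)
    if samplers is None:
        samplers = [_MateSampler(m) for m in model.mates]

    def read_length(mate: int) -> int:
        if config.static_read_length is not None:
            return config.static_read_length
        s = samplers[min(mate, len(samplers) - 1)].length_sampler
        if s is None:
            raise ValueError("model has no read-length distribution and no static length set")
        return s.draw(rng)

    if not config.paired:
        L = _lengths[0] if _lengths else read_length(0)
        if not config.circular and L > G:
            raise ValueError(f"read length {L} exceeds linear genome length {G}")
        strand = "+" if rng.random() < 0.5 else "-"
        start = int(rng.integers(0, G if config.circular else G - L + 1))
        return [(start, L, strand)]

    L1 = _lengths[0] if _lengths else read_length(0)
    L2 = _lengths[1] if _lengths else read_length(1)
    if _insert is not None:
        insert = _insert
    elif not model.insert_size_hist:
        raise ValueError("paired simulation needs an insert-size distribution")
    else:
        ins_sampler = _insert_sampler_cache(model)
        insert = ins_sampler.draw(rng)
        for _ in range(100):
            if insert >= max(L1, L2) and (config.circular or insert <= G):
                break
            insert = ins_sampler.draw(rng)  # resample until it fits
        else:
            raise ValueError(
                f"cannot draw an insert size in [{max(L1, L2)}, {G}] "
                "from the model distribution"
            )
    if insert < max(L1, L2) or (not config.circular and insert > G):
        raise ValueError(f"insert size {insert} incompatible with reads/genome")
    s = int(rng.integers(0, G if config.circular else G - insert + 1))
    if rng.random() < 0.5:  # first mate on the forward strand
        return [(s, L1, "+"), (s + insert - L2, L2, "-")]
    return [(s + insert - L1, L1, "-"), (s, L2, "+")]


def _template(genome: ReferenceGenome, start: int, length: int, strand: str) -> str:
    seq = genome.fetch(start, length)
    return seq if strand == "+" else reverse_complement(seq)


def _hap_for_interval(hap: Haplotype, genome_len: int, circular: bool) -> Haplotype:
    """Unroll SNPs past the origin so wrapped circular slices see them."""
    if not circular:
        return hap
    snps = list(hap.snps) + [(p + genome_len, r, a) for p, r, a in hap.snps]
    return Haplotype(hap.frequency, snps)


def introduce_errors(
    template: str,
    sampler: _MateSampler,
    rng: np.random.Generator,
) -> tuple[str, list[str], list[tuple[str, int]], list[str], int]:
    """Mutate a template according to the model.

    Walks the template in sequencing direction; at each output position the
    outcome (correct / mismatch / insertion after / deletion after) is
    drawn from the (position, context word) cell, backing off to shorter
    contexts when the cell has no support.  Indels are drawn only at
    homopolymer run ends (the base whose following base differs), matching
    the model-building attribution, so a run never receives two indels.

    Returns (sequence, per-base call classes, alignment ops, error tokens,
    template bases consumed).
    """
    out: list[str] = []
    classes: list[str] = []
    ops: list[tuple[str, int]] = []
    errors: list[str] = []

    def push_op(op: str, n: int = 1) -> None:
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + n)
        else:
            ops.append((op, n))

    t = 0
    n = len(template)
    while t < n:
        base = template[t]
        o = len(out)
        if base not in BASES:
            out.append(base)
            classes.append("correct")
            push_op("M")
            t += 1
            continue
        # context word key, inlined from context_at (hot loop)
        key = f"{template[max(0, t - 3):t]}.{base}.{template[t + 1:t + 2]}"
        outcome = sampler.outcome(o, key, rng)
        at_run_end = t + 1 >= n or template[t + 1] != base
        if outcome in (INSERTION, DELETION) and not at_run_end:
            outcome = CORRECT  # indels only at homopolymer run ends
        if outcome == CORRECT or (1 <= outcome <= 4 and BASES[outcome - 1] == base):
            out.append(base)
            classes.append("correct")
            push_op("M")
            t += 1
        elif 1 <= outcome <= 4:
            alt = BASES[outcome - 1]
            out.append(alt)
            classes.append("mismatch")
            push_op("M")
            errors.append(f"mm:{o}:{base}>{alt}")
            t += 1
        elif outcome == INSERTION:
            out.append(base)
            classes.append("correct")
            push_op("M")
            detail = sampler.mate.indel_detail(key, "insertion")
            ins = _Discrete(detail).draw(rng) if detail else str(rng.choice(list(BASES)))
            out.extend(ins)
            classes.extend("insertion" for _ in ins)
            push_op("I", len(ins))
            errors.append(f"ins:{o + 1}:{ins}")
            t += 1
        else:  # deletion
            out.append(base)
            classes.append("correct")
            push_op("M")
            detail = sampler.mate.indel_detail(key, "deletion")
            length = int(_Discrete(detail).draw(rng)) if detail else 1
            length = min(length, n - (t + 1))
            if length > 0:
                push_op("D", length)
                errors.append(f"del:{o + 1}:{length}")
            t += 1 + length
    return "".join(out), classes, ops, errors, t


def assign_qualities(
    classes: Sequence[str],
    sampler: _MateSampler,
    rng: np.random.Generator,
) -> list[int]:
    """Draw one Phred value per base from the (position, class) histograms.

    Positions beyond the model's deepest recorded cycle reuse the last
    cycle's histograms; a missing (position, class) histogram falls back to
    the position's correct-class histogram, then to the pooled histogram.
    """
    return [sampler.quality(pos, cls, rng) for pos, cls in enumerate(classes)]


def make_unaligned_mate(read_length: int) -> tuple[str, list[int]]:
    """An unalignable mate: all Ns at quality 2 (rendered 'B' at offset 64)."""
    if read_length < 1:
        raise ValueError("read length must be >= 1")
    return "N" * read_length, [UNALIGNED_MATE_QUALITY] * read_length


def simulate_reads(
    config: SimulationConfig,
    model: ErrorModel,
    genomes: Sequence[ReferenceGenome],
    abundances: AbundanceTable | None = None,
    haplotypes: HaplotypeSet | None = None,
) -> Iterator[tuple[SimulatedRead, ...]]:
    """Yield simulated reads (1-tuples) or pairs (2-tuples) with truth records."""
    if config.metagenomics:
        if abundances is None:
            raise ValueError("metagenomics mode needs an abundance table")
        if haplotypes is not None:
            raise ValueError("haplotypes are only supported in single-genome mode")
    else:
        if len(genomes) != 1:
            raise ValueError("single-genome mode takes exactly one genome")
    rng = np.random.default_rng(config.seed)
    samplers = [_MateSampler(m) for m in model.mates]
    hap_freq_cum = (
        list(np.cumsum(haplotypes.frequencies)) if haplotypes is not None else None
    )
    ppf = model.properly_paired_fraction

    # haplotypes with origin-wrapped SNP copies for circular genomes
    unrolled: dict[int, Haplotype] = {}
    if haplotypes is not None:
        G0 = len(genomes[0])
        unrolled = {
            k: _hap_for_interval(h, G0, config.circular)
            for k, h in enumerate(haplotypes.haplotypes)
        }

    for i in range(config.n_reads):
        genome = (
            choose_genome(abundances, genomes, rng) if config.metagenomics else genomes[0]
        )
        if haplotypes is not None:
            hap_idx = min(
                bisect_right(hap_freq_cum, rng.random()), len(hap_freq_cum) - 1
            )
            hap = unrolled[hap_idx]
        else:
            hap_idx, hap = 0, None
        placements = draw_fragment(genome, model, config, rng, samplers)

        mates: list[SimulatedRead] = []
        unaligned_second = (
            config.paired and len(model.mates) > 1 and rng.random() >= ppf
        )
        for mate_i, (start, L, strand) in enumerate(placements):
            suffix = f"/{mate_i + 1}" if config.paired else ""
            name = f"sim:{genome.name}:{i}{suffix}"
            if mate_i == 1 and unaligned_second:
                seq, quals = make_unaligned_mate(L)
                truth = ReadTruth(genome.name, hap_idx, start, strand, 0, [], [], aligned=False)
                mates.append(SimulatedRead(name, seq, quals, truth))
                continue
            template = _template(genome, start, L, strand)
            if hap is not None:
                template = apply_haplotype(template, (start, start + L), strand, hap)
            sampler = samplers[min(mate_i, len(samplers) - 1)]
            seq, classes, ops, errors, consumed = introduce_errors(template, sampler, rng)
            quals = assign_qualities(classes, sampler, rng)
            if strand == "+":
                span_start = start
            else:
                span_start = (start + L - consumed) % len(genome)
            truth = ReadTruth(
                genome.name, hap_idx, span_start % len(genome), strand, consumed, ops, errors
            )
            mates.append(SimulatedRead(name, seq, quals, truth))
        yield tuple(mates)


def simulate(
    config: SimulationConfig,
    model: ErrorModel,
    genomes: Sequence[ReferenceGenome],
    output_prefix: str | Path,
    abundances: AbundanceTable | None = None,
    haplotypes: HaplotypeSet | None = None,
) -> dict[str, Path]:
    """Run a simulation to FASTQ (plus a truth TSV).

    Single-end: ``<prefix>.fastq``; paired: ``<prefix>_1.fastq`` and
    ``<prefix>_2.fastq``.  The truth TSV ``<prefix>.truth.tsv`` records the
    seed and one provenance row per read.
    """
    prefix = Path(output_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    if config.paired:
        paths = {
            "fastq_1": prefix.with_name(prefix.name + "_1.fastq"),
            "fastq_2": prefix.with_name(prefix.name + "_2.fastq"),
        }
        handles = [paths["fastq_1"].open("w"), paths["fastq_2"].open("w")]
    else:
        paths = {"fastq": prefix.with_name(prefix.name + ".fastq")}
        handles = [paths["fastq"].open("w")]
    truth_path = (
        Path(config.truth_output)
        if config.truth_output
        else prefix.with_name(prefix.name + ".truth.tsv")
    )
    paths["truth"] = truth_path
    try:
        with truth_path.open("w") as truth_fh:
            truth_fh.write(f"# seed={config.seed}\n")
            truth_fh.write(
                "name\tgenome\thaplotype\tstart\tstrand\taligned\tcigar\terrors\n"
            )
            for mates in simulate_reads(config, model, genomes, abundances, haplotypes):
                for mate_i, read in enumerate(mates):
                    write_fastq_record(
                        handles[mate_i if config.paired else 0],
                        read.name,
                        read.sequence,
                        read.qualities,
                        config.quality_offset,
                    )
                    tr = read.truth
                    cigar = "".join(f"{n}{op}" for op, n in tr.ops) or "*"
                    errors = ";".join(tr.errors) or "."
                    truth_fh.write(
                        f"{read.name}\t{tr.genome}\t{tr.haplotype}\t{tr.start}\t"
                        f"{tr.strand}\t{int(tr.aligned)}\t{cigar}\t{errors}\n"
                    )
    finally:
        for h in handles:
            h.close()
    return paths
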