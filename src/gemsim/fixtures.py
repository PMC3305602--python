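"""Synthetic data generators: toy genomes, planted-error alignments, and
hand-specified error models.

Everything here is seeded and writes real files through the package's own
readers/writers, so format code is exercised by every test that uses a
fixture.  The planted-error SAM generator records every introduced event,
giving exact counting oracles for the model builder; the hand-specified
uniform model gives known generating rates for simulator round-trips.
"""

from __future__ import annotations

import os
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .error_model import (
    BASES,
    CORRECT,
    DELETION,
    INSERTION,
    MM_INDEX,
    ErrorModel,
    MateModel,
    word_key,
)
from .io_formats import ReferenceGenome, encode_quality, reverse_complement
from .simulator import SimulatedRead

# SAM flag bits
_F_PAIRED = 0x1
_F_PROPER = 0x2
_F_UNMAPPED = 0x4
_F_MATE_UNMAPPED = 0x8
_F_REVERSE = 0x10
_F_MATE_REVERSE = 0x20
_F_FIRST = 0x40
_F_SECOND = 0x80


def random_genome(
    length: int,
    gc_fraction: float = 0.5,
    seed: int | np.random.Generator = 0,
    name: str = "synthetic",
    circular: bool = False,
) -> ReferenceGenome:
    """A random genome with the given GC content, deterministic under seed."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError("gc_fraction must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = [
        (1 - gc_fraction) / 2,  # A
        gc_fraction / 2,  # C
        gc_fraction / 2,  # G
        (1 - gc_fraction) / 2,  # T
    ]
    seq = "".join(rng.choice(list("ACGT"), size=length, p=p))
    return ReferenceGenome(name, seq, circular=circular)


# ---------------------------------------------------------------------------
# Hand-specified error models

def uniform_model(
    read_length: int,
    mismatch: float = 0.0,
    insertion: float = 0.0,
    deletion: float = 0.0,
    quality_correct: int = 40,
    quality_mismatch: int = 10,
    quality_insertion: int = 20,
    paired: bool = False,
    insert_size: int | None = None,
    properly_paired: float = 1.0,
    scale: int = 3_000_000,
) -> ErrorModel:
    """An error model with the same per-base outcome rates at every cell.

    Counts are placed on (current base, following base) context words —
    the tail of every backoff chain — so any full word backs off onto them
    and observes the same rates.  Indel mass sits only on run-end contexts
    (following base differs from current, or read end), mirroring the
    attribution convention of models built from real alignments: a model
    built from data never holds indel counts inside a homopolymer run.
    Mismatches are spread evenly over the three non-reference bases;
    quality histograms are point masses per class.  ``scale`` sets the
    integer observation count realizing the rates.
    """
    if mismatch + insertion + deletion >= 1.0:
        raise ValueError("error rates must leave room for correct calls")

    def make_mate() -> MateModel:
        mate = MateModel()
        n_mm = round(mismatch * scale)
        n_ins = round(insertion * scale)
        n_del = round(deletion * scale)
        for pos in range(read_length):
            by_word: dict[str, np.ndarray] = {}
            for cur in BASES:
                for fol in list(BASES) + [""]:
                    run_end = fol != cur  # "" (read end) counts as a run end
                    vec = np.zeros(7, dtype=np.int64)
                    for b in BASES:
                        if b != cur:
                            vec[MM_INDEX[b]] = n_mm // 3
                    if run_end:
                        vec[INSERTION] = n_ins
                        vec[DELETION] = n_del
                    vec[CORRECT] = scale - vec[1:].sum()
                    by_word[word_key("", cur, fol)] = vec
            mate.counts[pos] = by_word
            mate.marginals[pos] = dict(by_word)
            mate.quality_hist[pos] = {
                "correct": Counter({quality_correct: scale}),
                "mismatch": Counter({quality_mismatch: max(n_mm, 1)}),
                "insertion": Counter({quality_insertion: max(n_ins, 1)}),
            }
        if n_ins:
            for cur in BASES:
                for fol in list(BASES) + [""]:
                    if fol != cur:
                        mate.insertion_detail[word_key("", cur, fol)] = Counter(
                            {b: 1 for b in BASES}
                        )
        if n_del:
            for cur in BASES:
                for fol in list(BASES) + [""]:
                    if fol != cur:
                        mate.deletion_detail[word_key("", cur, fol)] = Counter({1: 1})
        mate.read_length_hist[read_length] = 1
        return mate

    mates = [make_mate(), make_mate()] if paired else [make_mate()]
    model = ErrorModel(paired=paired, mates=mates)
    if paired:
        model.insert_size_hist = Counter({insert_size or 3 * read_length: 1})
        model.n_pairs = 10_000
        model.n_properly_paired = round(properly_paired * 10_000)
    return model


# ---------------------------------------------------------------------------
# Planted-error SAM alignments

@dataclass
class ErrorSpec:
    """Generating error rates for planted alignments.

    ``per_position_mismatch`` overrides the flat mismatch rate with one
    value per read position.  Indels are planted only at homopolymer run
    ends, matching the attribution convention of the model builder.
    """

    mismatch_rate: float = 0.0
    insertion_rate: float = 0.0
    deletion_rate: float = 0.0
    per_position_mismatch: list[float] | None = None
    quality_correct: int = 40
    quality_mismatch: int = 10
    quality_insertion: int = 20


@dataclass
class PlantedEvent:
    read_name: str
    kind: str  # mismatch | insertion | deletion
    read_position: int  # sequencing-direction position of the event base
    detail: str  # "ref>alt", inserted bases, or deletion length


@dataclass
class _SamRecord:
    qname: str
    flag: int
    rname: str
    pos: int  # 0-based; converted on write
    cigar: str
    seq: str
    quals: list[int]
    rnext: str = "*"
    pnext: int = -1
    tlen: int = 0


def _mutate(
    template: str,
    spec: ErrorSpec,
    rng: np.random.Generator,
    name: str,
) -> tuple[str, list[tuple[str, int]], list[int], list[PlantedEvent]]:
    """Plant errors on a template; returns (read, ops, qualities, events)."""
    out: list[str] = []
    quals: list[int] = []
    ops: list[tuple[str, int]] = []
    events: list[PlantedEvent] = []

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
        mm_rate = (
            spec.per_position_mismatch[min(o, len(spec.per_position_mismatch) - 1)]
            if spec.per_position_mismatch is not None
            else spec.mismatch_rate
        )
        at_run_end = t + 1 >= n or template[t + 1] != base
        r = rng.random()
        if r < mm_rate:
            alt = str(rng.choice([b for b in BASES if b != base]))
            out.append(alt)
            quals.append(spec.quality_mismatch)
            push_op("M")
            events.append(PlantedEvent(name, "mismatch", o, f"{base}>{alt}"))
            t += 1
        elif at_run_end and r < mm_rate + spec.insertion_rate:
            out.append(base)
            quals.append(spec.quality_correct)
            push_op("M")
            ins = str(rng.choice(list(BASES)))
            out.append(ins)
            quals.append(spec.quality_insertion)
            push_op("I")
            events.append(PlantedEvent(name, "insertion", o + 1, ins))
            t += 1
        elif at_run_end and r < mm_rate + spec.insertion_rate + spec.deletion_rate and t + 1 < n:
            out.append(base)
            quals.append(spec.quality_correct)
            push_op("M")
            push_op("D")
            events.append(PlantedEvent(name, "deletion", o + 1, "1"))
            t += 2
        else:
            out.append(base)
            quals.append(spec.quality_correct)
            push_op("M")
            t += 1
    return "".join(out), ops, quals, events


def _to_sam_orientation(
    read: str, ops: list[tuple[str, int]], quals: list[int], reverse: bool
) -> tuple[str, str, list[int]]:
    if reverse:
        read = reverse_complement(read)
        quals = list(reversed(quals))
        ops = list(reversed(ops))
    cigar = "".join(f"{l}{op}" for op, l in ops)
    return read, cigar, quals


def planted_alignment(
    genome: ReferenceGenome,
    n_reads: int,
    read_len: int,
    spec: ErrorSpec,
    path: str | os.PathLike,
    paired: bool = False,
    insert_size: int | None = None,
    properly_paired: float = 1.0,
    seed: int = 0,
) -> list[PlantedEvent]:
    """Write a SAM of reads with planted errors; return the truth events.

    Reads (or pairs) are placed uniformly on the linear genome, half on
    each strand (mate 1 forward, mate 2 reverse for pairs).  With
    probability ``1 - properly_paired`` the second mate is emitted as an
    unmapped record.  The returned event list is exact: the SAM differs
    from the reference at exactly those coordinates.
    """
    rng = np.random.default_rng(seed)
    G = len(genome)
    records: list[_SamRecord] = []
    truth: list[PlantedEvent] = []
    if paired:
        insert_size = insert_size or min(3 * read_len, G)
        if insert_size > G or insert_size < read_len:
            raise ValueError("insert size incompatible with genome/read length")
    elif read_len > G:
        raise ValueError("read length exceeds genome length")

    for i in range(n_reads):
        if not paired:
            start = int(rng.integers(0, G - read_len + 1))
            reverse = bool(rng.random() < 0.5)
            template = genome.fetch(start, read_len)
            if reverse:
                template = reverse_complement(template)
            name = f"planted:{i}"
            read, ops, quals, events = _mutate(template, spec, rng, name)
            truth.extend(events)
            seq, cigar, squals = _to_sam_orientation(read, ops, quals, reverse)
            # reverse reads: template consumed from the 3' end of the span
            consumed = sum(l for op, l in ops if op in "MD")
            pos = start if not reverse else start + read_len - consumed
            records.append(
                _SamRecord(name, _F_REVERSE if reverse else 0, genome.name, pos, cigar, seq, squals)
            )
        else:
            start = int(rng.integers(0, G - insert_size + 1))
            mate2_mapped = bool(rng.random() < properly_paired)
            name = f"planted:{i}"
            # mate 1: forward at the fragment's left end
            t1 = genome.fetch(start, read_len)
            read1, ops1, quals1, ev1 = _mutate(t1, spec, rng, name + "/1")
            truth.extend(ev1)
            seq1, cigar1, squals1 = _to_sam_orientation(read1, ops1, quals1, False)
            # mate 2: reverse at the right end
            start2 = start + insert_size - read_len
            t2 = reverse_complement(genome.fetch(start2, read_len))
            read2, ops2, quals2, ev2 = _mutate(t2, spec, rng, name + "/2")
            seq2, cigar2, squals2 = _to_sam_orientation(read2, ops2, quals2, True)
            consumed2 = sum(l for op, l in ops2 if op in "MD")
            pos2 = start2 + read_len - consumed2
            if mate2_mapped:
                truth.extend(ev2)
                f1 = _F_PAIRED | _F_PROPER | _F_FIRST | _F_MATE_REVERSE
                f2 = _F_PAIRED | _F_PROPER | _F_SECOND | _F_REVERSE
                records.append(
                    _SamRecord(name, f1, genome.name, start, cigar1, seq1, squals1,
                               rnext="=", pnext=pos2, tlen=insert_size)
                )
                records.append(
                    _SamRecord(name, f2, genome.name, pos2, cigar2, seq2, squals2,
                               rnext="=", pnext=start, tlen=-insert_size)
                )
            else:
                f1 = _F_PAIRED | _F_FIRST | _F_MATE_UNMAPPED
                f2 = _F_PAIRED | _F_SECOND | _F_UNMAPPED
                records.append(
                    _SamRecord(name, f1, genome.name, start, cigar1, seq1, squals1)
                )
                records.append(
                    _SamRecord(name, f2, "*", -1, "*", "N" * read_len,
                               [2] * read_len)
                )
    write_sam(path, {genome.name: G}, records)
    return truth


def write_sam(
    path: str | os.PathLike,
    references: dict[str, int],
    records: list[_SamRecord],
) -> None:
    """Plain-text SAM writer for fixture alignments."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name, length in references.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for r in records:
            qual = encode_quality(r.quals, 33) if r.quals else "*"
            pos1 = r.pos + 1 if r.pos >= 0 else 0
            pnext1 = r.pnext + 1 if r.pnext >= 0 else 0
            fh.write(
                f"{r.qname}\t{r.flag}\t{r.rname}\t{pos1}\t"
                f"{60 if not (r.flag & _F_UNMAPPED) else 0}\t{r.cigar}\t"
                f"{r.rnext}\t{pnext1}\t{r.tlen}\t{r.seq}\t{qual}\n"
            )


def truth_to_sam(
    reads: list[tuple[SimulatedRead, ...]],
    genome: ReferenceGenome,
    path: str | os.PathLike,
) -> None:
    """Write a truth-perfect SAM for simulated reads (linear genomes only).

    Placement, strand and per-base ops come straight from each read's truth
    record, so the alignment is exact by construction — no aligner runs.
    Reads wrapping a circular origin cannot be represented and raise.
    """
    G = len(genome)
    records: list[_SamRecord] = []
    for mates in reads:
        paired = len(mates) == 2
        for mate_i, read in enumerate(mates):
            tr = read.truth
            flag = 0
            if paired:
                flag |= _F_PAIRED | (_F_FIRST if mate_i == 0 else _F_SECOND)
                other = mates[1 - mate_i].truth
                if tr.aligned and other.aligned:
                    flag |= _F_PROPER
                    if other.strand == "-":
                        flag |= _F_MATE_REVERSE
                elif not other.aligned:
                    flag |= _F_MATE_UNMAPPED
            if not tr.aligned:
                flag |= _F_UNMAPPED
                records.append(
                    _SamRecord(read.name.rsplit("/", 1)[0], flag, "*", -1, "*",
                               read.sequence, list(read.qualities))
                )
                continue
            if tr.start + tr.consumed > G:
                raise ValueError(
                    f"read {read.name} wraps the circular origin; cannot emit SAM"
                )
            reverse = tr.strand == "-"
            if reverse:
                flag |= _F_REVERSE
            seq, cigar, quals = _to_sam_orientation(
                read.sequence, list(tr.ops), list(read.qualities), reverse
            )
            tlen = 0
            rnext, pnext = "*", -1
            if paired and (flag & _F_PROPER):
                other = mates[1 - mate_i].truth
                rnext, pnext = "=", other.start
                left = min(tr.start, other.start)
                right = max(tr.start + tr.consumed, other.start + other.consumed)
                tlen = (right - left) if tr.start <= other.start else -(right - left)
            records.append(
                _SamRecord(read.name.rsplit("/", 1)[0], flag, genome.name, tr.start,
                           cigar, seq, quals, rnext=rnext, pnext=pnext, tlen=tlen)
            )
    write_sam(path, {genome.name: G}, records)


def write_fasta(path: str | os.PathLike, genomes: list[ReferenceGenome]) -> None:
    """Write genomes as an uncompressed, unwrapped FASTA file."""
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.name}\n{g.sequence}\n")
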