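"""Build an empirical error model from a SAM alignment of control reads.

Every aligned read is walked against the reference via its CIGAR (MD tags
are ignored), each base classified as correct / mismatch / insertion /
deletion within its sequence-context word, and the counts accumulated into
an :class:`~gemsim.error_model.ErrorModel`.  Events are recorded in
*sequencing* orientation: reverse-strand alignments are reverse-complemented
first so that read position means sequencing cycle.

Indels inside a homopolymer run are attributed to the run's last base (the
base whose following base differs).  Aligners place such indels arbitrarily
within the run; normalizing to the run end means each run contributes at
most one indel context, and lets simulation place indels only once per
homopolymer rather than potentially at every base of the run.

Known polymorphic sites can be excluded: mismatches at those reference
positions are reclassified as correct calls.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .error_model import (
    CORRECT,
    DELETION,
    INSERTION,
    MM_INDEX,
    ContextWord,
    ErrorModel,
    MateModel,
    context_at,
    fill_sparse_contexts,
)
from .io_formats import AlignedRead, ReferenceGenome, reverse_complement

# pysam CIGAR op codes
_OP_M, _OP_I, _OP_D, _OP_N, _OP_S, _OP_H, _OP_P, _OP_EQ, _OP_X = range(9)

_ACGT = frozenset("ACGT")


@dataclass
class BaseEvent:
    """One classified observation at a read position (sequencing direction).

    ``kind`` is one of correct / mismatch / insertion / deletion.
    ``observed`` carries the mismatched base, the inserted string, or the
    deletion length.  ``quality`` is the base's Phred value (a tuple, one
    per inserted base, for insertions; None for deletions).
    """

    read_position: int
    word: ContextWord
    kind: str
    observed: str | int | None = None
    quality: int | tuple | None = None


@dataclass
class BuildOptions:
    known_snp_positions: set[int] = field(default_factory=set)
    x: int = 4
    paired: bool = False

    def __post_init__(self) -> None:
        if self.x < 1:
            raise ValueError("minimum word support x must be >= 1")


def _alignment_columns(read: AlignedRead) -> list[tuple[int | None, int | None]]:
    """(query index, reference index) pairs in SAM orientation.

    Insertions have reference index None; deletions have query index None.
    Soft-clipped bases are excluded entirely; hard clips and pads ignored.
    """
    cols: list[tuple[int | None, int | None]] = []
    q, r = 0, read.position
    for op, length in read.cigar:
        if op in (_OP_M, _OP_EQ, _OP_X):
            cols.extend((q + i, r + i) for i in range(length))
            q += length
            r += length
        elif op == _OP_I:
            cols.extend((q + i, None) for i in range(length))
            q += length
        elif op in (_OP_D, _OP_N):
            if op == _OP_D:
                cols.extend((None, r + i) for i in range(length))
            r += length
        elif op == _OP_S:
            q += length
        # H, P consume nothing we track
    return cols


def _run_end(seq: str, pos: int) -> int:
    """Last index of the homopolymer run of seq[pos] containing pos."""
    base = seq[pos]
    end = pos
    while end + 1 < len(seq) and seq[end + 1] == base:
        end += 1
    return end


def classify_read(
    read: AlignedRead, reference: ReferenceGenome, opts: BuildOptions | None = None
) -> list[BaseEvent]:
    """Classify every aligned base of one read in sequencing orientation."""
    if opts is None:
        opts = BuildOptions()
    if not read.mapped:
        raise ValueError(f"read {read.query_name!r} is unmapped")
    if read.query_consumed() != len(read.sequence):
        raise ValueError(
            f"read {read.query_name!r}: CIGAR consumes {read.query_consumed()} "
            f"query bases but SEQ has {len(read.sequence)}"
        )

    L = len(read.sequence)
    if read.reverse:
        seq = reverse_complement(read.sequence)
        quals = list(reversed(read.qualities)) if read.qualities else [0] * L
    else:
        seq = read.sequence
        quals = list(read.qualities) if read.qualities else [0] * L

    ref = reference.sequence
    known = opts.known_snp_positions
    events: list[BaseEvent] = []

    def to_seq_pos(q: int) -> int:
        return L - 1 - q if read.reverse else q

    # match/mismatch columns.  The context word's current base is the TRUE
    # (reference) base — a mismatch is an observation of the true base's
    # cell, recording which wrong base was called — while the preceding and
    # following bases are taken from the read as sequenced.
    cols = _alignment_columns(read)
    for qi, ri in cols:
        if qi is None or ri is None:
            continue
        p = to_seq_pos(qi)
        base = seq[p]
        refbase = ref[ri] if 0 <= ri < len(ref) else "N"
        if read.reverse:
            refbase = reverse_complement(refbase)
        if base not in _ACGT or refbase not in _ACGT:
            continue  # N carries no error semantics
        if base == refbase or ri in known:
            kind, obs = "correct", None
        else:
            kind, obs = "mismatch", base
        word = ContextWord(seq[max(0, p - 3) : p], refbase, seq[p + 1 : p + 2])
        events.append(BaseEvent(p, word, kind, obs, quals[p]))

    # indel blocks: contiguous runs of insertion / deletion columns
    i = 0
    while i < len(cols):
        qi, ri = cols[i]
        if qi is not None and ri is None:  # insertion block
            j = i
            while j + 1 < len(cols) and cols[j + 1][1] is None and cols[j + 1][0] is not None:
                j += 1
            q0, q1 = cols[i][0], cols[j][0]
            if read.reverse:
                ins_bases = reverse_complement(read.sequence[q0 : q1 + 1])
                ins_quals = tuple(reversed(read.qualities[q0 : q1 + 1])) if read.qualities else ()
                follows = L - 1 - (q1 + 1)
            else:
                ins_bases = read.sequence[q0 : q1 + 1]
                ins_quals = tuple(read.qualities[q0 : q1 + 1]) if read.qualities else ()
                follows = q0 - 1
            _attach_indel(events, seq, follows, "insertion", ins_bases, ins_quals,
                          ins_bases[0] if ins_bases else "")
            i = j + 1
        elif qi is None:  # deletion block
            j = i
            while j + 1 < len(cols) and cols[j + 1][0] is None:
                j += 1
            length = j - i + 1
            del_bases = ref[cols[i][1] : cols[j][1] + 1]
            if read.reverse:
                del_bases = reverse_complement(del_bases)
            # query positions flanking the deletion
            prev_q = next((c[0] for c in reversed(cols[:i]) if c[0] is not None), None)
            next_q = next((c[0] for c in cols[j + 1 :] if c[0] is not None), None)
            if read.reverse:
                follows = L - 1 - next_q if next_q is not None else -1
            else:
                follows = prev_q if prev_q is not None else -1
            _attach_indel(events, seq, follows, "deletion", length, None,
                          del_bases[0] if del_bases else "")
            i = j + 1
        else:
            i += 1

    events.sort(key=lambda e: e.read_position)
    return events


def _attach_indel(events, seq, follows, kind, observed, quality, unit_base) -> None:
    """Attribute an indel to the end of the homopolymer run it belongs to.

    ``follows`` is the sequenced position the indel comes after (-1 when it
    precedes the read's first base, in which case it is folded forward onto
    position 0); ``unit_base`` is the inserted (first) or deleted (first,
    strand-adjusted) base.  Aligners place an indel anywhere within a
    homopolymer run — even just before it — so when ``unit_base`` matches
    the run starting one base later, the event is pulled into that run;
    the final position is always the run's last base (the base whose
    following base differs), making the attribution placement-invariant.
    """
    pos = max(follows, 0)
    if pos >= len(seq):
        pos = len(seq) - 1
    if unit_base and seq[pos] != unit_base and pos + 1 < len(seq) and seq[pos + 1] == unit_base:
        pos += 1
    pos = _run_end(seq, pos)
    if seq[pos] not in _ACGT:
        return
    events.append(BaseEvent(pos, context_at(seq, pos), kind, observed, quality))


def build_model(
    alignments: Iterable[AlignedRead],
    reference: ReferenceGenome,
    opts: BuildOptions | None = None,
) -> ErrorModel:
    """Accumulate an error model from a stream of aligned reads.

    Unmapped reads contribute only to pairing statistics.  After
    accumulation the sparse-context backoff fill is applied with the
    configured minimum word support.
    """
    if opts is None:
        opts = BuildOptions()
    model = ErrorModel(paired=opts.paired, min_word_count=opts.x)
    n_mapped = 0
    n_skipped = 0

    for read in alignments:
        if opts.paired and read.paired and read.is_first_in_pair:
            model.n_pairs += 1
            if read.mapped and read.mate_mapped:
                model.n_properly_paired += 1
                if read.template_length != 0:
                    model.insert_size_hist[abs(read.template_length)] += 1
        if not read.mapped:
            continue
        mate = model.mates[0 if (not opts.paired or read.is_first_in_pair) else 1]
        try:
            events = classify_read(read, reference, opts)
        except ValueError:
            n_skipped += 1
            continue
        n_mapped += 1
        model.total_reads += 1
        mate.read_length_hist[len(read.sequence)] += 1
        for ev in events:
            vec = mate.cell(ev.read_position, ev.word.key)
            if ev.kind == "correct":
                vec[CORRECT] += 1
                mate.add_quality(ev.read_position, "correct", int(ev.quality))
            elif ev.kind == "mismatch":
                vec[MM_INDEX[ev.observed]] += 1
                mate.add_quality(ev.read_position, "mismatch", int(ev.quality))
            elif ev.kind == "insertion":
                vec[INSERTION] += 1
                mate.insertion_detail.setdefault(ev.word.key, Counter())[ev.observed] += 1
                for q in ev.quality or ():
                    mate.add_quality(ev.read_position, "insertion", int(q))
            elif ev.kind == "deletion":
                vec[DELETION] += 1
                mate.deletion_detail.setdefault(ev.word.key, Counter())[int(ev.observed)] += 1

    if n_mapped == 0:
        raise ValueError("empty model: no mapped reads in input")
    fill_sparse_contexts(model, reference, opts.x)
    return model
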