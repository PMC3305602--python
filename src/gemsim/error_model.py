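"""The empirical sequencing error model.

Errors are conditioned on the *sequence-context word* — a window of up to
three bases before the current base, the current base itself, and one base
after it — and on the base's position (cycle) within the read.  Each
(position, word) cell holds counts of correct calls, mismatches to each
nucleotide, and insertion/deletion events following the base.  Words too
rare in the control reference to be estimated reliably are *backed off*: the
cell is replaced by the aggregate over all words sharing the longest
sufficiently frequent sub-context, dropping the oldest preceding base first
(AACTG -> (A)ACTG -> ACTG and so on down to the current base alone).

Quality scores are tracked per (position, call class) — correct, mismatch or
inserted base — independently of the context word.  Read lengths, insert
sizes and the properly-paired fraction round out the model; paired-end
models keep one sub-model per mate.
"""

from __future__ import annotations

import gzip
import json
import os
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

FORMAT_VERSION = "gemsim-model/1"

BASES = "ACGT"

# Cell layout: [correct, mm->A, mm->C, mm->G, mm->T, insertion, deletion]
N_OUTCOMES = 7
CORRECT = 0
MM_INDEX = {b: i + 1 for i, b in enumerate(BASES)}
INSERTION = 5
DELETION = 6

#: Call classes used for quality-score histograms.
QUALITY_CLASSES = ("correct", "mismatch", "insertion")


@dataclass(frozen=True)
class ContextWord:
    """The sequence-context window around one read base.

    ``preceding`` is up to three bases ending just before the current base
    (shorter near the read start); ``following`` is the next base or empty
    at the read end.
    """

    preceding: str
    current: str
    following: str

    def __post_init__(self) -> None:
        if len(self.current) != 1:
            raise ValueError("current must be a single base")
        if len(self.preceding) > 3 or len(self.following) > 1:
            raise ValueError("context window is at most 3 preceding + 1 following")

    @property
    def key(self) -> str:
        return f"{self.preceding}.{self.current}.{self.following}"

    @property
    def text(self) -> str:
        """The word as a contiguous substring of the read."""
        return self.preceding + self.current + self.following

    def __len__(self) -> int:
        return len(self.text)


def context_at(read_sequence: str, index: int) -> ContextWord:
    """Context word at a 0-based position of a read.

    Near the read start the preceding window truncates; at the last base the
    following base is absent.
    """
    if not 0 <= index < len(read_sequence):
        raise IndexError(f"index {index} outside read of length {len(read_sequence)}")
    return ContextWord(
        preceding=read_sequence[max(0, index - 3) : index],
        current=read_sequence[index],
        following=read_sequence[index + 1 : index + 2],
    )


def word_key(preceding: str, current: str, following: str) -> str:
    return f"{preceding}.{current}.{following}"


def shorten_key(key: str) -> str | None:
    """Drop the oldest preceding base of a word key; None if nothing to drop.

    The chain for a full-length word is 3 -> 2 -> 1 -> 0 preceding bases,
    then the following base is dropped, leaving the current base alone.
    """
    pre, cur, fol = key.split(".")
    if pre:
        return f"{pre[1:]}.{cur}.{fol}"
    if fol:
        return f".{cur}."
    return None


def backoff_chain(key: str) -> list[str]:
    """The word key followed by its successive backoff shortenings."""
    chain = [key]
    k: str | None = key
    while (k := shorten_key(k)) is not None:
        chain.append(k)
    return chain


@dataclass
class MateModel:
    """Error model for one mate (or for single-end reads)."""

    # pos -> word key -> length-7 outcome count vector
    counts: dict[int, dict[str, np.ndarray]] = field(default_factory=dict)
    # word key -> Counter over inserted strings / deletion lengths
    insertion_detail: dict[str, Counter] = field(default_factory=dict)
    deletion_detail: dict[str, Counter] = field(default_factory=dict)
    # pos -> class -> Counter over Phred values
    quality_hist: dict[int, dict[str, Counter]] = field(default_factory=dict)
    read_length_hist: Counter = field(default_factory=Counter)
    # Backoff-filled cells for reference-rare full-length words (pos -> key -> vector)
    filled: dict[int, dict[str, np.ndarray]] = field(default_factory=dict)
    # Suffix-aggregated cells for every shortened word (pos -> key -> vector)
    marginals: dict[int, dict[str, np.ndarray]] = field(default_factory=dict)

    # -- accumulation -------------------------------------------------------
    def cell(self, pos: int, key: str) -> np.ndarray:
        by_word = self.counts.setdefault(pos, {})
        vec = by_word.get(key)
        if vec is None:
            vec = by_word[key] = np.zeros(N_OUTCOMES, dtype=np.int64)
        return vec

    def add_quality(self, pos: int, cls: str, q: int) -> None:
        self.quality_hist.setdefault(pos, {}).setdefault(cls, Counter())[q] += 1

    # -- aggregate views ----------------------------------------------------
    def total_vector(self) -> np.ndarray:
        tot = np.zeros(N_OUTCOMES, dtype=np.int64)
        for by_word in self.counts.values():
            for vec in by_word.values():
                tot += vec
        return tot

    def n_classified(self) -> int:
        """Number of classified base observations (correct + mismatch)."""
        t = self.total_vector()
        return int(t[CORRECT] + t[1:5].sum())

    def max_position(self) -> int:
        return max(self.counts, default=-1)

    def global_quality(self) -> Counter:
        g: Counter = Counter()
        for by_cls in self.quality_hist.values():
            for h in by_cls.values():
                g.update(h)
        return g

    # -- backoff lookup -----------------------------------------------------
    def lookup(self, pos: int, key: str) -> np.ndarray | None:
        """Cell for (pos, word) with build-time backoff applied.

        Order: backoff-filled cell (reference-rare full word), observed
        cell, then successively shortened marginal cells.  Returns None when
        nothing has support.
        """
        vec = self.filled.get(pos, {}).get(key)
        if vec is not None and vec.sum() > 0:
            return vec
        vec = self.counts.get(pos, {}).get(key)
        if vec is not None and vec.sum() > 0:
            return vec
        marg = self.marginals.get(pos)
        if marg is not None:
            k: str | None = key
            while (k := shorten_key(k)) is not None:
                vec = marg.get(k)
                if vec is not None and vec.sum() > 0:
                    return vec
        return None

    def indel_detail(self, key: str, kind: str) -> Counter | None:
        """Insertion/deletion detail for a word, backing off along the chain."""
        table = self.insertion_detail if kind == "insertion" else self.deletion_detail
        for k in backoff_chain(key):
            c = table.get(k)
            if c:
                return c
        # marginal over everything
        merged: Counter = Counter()
        for c in table.values():
            merged.update(c)
        return merged or None


@dataclass
class ErrorModel:
    """Position- and context-conditioned empirical error model."""

    paired: bool = False
    mates: list[MateModel] = field(default_factory=lambda: [MateModel()])
    insert_size_hist: Counter = field(default_factory=Counter)
    n_pairs: int = 0
    n_properly_paired: int = 0
    total_reads: int = 0
    min_word_count: int = 4  # minimum reference support x for a context word

    def __post_init__(self) -> None:
        if self.paired and len(self.mates) == 1:
            self.mates.append(MateModel())

    @property
    def properly_paired_fraction(self) -> float:
        if self.n_pairs == 0:
            return 1.0
        return self.n_properly_paired / self.n_pairs


# ---------------------------------------------------------------------------
# k-mer support counting and sparse-context backoff

def kmer_occurrences(sequence: str, k: int, circular: bool = False,
                     both_strands: bool = False) -> Counter:
    """Count overlapping occurrences of every k-mer over {A,C,G,T}.

    Windows containing N (or any non-ACGT character) are ignored.  Circular
    sequences wrap across the origin.  With ``both_strands`` the reverse
    complement is scanned too (occurrences summed).
    """
    from .io_formats import reverse_complement

    counts: Counter = Counter()
    seqs = [sequence]
    if both_strands:
        seqs.append(reverse_complement(sequence))
    valid = frozenset(BASES)
    for seq in seqs:
        scan = seq + seq[: k - 1] if circular and len(seq) >= k else seq
        n = len(seq) if circular and len(seq) >= k else len(scan) - k + 1
        for i in range(max(n, 0)):
            w = scan[i : i + k]
            if set(w) <= valid:
                counts[w] += 1
    return counts


def count_low_frequency_kmers(genome, k: int, x: int = 4,
                              both_strands: bool = False) -> int:
    """Number of k-mers over {A,C,G,T} occurring fewer than ``x`` times.

    Counts on the forward strand by default (set ``both_strands`` to scan
    both); circular genomes wrap across the origin.  A genome shorter than
    k contains no k-mers, so all 4**k are low-frequency.
    """
    if not 1 <= k <= 8:
        raise ValueError("k must be in [1, 8]")
    seq = genome.sequence if hasattr(genome, "sequence") else genome
    circular = getattr(genome, "circular", False)
    if len(seq) < k:
        return 4 ** k
    occ = kmer_occurrences(seq, k, circular=circular, both_strands=both_strands)
    n_supported = sum(1 for c in occ.values() if c >= x)
    return 4 ** k - n_supported


def _suffix_marginals(by_word: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Aggregate cells over every shortened form of their word."""
    marg: dict[str, np.ndarray] = {}
    for key, vec in by_word.items():
        k: str | None = key
        while (k := shorten_key(k)) is not None:
            acc = marg.get(k)
            if acc is None:
                marg[k] = vec.copy()
            else:
                acc += vec
    return marg


def fill_sparse_contexts(model: ErrorModel, reference, x: int | None = None) -> ErrorModel:
    """Back off reference-rare context words onto their longest frequent sub-context.

    For every full-length word (3 preceding + current + following) whose
    contiguous 5-mer occurs fewer than ``x`` times in the control reference
    (both strands — reads are sampled from both), the cell at each read
    position is replaced by the aggregate over all cells whose word ends in
    the longest shortened form that does occur at least ``x`` times.  Cells
    of well-supported words are left untouched.  Also materializes the
    suffix-marginal tables used for zero-support lookups at simulation time.
    """
    if x is None:
        x = model.min_word_count
    seq = reference.sequence if hasattr(reference, "sequence") else reference
    circular = getattr(reference, "circular", False)
    occ = {
        k: kmer_occurrences(seq, k, circular=circular, both_strands=True)
        for k in range(1, 6)
    }

    # For each full word, the shortened key chosen by the backoff rule
    # (None if the word itself is well supported).
    target: dict[str, str | None] = {}
    for b1 in BASES:
        for b2 in BASES:
            for b3 in BASES:
                for cur in BASES:
                    for fol in BASES:
                        pre = b1 + b2 + b3
                        key = word_key(pre, cur, fol)
                        if occ[5][pre + cur + fol] >= x:
                            target[key] = None
                            continue
                        chosen = word_key("", cur, "")  # degenerate fallback
                        for short in backoff_chain(key)[1:]:
                            p, c, f = short.split(".")
                            if occ[len(p + c + f)][p + c + f] >= x:
                                chosen = short
                                break
                        target[key] = chosen

    for mate in model.mates:
        mate.marginals = {
            pos: _suffix_marginals(by_word) for pos, by_word in mate.counts.items()
        }
        mate.filled = {}
        for pos, marg in mate.marginals.items():
            filled_here: dict[str, np.ndarray] = {}
            for key, chosen in target.items():
                if chosen is None:
                    continue
                vec = marg.get(chosen)
                if vec is not None and vec.sum() > 0:
                    filled_here[key] = vec
            if filled_here:
                mate.filled[pos] = filled_here
    return model


# ---------------------------------------------------------------------------
# Serialization: gzip-compressed JSON, exact integer counts.
# Layout documented in docs/model_format.md.

def _counter_to_json(c: Counter) -> dict:
    return {str(k): int(v) for k, v in sorted(c.items())}


def _mate_to_json(m: MateModel) -> dict:
    return {
        "counts": {
            str(pos): {k: [int(x) for x in vec] for k, vec in sorted(bw.items())}
            for pos, bw in sorted(m.counts.items())
        },
        "insertion_detail": {
            k: _counter_to_json(c) for k, c in sorted(m.insertion_detail.items())
        },
        "deletion_detail": {
            k: _counter_to_json(c) for k, c in sorted(m.deletion_detail.items())
        },
        "quality_hist": {
            str(pos): {cls: _counter_to_json(h) for cls, h in sorted(bc.items())}
            for pos, bc in sorted(m.quality_hist.items())
        },
        "read_length_hist": _counter_to_json(m.read_length_hist),
        "filled": {
            str(pos): {k: [int(x) for x in vec] for k, vec in sorted(bw.items())}
            for pos, bw in sorted(m.filled.items())
        },
        "marginals": {
            str(pos): {k: [int(x) for x in vec] for k, vec in sorted(bw.items())}
            for pos, bw in sorted(m.marginals.items())
        },
    }


def _mate_from_json(d: dict) -> MateModel:
    def vecs(dd):
        return {
            int(pos): {k: np.array(v, dtype=np.int64) for k, v in bw.items()}
            for pos, bw in dd.items()
        }

    return MateModel(
        counts=vecs(d["counts"]),
        insertion_detail={k: Counter(c) for k, c in d["insertion_detail"].items()},
        deletion_detail={
            k: Counter({int(l): n for l, n in c.items()})
            for k, c in d["deletion_detail"].items()
        },
        quality_hist={
            int(pos): {
                cls: Counter({int(q): n for q, n in h.items()}) for cls, h in bc.items()
            }
            for pos, bc in d["quality_hist"].items()
        },
        read_length_hist=Counter({int(k): v for k, v in d["read_length_hist"].items()}),
        filled=vecs(d["filled"]),
        marginals=vecs(d["marginals"]),
    )


def save_model(model: ErrorModel, path: str | os.PathLike) -> None:
    doc = {
        "format": FORMAT_VERSION,
        "paired": model.paired,
        "mates": [_mate_to_json(m) for m in model.mates],
        "insert_size_hist": _counter_to_json(model.insert_size_hist),
        "n_pairs": model.n_pairs,
        "n_properly_paired": model.n_properly_paired,
        "total_reads": model.total_reads,
        "min_word_count": model.min_word_count,
    }
    with gzip.open(path, "wt", encoding="utf-8") as fh:
        json.dump(doc, fh, separators=(",", ":"))


def load_model(path: str | os.PathLike) -> ErrorModel:
    try:
        with gzip.open(path, "rt", encoding="utf-8") as fh:
            doc = json.load(fh)
    except (OSError, EOFError, json.JSONDecodeError) as e:
        raise ValueError(f"cannot read model file {path}: {e}") from e
    version = doc.get("format")
    if version != FORMAT_VERSION:
        raise ValueError(
            f"model file {path}: format version {version!r}, expected {FORMAT_VERSION!r}"
        )
    return ErrorModel(
        paired=doc["paired"],
        mates=[_mate_from_json(m) for m in doc["mates"]],
        insert_size_hist=Counter({int(k): v for k, v in doc["insert_size_hist"].items()}),
        n_pairs=doc["n_pairs"],
        n_properly_paired=doc["n_properly_paired"],
        total_reads=doc["total_reads"],
        min_word_count=doc["min_word_count"],
    )
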