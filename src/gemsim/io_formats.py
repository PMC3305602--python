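"""Readers and writers for the standard formats the simulator touches.

FASTA genomes and SAM alignments come in through ``biopython`` and ``pysam``
respectively; FASTQ, haplotype, abundance and known-SNP files are simple
line-oriented text handled here directly.

Coordinate convention: every on-disk format that is 1-based (SAM POS,
haplotype and known-SNP files) is converted at the I/O boundary; all
in-memory coordinates are 0-based half-open.
"""

from __future__ import annotations

import os
import re
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence, TextIO

import pysam
from Bio import SeqIO

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Characters accepted in a normalized reference sequence.
VALID_BASES = frozenset("ACGTN")

#: CIGAR operations that consume query sequence (pysam op codes).
_QUERY_CONSUMING = {0, 1, 4, 7, 8}  # M, I, S, =, X


def reverse_complement(seq: str) -> str:
    """Reverse-complement a nucleotide string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ReferenceGenome:
    """A named nucleotide sequence with a circular/linear flag.

    The sequence is stored uppercase over {A,C,G,T,N}; any other IUPAC
    ambiguity code is normalized to N (``n_ambiguous`` counts them).
    """

    name: str
    sequence: str
    circular: bool = False
    n_ambiguous: int = 0

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"genome {self.name!r}: empty sequence")
        if not set(self.sequence) <= VALID_BASES:
            seq, n_amb = normalize_sequence(self.sequence)
            self.sequence = seq
            self.n_ambiguous += n_amb

    def __len__(self) -> int:
        return len(self.sequence)

    def fetch(self, start: int, length: int) -> str:
        """Forward-strand slice of ``length`` bases starting at ``start``.

        Circular genomes wrap across the origin; linear genomes raise if the
        slice runs off the end.
        """
        g = self.sequence
        if self.circular:
            start %= len(g)
            if start + length <= len(g):
                return g[start : start + length]
            piece = g[start:]
            # wrap, possibly more than once for pathological lengths
            while len(piece) < length:
                piece += g
            return piece[:length]
        if start < 0 or start + length > len(g):
            raise ValueError(
                f"slice [{start}, {start + length}) outside linear genome "
                f"{self.name!r} of length {len(g)}"
            )
        return g[start : start + length]


def normalize_sequence(raw: str) -> tuple[str, int]:
    """Uppercase a nucleotide string and map non-ACGTN IUPAC codes to N.

    Returns the normalized sequence and the number of characters changed to
    N (excluding existing N/n).
    """
    up = raw.upper()
    if set(up) <= VALID_BASES:
        return up, 0
    n_amb = sum(1 for c in up if c not in VALID_BASES)
    norm = "".join(c if c in VALID_BASES else "N" for c in up)
    return norm, n_amb


@dataclass
class AlignedRead:
    """One SAM record, reduced to the fields the model builder consumes.

    ``sequence`` and ``qualities`` are in aligner orientation (as stored in
    the SAM); ``position`` is the 0-based leftmost mapped coordinate.
    """

    query_name: str
    reference_name: str | None
    position: int
    cigar: list[tuple[int, int]]  # (pysam op code, length)
    sequence: str
    qualities: list[int] | None
    mapped: bool
    reverse: bool
    paired: bool
    is_first_in_pair: bool
    mate_mapped: bool
    properly_paired: bool
    template_length: int

    def query_consumed(self) -> int:
        return sum(l for op, l in self.cigar if op in _QUERY_CONSUMING)


@dataclass
class AbundanceTable:
    """Relative abundances of genomes for metagenomics-mode simulation."""

    entries: list[tuple[str, float]]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("duplicate genome names in abundance table")
        if any(a < 0 for _, a in self.entries):
            raise ValueError("negative abundance")
        if not any(a > 0 for _, a in self.entries):
            raise ValueError("abundance table needs at least one entry > 0")


@dataclass
class SamReadResult:
    """Stream wrapper returned by :func:`read_alignments`.

    Iterating yields :class:`AlignedRead`; ``n_skipped`` counts records that
    failed basic consistency checks (CIGAR/SEQ length mismatch and the like)
    and were dropped.
    """

    references: dict[str, int]
    _iter: Iterator[AlignedRead]
    n_skipped: int = 0

    def __iter__(self) -> Iterator[AlignedRead]:
        return self._iter


_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def _record_line_consistent(line: str) -> bool:
    """Cheap structural check so one bad line cannot abort the htslib stream."""
    f = line.rstrip("\n").split("\t")
    if len(f) < 11:
        return False
    cigar, seq, qual = f[5], f[9], f[10]
    if cigar != "*" and seq != "*":
        ops = _CIGAR_RE.findall(cigar)
        if "".join(n + op for n, op in ops) != cigar:
            return False
        qlen = sum(int(n) for n, op in ops if op in "MIS=X")
        if qlen != len(seq):
            return False
    if seq != "*" and qual != "*" and len(seq) != len(qual):
        return False
    return True


def read_alignments(path: str | os.PathLike) -> SamReadResult:
    """Stream a SAM file (plain or BGZF) as :class:`AlignedRead` records.

    The header is parsed for reference names and lengths.  Records whose
    query-consuming CIGAR length disagrees with SEQ, or whose quality string
    length disagrees with SEQ, are skipped and counted on the returned
    object's ``n_skipped`` (htslib would otherwise abort the whole stream
    at the first such line, so they are filtered up front).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    # Pre-filter structurally broken record lines into a cleaned temp file.
    n_prefiltered = 0
    opener = pysam.BGZFile if str(path).endswith(".gz") else open
    tmp = tempfile.NamedTemporaryFile("w", suffix=".sam", delete=False)
    try:
        with opener(str(path)) as src:
            for raw in src:
                line = raw.decode() if isinstance(raw, bytes) else raw
                if line.startswith("@") or _record_line_consistent(line):
                    tmp.write(line if line.endswith("\n") else line + "\n")
                else:
                    n_prefiltered += 1
    finally:
        tmp.close()

    af = pysam.AlignmentFile(tmp.name, "r", check_sq=False)
    refs = dict(zip(af.references, af.lengths))
    result = SamReadResult(references=refs, _iter=iter(()), n_skipped=n_prefiltered)

    def gen() -> Iterator[AlignedRead]:
        with af:
            for rec in af:
                rec_quals = (
                    list(rec.query_qualities) if rec.query_qualities is not None else None
                )
                seq = rec.query_sequence or ""
                read = AlignedRead(
                    query_name=rec.query_name,
                    reference_name=rec.reference_name,
                    position=rec.reference_start if not rec.is_unmapped else -1,
                    cigar=list(rec.cigartuples or []),
                    sequence=seq.upper(),
                    qualities=rec_quals,
                    mapped=not rec.is_unmapped,
                    reverse=rec.is_reverse,
                    paired=rec.is_paired,
                    is_first_in_pair=not rec.is_paired or rec.is_read1,
                    mate_mapped=rec.is_paired and not rec.mate_is_unmapped,
                    properly_paired=rec.is_proper_pair,
                    template_length=rec.template_length,
                )
                if read.mapped and read.cigar and read.query_consumed() != len(read.sequence):
                    result.n_skipped += 1
                    continue
                if read.qualities is not None and len(read.qualities) != len(read.sequence):
                    result.n_skipped += 1
                    continue
                yield read
        os.unlink(tmp.name)

    result._iter = gen()
    return result


# ---------------------------------------------------------------------------
# FASTA genomes

def read_genomes(
    path: str | os.PathLike, circular: bool = False
) -> list[ReferenceGenome]:
    """Load genome(s) from a FASTA file or a directory of FASTA files.

    A file yields one :class:`ReferenceGenome` per record.  A directory
    yields one genome per file (records concatenated), named by the file
    stem — the layout used in metagenomics mode, where each file is one
    species.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(
            p
            for p in path.iterdir()
            if p.suffix.lower() in {".fa", ".fasta", ".fna"} and p.is_file()
        )
        if not files:
            raise ValueError(f"no FASTA files in directory {path}")
        genomes = []
        for f in files:
            records = list(SeqIO.parse(str(f), "fasta"))
            if not records:
                raise ValueError(f"empty FASTA file {f}")
            seq = "".join(str(r.seq) for r in records)
            norm, n_amb = normalize_sequence(seq)
            genomes.append(
                ReferenceGenome(f.stem, norm, circular=circular, n_ambiguous=n_amb)
            )
    else:
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"empty FASTA file {path}")
        genomes = []
        for r in records:
            norm, n_amb = normalize_sequence(str(r.seq))
            genomes.append(
                ReferenceGenome(r.id, norm, circular=circular, n_ambiguous=n_amb)
            )
    names = [g.name for g in genomes]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate genome names: {sorted(names)}")
    return genomes


# ---------------------------------------------------------------------------
# FASTQ

_QUAL_MAX = {33: 93, 64: 62}


def encode_quality(values: Sequence[int], offset: int = 33) -> str:
    """Render Phred integers as a FASTQ quality string at offset 33 or 64."""
    if offset not in _QUAL_MAX:
        raise ValueError(f"quality offset must be 33 or 64, got {offset}")
    hi = _QUAL_MAX[offset]
    for i, v in enumerate(values):
        if not 0 <= v <= hi:
            raise ValueError(
                f"quality value {v} at index {i} outside [0, {hi}] for offset {offset}"
            )
    return "".join(chr(v + offset) for v in values)


def decode_quality(text: str, offset: int = 33) -> list[int]:
    """Inverse of :func:`encode_quality`."""
    if offset not in _QUAL_MAX:
        raise ValueError(f"quality offset must be 33 or 64, got {offset}")
    values = [ord(c) - offset for c in text]
    hi = _QUAL_MAX[offset]
    for i, v in enumerate(values):
        if not 0 <= v <= hi:
            raise ValueError(f"quality character {text[i]!r} at index {i} out of range")
    return values


def write_fastq_record(
    handle: TextIO, name: str, sequence: str, qualities: Sequence[int], offset: int = 33
) -> None:
    """Append one never-wrapped FASTQ record."""
    if len(sequence) != len(qualities):
        raise ValueError(
            f"record {name!r}: sequence length {len(sequence)} != "
            f"{len(qualities)} quality values"
        )
    handle.write(f"@{name}\n{sequence}\n+\n{encode_quality(qualities, offset)}\n")


def read_fastq(path: str | os.PathLike, offset: int = 33) -> Iterator[tuple[str, str, list[int]]]:
    """Yield (name, sequence, qualities) from an uncompressed FASTQ file."""
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            if not header.startswith("@"):
                raise ValueError(f"malformed FASTQ header line: {header!r}")
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            if not plus.startswith("+"):
                raise ValueError("malformed FASTQ: missing '+' line")
            qual = fh.readline().rstrip("\n")
            yield header[1:].rstrip("\n"), seq, decode_quality(qual, offset)


# ---------------------------------------------------------------------------
# Tab-delimited side files

def write_haplotype_file(path: str | os.PathLike, haplotypes, genome_name: str = "") -> None:
    """Write a haplotype set in the package's tab-delimited dialect.

    One line per SNP: ``hap-id  frequency  pos(1-based)  ref  alt``.
    A SNP-free haplotype is a single line with ``.`` in the last three
    columns.  ``haplotypes`` is a sequence of (frequency, snps) pairs where
    snps is a list of (0-based position, ref, alt).
    """
    with open(path, "w") as fh:
        if genome_name:
            fh.write(f"# haplotypes for {genome_name}\n")
        for i, (freq, snps) in enumerate(haplotypes):
            hap_id = f"hap{i}"
            if not snps:
                fh.write(f"{hap_id}\t{freq:.10g}\t.\t.\t.\n")
            for pos, ref, alt in snps:
                fh.write(f"{hap_id}\t{freq:.10g}\t{pos + 1}\t{ref}\t{alt}\n")


def read_haplotype_file(path: str | os.PathLike) -> list[tuple[float, list[tuple[int, str, str]]]]:
    """Read the haplotype dialect written by :func:`write_haplotype_file`.

    Returns (frequency, snps) pairs in file order with 0-based positions.
    """
    order: list[str] = []
    freqs: dict[str, float] = {}
    snps: dict[str, list[tuple[int, str, str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 tab-delimited fields")
            hap_id, freq_s, pos_s, ref, alt = parts
            if hap_id not in freqs:
                order.append(hap_id)
                freqs[hap_id] = float(freq_s)
                snps[hap_id] = []
            elif float(freq_s) != freqs[hap_id]:
                raise ValueError(
                    f"{path}:{lineno}: inconsistent frequency for haplotype {hap_id!r}"
                )
            if pos_s == ".":
                continue
            snps[hap_id].append((int(pos_s) - 1, ref.upper(), alt.upper()))
    return [(freqs[h], snps[h]) for h in order]


def read_abundance_file(path: str | os.PathLike) -> AbundanceTable:
    """Read a ``genome-name<TAB>abundance`` file."""
    entries = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'name<TAB>abundance'")
            entries.append((parts[0], float(parts[1])))
    return AbundanceTable(entries)


def write_abundance_file(path: str | os.PathLike, table: AbundanceTable) -> None:
    with open(path, "w") as fh:
        for name, ab in table.entries:
            fh.write(f"{name}\t{ab:.10g}\n")


def read_known_snps(path: str | os.PathLike) -> set[int] | dict[str, set[int]]:
    """Read known polymorphic sites to exclude from model building.

    One 1-based position per line, optionally prefixed ``refname<TAB>``.
    Returns a set of 0-based positions, or a dict keyed by reference name
    when any line carries one.
    """
    plain: set[int] = set()
    by_ref: dict[str, set[int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                plain.add(int(parts[0]) - 1)
            elif len(parts) == 2:
                by_ref.setdefault(parts[0], set()).add(int(parts[1]) - 1)
            else:
                raise ValueError(f"{path}:{lineno}: expected 'pos' or 'refname<TAB>pos'")
    if by_ref:
        if plain:
            raise ValueError(f"{path}: mixed bare and refname-qualified positions")
        return by_ref
    return plain
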