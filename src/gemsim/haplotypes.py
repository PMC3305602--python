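"""Haplotype mixtures: frequency-weighted sets of SNP-bearing variants.

A haplotype set models a population of closely related sequences — for
example a viral quasispecies or a bacterial population sampled by deep
sequencing — as a reference genome plus, per haplotype, a frequency and a
list of SNPs.  Reads are later drawn from haplotypes in proportion to their
frequencies, so low-frequency variants appear in the simulated data at
known truth rates.
"""

from __future__ import annotations

import numpy as np

from .io_formats import ReferenceGenome, reverse_complement

_FREQ_TOL = 1e-9


class Haplotype:
    """One variant: a frequency and SNPs as (0-based position, ref, alt)."""

    __slots__ = ("frequency", "snps")

    def __init__(self, frequency: float, snps: list[tuple[int, str, str]]):
        self.frequency = frequency
        self.snps = sorted(snps)

    def __repr__(self) -> str:
        return f"Haplotype(frequency={self.frequency}, n_snps={len(self.snps)})"


class HaplotypeSet:
    def __init__(self, haplotypes: list[Haplotype], genome: ReferenceGenome | None = None):
        total = sum(h.frequency for h in haplotypes)
        if abs(total - 1.0) > _FREQ_TOL:
            raise ValueError(f"haplotype frequencies sum to {total}, expected 1")
        for h in haplotypes:
            positions = [p for p, _, _ in h.snps]
            if len(set(positions)) != len(positions):
                raise ValueError("duplicate SNP positions within a haplotype")
            for pos, ref, alt in h.snps:
                if ref == alt:
                    raise ValueError(f"SNP at {pos}: alt equals ref ({ref})")
                if genome is not None and genome.sequence[pos] != ref:
                    raise ValueError(
                        f"SNP at {pos}: ref base {ref!r} does not match genome "
                        f"base {genome.sequence[pos]!r} (corrupt haplotype file?)"
                    )
        self.haplotypes = haplotypes

    def __len__(self) -> int:
        return len(self.haplotypes)

    def __iter__(self):
        return iter(self.haplotypes)

    @property
    def frequencies(self) -> np.ndarray:
        return np.array([h.frequency for h in self.haplotypes])

    def as_pairs(self) -> list[tuple[float, list[tuple[int, str, str]]]]:
        return [(h.frequency, list(h.snps)) for h in self.haplotypes]


def generate_haplotypes(
    genome: ReferenceGenome,
    spec: list[tuple[float, int]],
    seed: int | np.random.Generator = 0,
) -> HaplotypeSet:
    """Place random SNPs to realize a (frequency, n_snps) specification.

    SNP positions are drawn uniformly without replacement per haplotype
    (different haplotypes may hit the same site); the alternate base is
    uniform over the three non-reference bases.  Positions whose reference
    base is N are not mutated.  Deterministic under a fixed seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    total = sum(f for f, _ in spec)
    if abs(total - 1.0) > _FREQ_TOL:
        raise ValueError(f"frequencies sum to {total}, expected 1")
    eligible = np.array([i for i, b in enumerate(genome.sequence) if b in "ACGT"])
    haps = []
    for freq, n_snps in spec:
        if n_snps > len(eligible):
            raise ValueError(
                f"{n_snps} SNPs requested but genome has only "
                f"{len(eligible)} mutable positions"
            )
        positions = rng.choice(eligible, size=n_snps, replace=False)
        snps = []
        for pos in sorted(int(p) for p in positions):
            ref = genome.sequence[pos]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            snps.append((pos, ref, str(alt)))
        haps.append(Haplotype(freq, snps))
    return HaplotypeSet(haps, genome)


def apply_haplotype(
    template: str,
    interval: tuple[int, int],
    strand: str,
    haplotype: Haplotype,
) -> str:
    """Substitute a haplotype's SNPs into a read template.

    ``template`` is the genome slice over the 0-based half-open ``interval``
    — forward sequence for strand '+', reverse complement for '-'.  SNPs
    falling inside the interval are substituted (complemented and
    re-indexed from the 3' end for '-'); the length never changes.
    """
    start, end = interval
    if len(template) != end - start:
        raise ValueError("template length does not match interval")
    if strand not in "+-":
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    out = list(template)
    for pos, ref, alt in haplotype.snps:
        if not start <= pos < end:
            continue
        if strand == "+":
            offset = pos - start
            expect, put = ref, alt
        else:
            offset = end - 1 - pos
            expect, put = reverse_complement(ref), reverse_complement(alt)
        if out[offset] != expect:
            raise ValueError(
                f"haplotype SNP at genome position {pos}: template has "
                f"{out[offset]!r} where ref base {expect!r} was expected"
            )
        out[offset] = put
    return "".join(out)
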