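import math
from collections import Counter

import numpy as np
import pytest

from gemsim import fixtures, haplotypes, io_formats, simulator
from gemsim.error_model import ErrorModel, MateModel, CORRECT, INSERTION, word_key
from gemsim.simulator import (
    SimulationConfig,
    _MateSampler,
    choose_genome,
    draw_fragment,
    introduce_errors,
    make_unaligned_mate,
    simulate,
    simulate_reads,
)


def binom_se(p, n):
    return math.sqrt(p * (1 - p) / n)


class TestChooseGenome:
    def test_single_genome_always_chosen(self, genome5k):
        table = io_formats.AbundanceTable([(genome5k.name, 1.0)])
        rng = np.random.default_rng(1)
        assert all(
            choose_genome(table, [genome5k], rng) is genome5k for _ in range(50)
        )

    @pytest.mark.parametrize(
        "lens,abunds,expected",
        [
            ((1000, 2000), (1.0, 1.0), (1 / 3, 2 / 3)),  # length weighting
            ((1500, 1500), (3.0, 1.0), (0.75, 0.25)),  # abundance weighting
        ],
    )
    def test_weighting_proportional_to_abundance_times_length(
        self, lens, abunds, expected
    ):
        genomes = [
            fixtures.random_genome(n, 0.5, seed=i, name=f"g{i}")
            for i, n in enumerate(lens)
        ]
        table = io_formats.AbundanceTable(
            [(g.name, a) for g, a in zip(genomes, abunds)]
        )
        rng = np.random.default_rng(4)
        n = 30_000
        counts = Counter(choose_genome(table, genomes, rng).name for _ in range(n))
        for g, p in zip(genomes, expected):
            assert abs(counts[g.name] / n - p) < 4 * binom_se(p, n)

    def test_zero_weights_fatal(self, genome5k):
        with pytest.raises(ValueError):
            io_formats.AbundanceTable([(genome5k.name, 0.0)])


class TestDrawFragment:
    def test_static_length_single_end(self, genome5k):
        model = fixtures.uniform_model(50)
        cfg = SimulationConfig(n_reads=1, static_read_length=100, seed=0)
        rng = np.random.default_rng(2)
        for _ in range(200):
            ((start, L, strand),) = draw_fragment(genome5k, model, cfg, rng)
            assert L == 100
            assert 0 <= start <= len(genome5k) - 100
            assert strand in "+-"

    def test_circular_genome_covers_every_position(self, genome1k_circular):
        """100 bp reads on a 1 kb circle: all positions reachable; coverage
        across the origin consistent with the genome-wide mean."""
        model = fixtures.uniform_model(100)
        cfg = SimulationConfig(n_reads=1, static_read_length=100, circular=True, seed=0)
        rng = np.random.default_rng(3)
        G = len(genome1k_circular)
        n = 30_000
        start_counts = np.zeros(G)
        for _ in range(n):
            ((start, L, _),) = draw_fragment(genome1k_circular, model, cfg, rng)
            start_counts[start] += 1
        coverage = np.convolve(
            np.concatenate([start_counts, start_counts]), np.ones(100), mode="full"
        )[G : 2 * G]
        assert (coverage > 0).all()
        mean, sd = coverage.mean(), coverage.std()
        origin_span = np.concatenate([coverage[-99:], coverage[:1]])
        assert (np.abs(origin_span - mean) < 4 * sd).all()

    def test_paired_mate_coordinates(self, genome5k):
        """Fixed insert 300, reads 100 bp: the mate occupies [s+200, s+300)
        on the opposite strand."""
        model = fixtures.uniform_model(100, paired=True, insert_size=300)
        cfg = SimulationConfig(n_reads=1, paired=True, static_read_length=100, seed=0)
        rng = np.random.default_rng(5)
        for _ in range(100):
            (p1, p2) = draw_fragment(
                genome5k, model, cfg, rng, _lengths=(100, 100), _insert=300
            )
            (s1, L1, str1), (s2, L2, str2) = (p1, p2)
            assert {str1, str2} == {"+", "-"}
            fwd, rev = (p1, p2) if str1 == "+" else (p2, p1)
            assert rev[0] == fwd[0] + 300 - 100
            assert 0 <= fwd[0] and rev[0] + 100 <= len(genome5k)


class TestIntroduceErrors:
    def test_zero_error_model_is_identity(self, genome5k):
        model = fixtures.uniform_model(60)
        sampler = _MateSampler(model.mates[0])
        rng = np.random.default_rng(6)
        for start in range(0, 500, 60):
            template = genome5k.fetch(start, 60)
            seq, classes, ops, errors, consumed = introduce_errors(template, sampler, rng)
            assert seq == template
            assert errors == [] and ops == [("M", 60)] and consumed == 60

    def test_mismatch_rate_recovered_binomially(self, genome5k):
        model = fixtures.uniform_model(50, mismatch=0.10)
        sampler = _MateSampler(model.mates[0])
        rng = np.random.default_rng(7)
        n_bases = n_mm = 0
        while n_bases < 100_000:
            start = int(rng.integers(0, len(genome5k) - 50))
            template = genome5k.fetch(start, 50)
            seq, classes, *_ = introduce_errors(template, sampler, rng)
            n_bases += len(classes)
            n_mm += sum(1 for c in classes if c == "mismatch")
        assert abs(n_mm / n_bases - 0.10) < 4 * binom_se(0.10, n_bases)

    def test_homopolymer_run_gets_at_most_one_insertion(self):
        """A model whose only insertion mass sits on the run-end word AAA|A|C
        never inserts twice within one A-run."""
        mate = MateModel()
        for pos in range(40):
            vec = mate.cell(pos, word_key("AAA", "A", "C"))
            vec[CORRECT] = 50
            vec[INSERTION] = 50
        mate.insertion_detail[word_key("AAA", "A", "C")] = Counter({"A": 1})
        mate.read_length_hist[40] = 1
        model = ErrorModel(mates=[mate])
        sampler = _MateSampler(model.mates[0])
        rng = np.random.default_rng(8)
        template = "GGAAAACGG" * 4
        for _ in range(300):
            seq, classes, ops, errors, _ = introduce_errors(template, sampler, rng)
            ins_positions = [int(e.split(":")[1]) for e in errors if e.startswith("ins")]
            # each template A-run (4 As) may produce at most one insertion
            assert len(ins_positions) == len(set(ins_positions))
            # insertions land right after a full A-run followed by C
            for p in ins_positions:
                assert seq[p] == "A" and seq[p - 1] == "A"
        # sanity: the scenario does produce insertions at all
        rng2 = np.random.default_rng(9)
        total = sum(
            len([e for e in introduce_errors(template, sampler, rng2)[3]])
            for _ in range(50)
        )
        assert total > 0


class TestAssignQualities:
    def test_point_mass_model_gives_constant_quality(self, genome5k):
        model = fixtures.uniform_model(30, quality_correct=40)
        cfg = SimulationConfig(n_reads=20, static_read_length=30, seed=1)
        for (read,) in simulate_reads(cfg, model, [genome5k]):
            assert read.qualities == [40] * 30

    def test_mismatch_bases_use_mismatch_histogram(self, genome5k):
        model = fixtures.uniform_model(
            40, mismatch=0.2, quality_correct=40, quality_mismatch=10
        )
        cfg = SimulationConfig(n_reads=50, static_read_length=40, seed=2)
        n_mm = 0
        for (read,) in simulate_reads(cfg, model, [genome5k]):
            mm_pos = {
                int(e.split(":")[1]) for e in read.truth.errors if e.startswith("mm")
            }
            n_mm += len(mm_pos)
            for p, q in enumerate(read.qualities):
                assert q == (10 if p in mm_pos else 40)
        assert n_mm > 0

    def test_empirical_histogram_recovered(self, genome5k):
        """Simulated per-position quality distribution matches the model
        histogram (chi-square, alpha = 0.001)."""
        from scipy.stats import chisquare

        model = fixtures.uniform_model(20)
        probs = {30: 0.7, 35: 0.2, 40: 0.1}
        for pos in range(20):
            model.mates[0].quality_hist[pos]["correct"] = Counter(
                {q: int(p * 1000) for q, p in probs.items()}
            )
        cfg = SimulationConfig(n_reads=5000, static_read_length=20, seed=3)
        observed = Counter()
        for (read,) in simulate_reads(cfg, model, [genome5k]):
            observed[read.qualities[0]] += 1
        n = sum(observed.values())
        stat, p = chisquare(
            [observed[q] for q in sorted(probs)],
            [probs[q] * n for q in sorted(probs)],
        )
        assert p > 0.001


class TestUnalignedMate:
    @pytest.mark.parametrize("length", [100, 1])
    def test_all_n_at_quality_two(self, length):
        seq, quals = make_unaligned_mate(length)
        assert seq == "N" * length
        assert quals == [2] * length

    def test_rendering_at_both_offsets(self):
        seq, quals = make_unaligned_mate(5)
        assert io_formats.encode_quality(quals, 64) == "B" * 5
        assert io_formats.encode_quality(quals, 33) == "#" * 5


class TestSimulate:
    def test_zero_error_reads_are_exact_genome_substrings(self, genome5k):
        model = fixtures.uniform_model(50)
        cfg = SimulationConfig(n_reads=300, static_read_length=50, seed=4)
        for (read,) in simulate_reads(cfg, model, [genome5k]):
            tr = read.truth
            slice_ = genome5k.fetch(tr.start, 50)
            expected = (
                slice_ if tr.strand == "+" else io_formats.reverse_complement(slice_)
            )
            assert read.sequence == expected
            assert read.sequence in genome5k.sequence or (
                io_formats.reverse_complement(read.sequence) in genome5k.sequence
            )

    def test_record_count_and_fastq_validity(self, genome5k, tmp_path):
        model = fixtures.uniform_model(40, mismatch=0.01, paired=True, insert_size=150)
        cfg = SimulationConfig(n_reads=200, paired=True, seed=5)
        paths = simulate(cfg, model, [genome5k], tmp_path / "sim")
        r1 = list(io_formats.read_fastq(paths["fastq_1"]))
        r2 = list(io_formats.read_fastq(paths["fastq_2"]))
        assert len(r1) == len(r2) == 200
        for name, seq, quals in r1 + r2:
            assert len(seq) == len(quals) > 0
        truth_rows = [
            l for l in paths["truth"].read_text().splitlines() if not l.startswith("#")
        ]
        assert len(truth_rows) == 401  # header + one row per mate

    def test_fixed_seed_byte_identical_output(self, genome5k, tmp_path):
        model = fixtures.uniform_model(40, mismatch=0.02, insertion=0.002, deletion=0.002)
        outs = []
        for name in ("one", "two"):
            cfg = SimulationConfig(n_reads=150, seed=99)
            paths = simulate(cfg, model, [genome5k], tmp_path / name)
            outs.append(paths["fastq"].read_bytes())
        assert outs[0] == outs[1]

    def test_unaligned_second_mate_frequency(self, genome5k):
        model = fixtures.uniform_model(
            40, paired=True, insert_size=150, properly_paired=0.9
        )
        cfg = SimulationConfig(n_reads=2000, paired=True, seed=6)
        n_unaligned = sum(
            1 for _, r2 in simulate_reads(cfg, model, [genome5k]) if not r2.truth.aligned
        )
        for _, r2 in simulate_reads(cfg, model, [genome5k]):
            if not r2.truth.aligned:
                assert set(r2.sequence) == {"N"}
                assert set(r2.qualities) == {2}
                break
        assert abs(n_unaligned / 2000 - 0.1) < 4 * binom_se(0.1, 2000)

    def test_haplotype_fractions_match_frequencies(self, genome5k):
        spec = [(0.05, 20), (0.15, 10), (0.80, 0)]
        hset = haplotypes.generate_haplotypes(genome5k, spec, seed=10)
        model = fixtures.uniform_model(50)
        cfg = SimulationConfig(n_reads=20_000, static_read_length=50, seed=7)
        counts = Counter(
            read.truth.haplotype
            for (read,) in simulate_reads(cfg, model, [genome5k], haplotypes=hset)
        )
        for idx, (freq, _) in enumerate(spec):
            assert abs(counts[idx] / 20_000 - freq) < 4 * binom_se(freq, 20_000)

    def test_haplotype_snps_appear_in_reads(self, genome5k):
        hap = haplotypes.generate_haplotypes(genome5k, [(1.0, 200)], seed=11)
        model = fixtures.uniform_model(50)
        cfg = SimulationConfig(n_reads=200, static_read_length=50, seed=8)
        snps = dict((p, a) for p, _, a in hap.haplotypes[0].snps)
        n_checked = 0
        for (read,) in simulate_reads(cfg, model, [genome5k], haplotypes=hap):
            tr = read.truth
            for off in range(50):
                gpos = tr.start + off
                if gpos in snps:
                    if tr.strand == "+":
                        assert read.sequence[off] == snps[gpos]
                    else:
                        assert read.sequence[50 - 1 - (gpos - tr.start)] == (
                            io_formats.reverse_complement(snps[gpos])
                        )
                    n_checked += 1
        assert n_checked > 0

    def test_metagenomics_read_counts_track_weights(self, tmp_path):
        g1 = fixtures.random_genome(1000, 0.5, seed=31, name="g1")
        g2 = fixtures.random_genome(2000, 0.5, seed=32, name="g2")
        table = io_formats.AbundanceTable([("g1", 1.0), ("g2", 1.0)])
        model = fixtures.uniform_model(50)
        cfg = SimulationConfig(
            n_reads=15_000, static_read_length=50, seed=9, metagenomics=True
        )
        counts = Counter(
            r.truth.genome
            for (r,) in simulate_reads(cfg, model, [g1, g2], abundances=table)
        )
        from scipy.stats import chisquare

        stat, p = chisquare(
            [counts["g1"], counts["g2"]], [15_000 / 3, 2 * 15_000 / 3]
        )
        assert p > 0.001
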