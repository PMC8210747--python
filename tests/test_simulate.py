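"""Simulator contracts: determinism, conservation, error models, truth."""

import io
from collections import Counter

import edlib
import numpy as np
import pytest

from satcons import seqio, simulate
from satcons.simulate import (
    AmplificationProfile,
    ConfigurationError,
    LongReadSpec,
    ShortReadSpec,
    SimulationConfig,
    SizingError,
    SpeciesSpec,
)


def _config(monomer, seed=3, **kw):
    defaults = dict(
        species=(SpeciesSpec("sp", 0.05, AmplificationProfile(2, 20, 30)),),
        ancestral_monomer=monomer,
        background_length=20_000,
        short_read=ShortReadSpec(n_pairs=500),
        long_read=LongReadSpec(n_reads=4, mean_log=8.0, sd_log=0.3),
    )
    defaults.update(kw)
    return SimulationConfig(seed=seed, **defaults)


class TestEvolveLibrary:
    def test_rate_zero_keeps_ancestor_only(self, monomer):
        pools = simulate.evolve_library(_config(monomer, substitution_rate=0.0))
        assert pools["sp"].keys() == {monomer}

    def test_full_homogenization_single_variant(self, monomer):
        pools = simulate.evolve_library(
            _config(monomer, substitution_rate=1.0, homogenization=1.0)
        )
        assert len(pools["sp"]) == 1

    def test_longer_branch_diverges_more(self, monomer):
        cfg = _config(
            monomer,
            species=(
                SpeciesSpec("slow", 0.01, AmplificationProfile(2, 40, 50)),
                SpeciesSpec("fast", 0.10, AmplificationProfile(2, 40, 50)),
            ),
        )
        pools = simulate.evolve_library(cfg)

        def mean_hamming(pool):
            total = n = 0
            for seq, c in pool.items():
                d = sum(a != b for a, b in zip(seq, monomer))
                total += d * c
                n += c
            return total / n

        assert mean_hamming(pools["fast"]) > mean_hamming(pools["slow"])

    def test_mutation_draws_replay_exactly(self, monomer):
        """Replaying the documented RNG draw order reproduces mutate()."""
        rng = simulate.stream(9, "x")
        mutated = simulate.mutate(monomer, 0.3, 2.0, rng)
        rng2 = simulate.stream(9, "x")
        hits = np.flatnonzero(rng2.random(52) < 0.3)
        expected = list(monomer)
        code = {b: i for i, b in enumerate("ACGT")}
        bases = "ACGT"
        for i in hits:
            c = code[expected[i]]
            if rng2.random() < 2.0 / 4.0:
                expected[i] = bases[(c + 2) % 4]
            else:
                expected[i] = bases[(c + (1 if rng2.integers(2) == 0 else 3)) % 4]
        assert mutated == "".join(expected)

    def test_empty_species_rejected(self, monomer):
        with pytest.raises(ConfigurationError):
            simulate.evolve_library(_config(monomer, species=()))


class TestBuildGenome:
    def test_no_arrays(self, monomer):
        cfg = _config(monomer, species=(SpeciesSpec("sp", 0.0, AmplificationProfile(0, 1, 1)),))
        genome, truth = simulate.build_genome({monomer: 1}, cfg, "sp")
        assert len(genome) == 20_000
        assert truth.intervals == [] and truth.copy_number == 0

    def test_single_array_arithmetic(self, monomer):
        cfg = _config(monomer, species=(SpeciesSpec("sp", 0.0, AmplificationProfile(1, 10, 10)),))
        genome, truth = simulate.build_genome({monomer: 1}, cfg, "sp")
        (iv,) = truth.intervals
        assert len(iv) == 520 and truth.copy_number == 10

    def test_conservation_of_planted_bases(self, monomer):
        cfg = _config(monomer)
        pool = simulate.evolve_library(cfg)["sp"]
        _, truth = simulate.build_genome(pool, cfg, "sp")
        assert sum(len(iv) for iv in truth.intervals) == 52 * truth.copy_number
        assert truth.copy_number == sum(truth.variant_frequencies.values())

    def test_clustered_vs_dispersed_copy_ratio(self, monomer):
        clustered = _config(
            monomer, species=(SpeciesSpec("sp", 0.0, AmplificationProfile(5, 250, 250)),),
            background_length=150_000,
        )
        dispersed = _config(
            monomer, species=(SpeciesSpec("sp", 0.0, AmplificationProfile(5, 20, 20)),)
        )
        _, t_c = simulate.build_genome({monomer: 1}, clustered, "sp")
        _, t_d = simulate.build_genome({monomer: 1}, dispersed, "sp")
        assert (t_c.copy_number, t_d.copy_number) == (1250, 100)
        assert t_c.copy_number / t_d.copy_number == 12.5

    def test_intervals_nonoverlapping_within_bounds(self, monomer):
        cfg = _config(monomer)
        pool = simulate.evolve_library(cfg)["sp"]
        genome, truth = simulate.build_genome(pool, cfg, "sp")
        ivs = sorted(truth.intervals)
        for a, b in zip(ivs, ivs[1:]):
            assert a.end <= b.start
        assert all(0 <= iv.start < iv.end <= len(genome) for iv in ivs)
        assert all(len(iv) >= 52 for iv in ivs)

    def test_oversized_request_rejected(self, monomer):
        cfg = _config(
            monomer,
            species=(SpeciesSpec("sp", 0.0, AmplificationProfile(2, 250, 250)),),
            background_length=20_000,
        )
        with pytest.raises(SizingError):
            simulate.build_genome({monomer: 1}, cfg, "sp")

    def test_background_composition(self, monomer):
        cfg = _config(
            monomer,
            species=(SpeciesSpec("sp", 0.0, AmplificationProfile(0, 1, 1)),),
            background_length=50_000,
            background_at=0.65,
            substitution_rate=0.0,
        )
        genome, _ = simulate.build_genome({monomer: 1}, cfg, "sp")
        at = (genome.count("A") + genome.count("T")) / len(genome)
        assert at == pytest.approx(0.65, abs=0.02)


class TestShortReads:
    def test_counts_and_lengths(self, monomer):
        cfg = _config(monomer, short_read=ShortReadSpec(n_pairs=1000))
        genome, _ = simulate.build_genome({monomer: 1}, cfg, "sp")
        pairs = simulate.simulate_short_reads(genome, cfg, "sp")
        reads = [r for p in pairs for r in p]
        assert len(reads) == 2000
        assert all(len(r) == 101 for r in reads)

    def test_error_free_reads_are_genome_substrings(self, monomer):
        cfg = _config(monomer)
        genome, _ = simulate.build_genome(simulate.evolve_library(cfg)["sp"], cfg, "sp")
        rc = seqio.reverse_complement(genome)
        for pair in simulate.simulate_short_reads(genome, cfg, "sp")[:200]:
            for read in pair:
                assert read.sequence in genome or read.sequence in rc

    def test_same_seed_identical_fastq_bytes(self, monomer, tmp_path):
        cfg = _config(monomer)
        genome, _ = simulate.build_genome({monomer: 1}, cfg, "sp")
        paths = []
        for name in ("a.fq", "b.fq"):
            path = tmp_path / name
            reads = [r for p in simulate.simulate_short_reads(genome, cfg, "sp") for r in p]
            seqio.write_sequences(path, reads, format="fastq")
            paths.append(path.read_bytes())
        assert paths[0] == paths[1]

    def test_genome_shorter_than_read_rejected(self, monomer):
        cfg = _config(monomer)
        with pytest.raises(SizingError):
            simulate.simulate_short_reads("ACGT" * 10, cfg, "sp")


class TestLongReads:
    def test_error_free_reads_are_exact_substrings(self, monomer):
        cfg = _config(monomer, long_read=LongReadSpec(n_reads=5, error_rate=0.0, mean_log=8.0))
        genome, truth = simulate.build_genome({monomer: 1}, cfg, "sp")
        reads, _ = simulate.simulate_long_reads(genome, cfg, truth.intervals, "sp")
        rc = seqio.reverse_complement(genome)
        for read in reads:
            assert read.sequence in genome or read.sequence in rc

    def test_realized_error_rate_within_three_points(self, monomer):
        """Edit distance to the source region stays in [0.12, 0.18] for
        ~10-kb reads at a 15% error rate (edlib global-alignment oracle)."""
        cfg = _config(
            monomer,
            species=(SpeciesSpec("sp", 0.0, AmplificationProfile(0, 1, 1)),),
            background_length=40_000,
            long_read=LongReadSpec(n_reads=6, mean_log=9.2, sd_log=0.1, error_rate=0.15),
        )
        genome, _ = simulate.build_genome({monomer: 1}, cfg, "sp")
        reads, _ = simulate.simulate_long_reads(genome, cfg, [], "sp")
        rc = seqio.reverse_complement(genome)
        long_enough = [r for r in reads if len(r) >= 5000]
        assert long_enough
        for read in long_enough:
            hits = []
            for target in (genome, rc):
                res = edlib.align(read.sequence, target, mode="HW", task="distance")
                hits.append(res["editDistance"])
            rate = min(hits) / len(read.sequence)
            assert 0.12 <= rate <= 0.18

    def test_truth_covers_read_inside_array(self, monomer):
        # genome almost entirely one array: reads land inside it
        cfg = _config(
            monomer,
            species=(SpeciesSpec("sp", 0.0, AmplificationProfile(1, 380, 380)),),
            background_length=21_000,
            long_read=LongReadSpec(n_reads=8, mean_log=8.4, sd_log=0.1, min_length=2000),
        )
        genome, truth = simulate.build_genome({monomer: 1}, cfg, "sp")
        reads, read_truth = simulate.simulate_long_reads(genome, cfg, truth.intervals, "sp")
        fully_inside = 0
        for read in reads:
            ivs = read_truth.get(read.id, [])
            covered = sum(len(iv) for iv in ivs)
            if ivs and covered >= 0.95 * len(read):
                fully_inside += 1
        assert fully_inside >= 1  # the 19.8-kb array dominates the genome

    def test_indel_dominated_reads_change_length(self, monomer):
        cfg = _config(
            monomer,
            long_read=LongReadSpec(n_reads=6, mean_log=8.5, sd_log=0.1,
                                   error_rate=0.15, indel_fraction=1.0),
        )
        genome, _ = simulate.build_genome({monomer: 1}, cfg, "sp")
        reads, _ = simulate.simulate_long_reads(genome, cfg, [], "sp")
        assert any(len(r) != 0 for r in reads)


class TestDeterminism:
    def test_identical_config_identical_outputs(self, monomer):
        outputs = []
        for _ in range(2):
            cfg = _config(monomer, seed=11)
            pools = simulate.evolve_library(cfg)
            genome, truth = simulate.build_genome(pools["sp"], cfg, "sp")
            pairs = simulate.simulate_short_reads(genome, cfg, "sp")
            lreads, rtruth = simulate.simulate_long_reads(genome, cfg, truth.intervals, "sp")
            outputs.append(
                (
                    pools,
                    genome,
                    [(iv.start, iv.end, iv.strand) for iv in truth.intervals],
                    [(a.sequence, b.sequence) for a, b in pairs],
                    [r.sequence for r in lreads],
                    {k: [(i.start, i.end) for i in v] for k, v in rtruth.items()},
                )
            )
        assert outputs[0] == outputs[1]

    def test_streams_are_label_independent(self, monomer):
        a = simulate.stream(5, "short:sp").random(4).tolist()
        b = simulate.stream(5, "long:sp").random(4).tolist()
        assert a != b
        assert simulate.stream(5, "short:sp").random(4).tolist() == a


class TestConfigValidation:
    def test_monomer_length_enforced(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(seed=1, species=(), ancestral_monomer="ACGT")

    def test_probabilities_in_unit_interval(self, monomer):
        with pytest.raises(ConfigurationError):
            _config(monomer, homogenization=1.5)
        with pytest.raises(ConfigurationError):
            _config(monomer, background_at=-0.1)
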