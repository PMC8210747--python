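"""Monomer extraction, canonical rotation, tallying and composition."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from satcons import monomers
from satcons.seqio import reverse_complement

from conftest import random_seq

dna = st.text(alphabet="ACGT", min_size=1, max_size=60)


class TestCanonicalRotation:
    def test_examples(self):
        assert monomers.canonical_rotation("GATC") == "ATCG"
        assert monomers.canonical_rotation("AAAA") == "AAAA"

    @given(dna)
    def test_minimal_over_all_rotations(self, seq):
        rotations = {seq[i:] + seq[:i] for i in range(len(seq))}
        assert monomers.canonical_rotation(seq) == min(rotations)

    @given(dna, st.integers(0, 59))
    def test_rotation_class_invariant_and_idempotent(self, seq, k):
        k %= len(seq)
        rotated = seq[k:] + seq[:k]
        canon = monomers.canonical_rotation(seq)
        assert monomers.canonical_rotation(rotated) == canon
        assert monomers.canonical_rotation(canon) == canon


class TestExtraction:
    def test_read_with_under_two_copies_yields_one_monomer(self, monomer):
        read = (monomer * 2)[:101]  # 1.94 copies, in phase
        assert monomers.extract_monomers([read], monomer) == [monomer]

    def test_three_exact_copies(self, monomer):
        assert monomers.extract_monomers([monomer * 3], monomer) == [monomer] * 3

    def test_random_read_yields_nothing(self, monomer, rng):
        read = random_seq(rng, 150, at=0.5)
        assert monomers.extract_monomers([read], monomer) == []

    def test_phase_locked_to_consensus_frame(self, monomer):
        # read starts 17 nt into a copy; the one complete copy is recovered
        # in the consensus frame, not in the read's arrival phase
        read = monomer[17:] + monomer + monomer[:30]
        assert monomers.extract_monomers([read], monomer) == [monomer]

    def test_strand_symmetry(self, monomer, rng):
        reads = [monomer[7:] + monomer + monomer[:20], (monomer * 3)[10:140]]
        fwd = monomers.tally_and_filter(
            monomers.extract_monomers(reads, monomer), drop_singletons=False
        )
        rc = monomers.tally_and_filter(
            monomers.extract_monomers([reverse_complement(r) for r in reads], monomer),
            drop_singletons=False,
        )
        assert fwd == rc

    def test_flanking_background_windows_are_not_emitted(self, monomer, rng):
        read = monomer + random_seq(rng, 52, at=0.5)
        assert monomers.extract_monomers([read], monomer) == [monomer]

    def test_consensus_must_be_monomer_length(self, monomer):
        with pytest.raises(monomers.ConfigurationError):
            monomers.extract_monomers(["ACGT" * 30], monomer[:40])


class TestTally:
    def test_singleton_filtering(self):
        counts = monomers.tally_and_filter(["AAAC"] * 5 + ["AACC"])
        assert counts == Counter({"AAAC": 5})

    def test_ties_kept(self):
        counts = monomers.tally_and_filter(["AAAC"] * 2 + ["AACC"] * 2)
        assert counts == Counter({"AAAC": 2, "AACC": 2})

    def test_keep_singletons(self):
        counts = monomers.tally_and_filter(["AAAC"] * 5 + ["AACC"], drop_singletons=False)
        assert counts == Counter({"AAAC": 5, "AACC": 1})

    def test_rotations_tally_together(self):
        counts = monomers.tally_and_filter(["GATC", "TCGA"])
        assert counts == Counter({"ATCG": 2})


class TestComposition:
    def test_pure_at_consensus(self):
        comp = monomers.consensus_and_composition({"AT" * 26: 4})
        assert comp.at_fraction == 1.0

    def test_majority_rules_by_count(self, monomer):
        variant = monomer[:31] + ("A" if monomer[31] != "A" else "C") + monomer[32:]
        comp = monomers.consensus_and_composition({monomer: 3, variant: 1})
        assert comp.consensus == monomer
        assert not comp.ambiguous_positions

    def test_tie_flagged_and_alphabetical(self):
        comp = monomers.consensus_and_composition({"A" * 52: 1, "C" * 52: 1})
        assert comp.consensus == "A" * 52
        assert comp.ambiguous_positions == list(range(52))

    def test_column_sums_equal_total_count(self, monomer):
        counts = {monomer: 3, monomer[1:] + monomer[0]: 2}
        comp = monomers.consensus_and_composition(counts)
        assert (comp.matrix.sum(axis=0) == 5).all()

    def test_mixed_lengths_rejected(self):
        with pytest.raises(ValueError):
            monomers.consensus_and_composition({"ACGT": 1, "ACG": 1})


class TestPhaseAlign:
    def test_variant_lands_in_consensus_frame(self, monomer):
        variant = "T" + monomer[1:]
        rotated = variant[13:] + variant[:13]
        aligned = monomers.phase_align({rotated: 7}, monomer)
        assert aligned == Counter({variant: 7})

    def test_colliding_frames_sum(self, monomer):
        aligned = monomers.phase_align({monomer: 2, monomer[5:] + monomer[:5]: 3}, monomer)
        assert aligned == Counter({monomer: 5})


@pytest.mark.parametrize(
    "n_ref,ref_gb,target_gb,expected",
    [
        (1_000_000, 1.38, 1.38, 1_000_000),
        (1_000_000, 1.38, 2.76, 2_000_000),
        (1_000_000, 1.38, 0.69, 500_000),
    ],
)
def test_subsample_scales_with_genome_size(n_ref, ref_gb, target_gb, expected):
    assert monomers.subsample_by_genome_size(n_ref, ref_gb, target_gb) == expected


def test_subsample_rejects_nonpositive_sizes():
    with pytest.raises(ValueError):
        monomers.subsample_by_genome_size(1000, 0.0, 1.0)


def test_frequency_recovery_on_error_free_reads(monomer):
    """Extracted variant frequencies track planted frequencies (±0.05)."""
    from satcons import simulate
    from satcons.simulate import AmplificationProfile, ShortReadSpec, SimulationConfig, SpeciesSpec

    trans = {"A": "G", "G": "A", "C": "T", "T": "C"}
    v2 = monomer[:5] + trans[monomer[5]] + monomer[6:]
    pool = Counter({monomer: 60, v2: 40})
    cfg = SimulationConfig(
        seed=5,
        species=(SpeciesSpec("sp", 0.0, AmplificationProfile(2, 90, 110)),),
        ancestral_monomer=monomer,
        background_length=20_000,
        short_read=ShortReadSpec(n_pairs=2500),  # ~25x
    )
    genome, truth = simulate.build_genome(pool, cfg, "sp")
    reads = [r for p in simulate.simulate_short_reads(genome, cfg, "sp") for r in p]
    counts = monomers.tally_and_filter(monomers.extract_monomers(reads, monomer))
    total_e = sum(counts.values())
    total_t = sum(truth.variant_frequencies.values())
    for seq, c in truth.variant_frequencies.items():
        canon = monomers.canonical_rotation(seq)
        assert abs(counts.get(canon, 0) / total_e - c / total_t) < 0.05
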