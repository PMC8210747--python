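"""Concatemer mapping, copy-number normalization, variant and valley profiles."""

import numpy as np
import pytest

from satcons import profiles
from satcons.seqio import SequenceRecord, reverse_complement

from conftest import random_seq


@pytest.fixture
def concat(monomer):
    return profiles.build_concatemer(monomer)


class TestConcatemer:
    def test_default_is_208(self, monomer):
        assert len(profiles.build_concatemer(monomer)) == 208

    def test_k2(self, monomer):
        assert len(profiles.build_concatemer(monomer, k=2)) == 104

    def test_periodic(self, concat):
        assert concat[0:52] == concat[52:104]

    def test_k_below_two_rejected(self, monomer):
        with pytest.raises(ValueError):
            profiles.build_concatemer(monomer, k=1)


def _mismatched(seq, positions):
    other = {"A": "C", "C": "G", "G": "T", "T": "A"}
    s = list(seq)
    for p in positions:
        s[p] = other[s[p]]
    return "".join(s)


class TestMapReads:
    def test_exact_gene_tiling(self, monomer, rng):
        gene = random_seq(rng, 1010, at=0.5)
        reads = [gene[i : i + 101] for i in range(0, 910, 10)] * 2
        refs = [("sat", profiles.build_concatemer(monomer)), ("gene", gene)]
        res = profiles.map_reads(reads, refs)
        assert res.profiles["sat"].aligned_bases == 0
        assert res.profiles["gene"].n_reads == len(reads)

    def test_single_read_depth_window(self, concat):
        read = concat[10:111]
        res = profiles.map_reads([read], [("sat", concat)])
        depth = res.profiles["sat"].depth
        assert depth[10:111].tolist() == [1] * 101
        assert depth.sum() == 101

    def test_reverse_complement_read_maps(self, concat):
        res = profiles.map_reads([reverse_complement(concat[10:111])], [("sat", concat)])
        assert res.profiles["sat"].depth[10:111].sum() == 101

    @pytest.mark.parametrize("threshold,assigned", [(0.90, 1), (0.95, 0)])
    def test_identity_threshold(self, concat, threshold, assigned):
        # 6 mismatches over 101 nt: identity 95/101 = 0.9406
        read = _mismatched(concat[50:151], [8, 25, 42, 59, 76, 93])
        res = profiles.map_reads([read], [("sat", concat)], min_identity=threshold)
        assert res.n_assigned == assigned

    def test_duplicate_reference_ids_rejected(self, concat):
        with pytest.raises(ValueError):
            profiles.map_reads([], [("sat", concat), ("sat", concat)])

    def test_local_mode_clips_array_boundary(self, monomer, concat, rng):
        # 60 nt of repeat then 41 nt of background: global fails, local
        # recovers the repeat half only
        read = concat[52:112] + random_seq(rng, 41, at=0.5)
        res_g = profiles.map_reads([read], [("sat", concat)], mode="global")
        res_l = profiles.map_reads([read], [("sat", concat)], mode="local")
        assert res_g.n_assigned == 0
        assert res_l.n_assigned == 1
        assert res_l.profiles["sat"].aligned_bases == 60

    def test_split_mapping_recovers_both_sides_of_a_deletion(self, monomer, concat):
        # a read crossing a 3-nt deletion maps one side per segment;
        # max_segments=2 recovers both
        copy_del = monomer[:21] + monomer[24:]
        read = (monomer + copy_del + monomer)[20:121]
        one = profiles.map_reads([read], [("sat", concat)], mode="local")
        two = profiles.map_reads([read], [("sat", concat)], mode="local", max_segments=2)
        assert two.profiles["sat"].aligned_bases > one.profiles["sat"].aligned_bases
        assert two.profiles["sat"].aligned_bases >= 95


class TestCopyNumber:
    def test_simple_ratio(self):
        assert profiles.copy_number(500.0, [5.0] * 10) == 100.0

    def test_zero_satellite(self):
        assert profiles.copy_number(0.0, [5.0] * 10) == 0.0

    def test_median_resists_outlier(self):
        genes = [4, 5, 6, 5, 5, 5, 5, 5, 5, 100]
        assert profiles.copy_number(50.0, genes) == 10.0

    def test_all_zero_genes_rejected(self):
        with pytest.raises(profiles.NormalizationError):
            profiles.copy_number(10.0, [0.0, 0.0])


class TestVariantFraction:
    def test_all_reference_reads(self, concat):
        res = profiles.map_reads([concat[i : i + 101] for i in range(0, 108, 4)], [("sat", concat)])
        frac = profiles.variant_fraction(res.profiles["sat"], concat)
        covered = ~np.isnan(frac)
        assert covered.any()
        assert np.nanmax(frac) == 0.0

    def test_substitution_at_monomer_position_32(self, monomer, concat):
        # half of the copies carry a substitution at monomer position 32
        # (1-based): reads from those copies show it at every concatemer
        # image of that position (31 + 52k, 0-based)
        variant = _mismatched(monomer, [31]) * 4
        reads = [concat, variant] * 3
        res = profiles.map_reads(reads, [("sat", concat)])
        frac = profiles.variant_fraction(res.profiles["sat"], concat)
        for image in (31, 83, 135, 187):
            assert frac[image] == pytest.approx(0.5)

    def test_uncovered_is_nan_not_zero(self, concat):
        res = profiles.map_reads([concat[0:101]], [("sat", concat)])
        frac = profiles.variant_fraction(res.profiles["sat"], concat)
        assert np.isnan(frac[150])
        assert frac[50] == 0.0


class TestCorrelation:
    def test_identical(self):
        x = np.array([1.0, 2.0, 3.0, 2.0])
        assert profiles.profile_correlation(x, x) == pytest.approx(1.0)

    def test_negation_about_mean(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert profiles.profile_correlation(x, 5 - x) == pytest.approx(-1.0)

    def test_affine_invariance(self):
        assert profiles.profile_correlation([1, 2, 3, 4], [2, 4, 6, 8]) == pytest.approx(1.0)

    def test_constant_profile_rejected(self):
        with pytest.raises(profiles.UndefinedCorrelationError):
            profiles.profile_correlation([1, 1, 1], [1, 2, 3])


class TestValleys:
    def test_uniform_profile_has_no_valleys(self):
        assert profiles.find_valleys(np.full(208, 50.0)) == []

    def test_half_depth_at_positions_22_to_24(self):
        depth = np.full(208, 100.0)
        for image in range(4):
            depth[image * 52 + 21 : image * 52 + 24] = 50.0
        assert profiles.find_valleys(depth) == [(22, 24)]

    def test_single_position_dip_needs_min_run(self):
        depth = np.full(208, 100.0)
        depth[21::52] = 10.0
        assert profiles.find_valleys(depth, min_run=2) == []
        assert profiles.find_valleys(depth, min_run=1) == [(22, 22)]

    def test_fold_invariant_to_k(self):
        base = np.full(52, 80.0)
        base[21:24] = 30.0
        for k in (2, 4, 6):
            assert profiles.find_valleys(np.tile(base, k)) == [(22, 24)]

    def test_empty_profile_has_no_valleys(self):
        assert profiles.find_valleys(np.zeros(208)) == []


def test_copy_number_recovery_parameter_sweep():
    """Planted copy numbers {10, 100, 1000} recovered within ±10% from
    error-free reads (estimator invariant; also an acceptance condition)."""
    from satcons.scenarios import run_copy_number_recovery

    for planted, (true_c, est) in run_copy_number_recovery(seed=7).items():
        assert est == pytest.approx(true_c, rel=0.10), planted


def test_shared_monomer_profiles_correlate_across_species(monomer):
    """Two species carrying the same monomer at low divergence give scaled
    profiles with r >= 0.95 at >= 20x coverage."""
    from satcons import simulate
    from satcons.simulate import AmplificationProfile, ShortReadSpec, SimulationConfig, SpeciesSpec

    scaled = {}
    for name, seed in (("a", 31), ("b", 77)):
        cfg = SimulationConfig(
            seed=seed,
            species=(SpeciesSpec(name, 0.005, AmplificationProfile(2, 60, 80)),),
            ancestral_monomer=monomer,
            homogenization=0.9,
            background_length=25_000,
            short_read=ShortReadSpec(n_pairs=3200),  # ~26x
        )
        pool = simulate.evolve_library(cfg)[name]
        genome, _ = simulate.build_genome(pool, cfg, name)
        reads = [r for p in simulate.simulate_short_reads(genome, cfg, name) for r in p]
        res = profiles.map_reads(reads, [("sat", profiles.build_concatemer(monomer))], mode="local")
        scaled[name] = res.profiles["sat"].scaled
    assert profiles.profile_correlation(scaled["a"], scaled["b"]) >= 0.95
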