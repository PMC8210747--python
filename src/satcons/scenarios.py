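"""Study conditions: the synthetic scenarios the analyses run on.

Every scenario function is deterministic given a seed and returns plain
package objects, so tests, the analysis drivers and the acceptance script
all execute the same conditions.  The default community emulates the
biological setting the package addresses: eight related species sharing one
ancestral 52-bp A+T-rich monomer, one species with large clustered
subtelomeric-style arrays and the rest carrying few short arrays, sequenced
as 2x101 read pairs and (for two species) noisy long reads.

Sizing notes (the package's own desk-scale choices): genomes are tens of
kilobases and coverages 20-80x; the shortest satellite loci are sequenced
deepest because the coverage estimate of a 500-bp locus at 20x has ~10%
relative sampling error.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import longread, monomers, profiles, simulate
from .simulate import (
    AmplificationProfile,
    LongReadSpec,
    ShortReadSpec,
    SimulationConfig,
    SpeciesSpec,
)

__all__ = [
    "DEFAULT_MONOMER",
    "default_config",
    "make_gene_panel",
    "run_copy_number_recovery",
    "run_variant_frequency_recovery",
    "run_valley_detection",
    "run_array_length_recovery",
    "run_density_ratio",
    "run_expression_ratio",
]

#: Synthetic ancestral monomer: 52 nt, 65.4% A+T, fixed once for the package.
DEFAULT_MONOMER = "GCCCTGGCTAATATTTAATCGAACTGATACGACTCGTATCATATTTAATCAT"

_READ_LEN = 101


def make_gene_panel(
    n_genes: int = 10, length: int = 1500, seed: int = 7_777
) -> list[tuple[str, str]]:
    """Synthetic single-copy normalization genes (random 50% A+T loci)."""
    rng = np.random.default_rng(seed)
    return [
        (f"gene{i:02d}", simulate.random_background(length, 0.5, rng))
        for i in range(n_genes)
    ]


def default_config(seed: int, coverage: float = 15.0) -> SimulationConfig:
    """Eight-species community, 50-kb genomes, one clustered-array species.

    Branch lengths span 0.02-0.12 substitutions/site; `clustered` carries
    4 arrays of 80-110 copies (subtelomeric-style amplification; ~20 kb of
    satellite, the most that fits a 50-kb genome alongside the gene panel),
    the other species 2-4 short arrays of 8-30 copies.
    """
    species = [
        SpeciesSpec("clustered_sp1", 0.04, AmplificationProfile(4, 80, 110)),
        SpeciesSpec("dispersed_sp2", 0.02, AmplificationProfile(3, 10, 30)),
        SpeciesSpec("dispersed_sp3", 0.04, AmplificationProfile(2, 8, 25)),
        SpeciesSpec("dispersed_sp4", 0.06, AmplificationProfile(3, 10, 30)),
        SpeciesSpec("dispersed_sp5", 0.06, AmplificationProfile(4, 8, 20)),
        SpeciesSpec("dispersed_sp6", 0.08, AmplificationProfile(2, 10, 30)),
        SpeciesSpec("dispersed_sp7", 0.10, AmplificationProfile(3, 8, 25)),
        SpeciesSpec("dispersed_sp8", 0.12, AmplificationProfile(2, 10, 20)),
    ]
    background = 50_000
    n_pairs = int(background * coverage / (2 * _READ_LEN))
    return SimulationConfig(
        seed=seed,
        species=tuple(species),
        ancestral_monomer=DEFAULT_MONOMER,
        substitution_rate=1.0,
        kappa=2.0,
        homogenization=0.6,
        background_length=background,
        background_at=0.65,
        short_read=ShortReadSpec(n_pairs=n_pairs),
        long_read=LongReadSpec(n_reads=20, mean_log=8.6, sd_log=0.35),
    )


def _single_species_config(
    seed: int,
    amplification: AmplificationProfile,
    background: int,
    coverage: float,
    branch_length: float = 0.01,
    homogenization: float = 0.8,
    long_read: Optional[LongReadSpec] = None,
) -> SimulationConfig:
    return SimulationConfig(
        seed=seed,
        species=(SpeciesSpec("sp", branch_length, amplification),),
        ancestral_monomer=DEFAULT_MONOMER,
        homogenization=homogenization,
        background_length=background,
        short_read=ShortReadSpec(n_pairs=int(background * coverage / (2 * _READ_LEN))),
        long_read=long_read,
    )


def run_copy_number_recovery(
    seed: int, planted: Sequence[int] = (10, 100, 1000)
) -> dict[int, tuple[int, float]]:
    """Planted-vs-estimated copy number for each target copy count.

    Returns {planted: (true copies, estimated copies)}.  Reads are
    error-free; the mapping runs in local mode against the 208-nt concatemer
    plus ten single-copy genes.  Coverage rises as the satellite locus
    shrinks (300x for C=10) because the realized sequencing depth of a
    520-bp locus fluctuates by several percent even when the genome-wide
    mean is exact; the estimator can only recover what was sequenced.
    """
    layouts = {
        10: (1, 10, 10, 10_000, 300.0, 500),
        100: (2, 50, 50, 60_000, 80.0, 1500),
        1000: (5, 200, 200, 120_000, 20.0, 1500),
    }
    out: dict[int, tuple[int, float]] = {}
    for c in planted:
        n_arrays, cmin, cmax, background, coverage, gene_len = layouts[c]
        genes = make_gene_panel(length=gene_len)
        refs = [("sat", profiles.build_concatemer(DEFAULT_MONOMER))] + genes
        cfg = _single_species_config(
            seed, AmplificationProfile(n_arrays, cmin, cmax), background, coverage
        )
        pool = simulate.evolve_library(cfg)["sp"]
        genome, truth = simulate.build_genome(pool, cfg, "sp", extra_segments=genes)
        reads = [r for p in simulate.simulate_short_reads(genome, cfg, "sp") for r in p]
        result = profiles.map_reads(reads, refs, mode="local")
        est = profiles.estimate_copy_number(result, "sat", [g for g, _ in genes])
        out[c] = (truth.copy_number, est)
    return out


def _structured_pool(variants: Sequence[tuple[str, int]]) -> Counter:
    return Counter(dict(variants))


def _mutant(base: str, positions: Sequence[int]) -> str:
    """Substitute a transition at each given 0-based position."""
    trans = {"A": "G", "G": "A", "C": "T", "T": "C"}
    s = list(base)
    for p in positions:
        s[p] = trans[s[p]]
    return "".join(s)


def run_variant_frequency_recovery(seed: int, coverage: float = 25.0):
    """Recover planted variant frequencies and a 5-of-8-species variant.

    Five species carry the ancestral monomer among their variants; three
    diverged species carry private variants only.  For the first species the
    planted variant frequencies are compared with the frequencies extracted
    from its error-free reads.  Returns (max abs frequency error, extracted
    VariantPool, species count of the most widely shared variant).
    """
    anc = DEFAULT_MONOMER
    shared_specs = [
        [(anc, 50), (_mutant(anc, [5]), 30), (_mutant(anc, [12, 40]), 20)],
        [(anc, 40), (_mutant(anc, [7]), 35)],
        [(anc, 60), (_mutant(anc, [3, 22]), 25), (_mutant(anc, [31]), 15)],
        [(anc, 55), (_mutant(anc, [18]), 20)],
        [(anc, 45), (_mutant(anc, [44, 9]), 30)],
    ]
    private_specs = [
        [(_mutant(anc, [1, 10, 20, 30, 40, 50]), 70)],
        [(_mutant(anc, [2, 11, 21, 31, 41]), 60), (_mutant(anc, [2, 11, 21, 31, 41, 8]), 25)],
        [(_mutant(anc, [4, 14, 24, 34, 44, 6]), 80)],
    ]
    background = 20_000
    pools = monomers.VariantPool()
    max_err = 0.0
    for i, spec_variants in enumerate(shared_specs + private_specs):
        name = f"sp{i + 1}"
        cfg = SimulationConfig(
            seed=seed,
            species=(SpeciesSpec(name, 0.0, AmplificationProfile(2, 90, 110)),),
            ancestral_monomer=anc,
            background_length=background,
            short_read=ShortReadSpec(n_pairs=int(background * coverage / (2 * _READ_LEN))),
        )
        pool = _structured_pool(spec_variants)
        genome, truth = simulate.build_genome(pool, cfg, name)
        reads = [r for p in simulate.simulate_short_reads(genome, cfg, name) for r in p]
        raw = monomers.extract_monomers(reads, anc)
        counts = monomers.tally_and_filter(raw)
        pools.add_species(name, counts)
        if i == 0:
            total_t = sum(truth.variant_frequencies.values())
            total_e = sum(counts.values())
            truth_canon = Counter()
            for s, c in truth.variant_frequencies.items():
                truth_canon[monomers.canonical_rotation(s)] += c
            for s, c in truth_canon.items():
                err = abs(counts.get(s, 0) / total_e - c / total_t)
                max_err = max(max_err, err)
    from .mst import shared_variants

    shared = shared_variants(pools, min_species=2)
    top_shared = shared[0].n_species if shared else 0
    return max_err, pools, top_shared


def run_valley_detection(seed: int, coverage: float = 40.0):
    """Plant a 3-bp deletion (monomer positions 22-24) in half of all copies.

    Builds arrays whose copies are a 50:50 mix of the full consensus and a
    49-nt copy lacking positions 22-24 (1-based), sequences error-free
    reads, maps them in local mode and runs valley detection on the folded
    coverage profile.  Returns the valley interval list.
    """
    anc = DEFAULT_MONOMER
    deleted = anc[:21] + anc[24:]  # drop 1-based positions 22, 23, 24
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x7A11E]))
    background = simulate.random_background(30_000, 0.65, rng)
    copies = [anc if rng.random() < 0.5 else deleted for _ in range(300)]
    array_seq = "".join(copies)
    mid = 12_000
    genome = background[:mid] + array_seq + background[mid:]
    cfg = SimulationConfig(
        seed=seed,
        species=(SpeciesSpec("sp", 0.0, AmplificationProfile(0, 1, 1)),),
        ancestral_monomer=anc,
        background_length=len(genome),
        short_read=ShortReadSpec(n_pairs=int(len(genome) * coverage / (2 * _READ_LEN))),
    )
    reads = [r for p in simulate.simulate_short_reads(genome, cfg, "valley") for r in p]
    refs = [("sat", profiles.build_concatemer(anc))]
    # split mapping: a read crossing a deletion junction continues on a
    # shifted diagonal; keeping its disjoint segments preserves flank depth
    result = profiles.map_reads(reads, refs, mode="local", max_segments=3)
    return profiles.find_valleys(result.profiles["sat"])


def run_array_length_recovery(
    seed: int,
    copy_numbers: Sequence[int] = (10, 19, 38, 58, 77),
    replicates: int = 6,
    error_rate: float = 0.15,
) -> dict[int, tuple[int, float]]:
    """Detect planted arrays of 0.5-4 kb in 15%-error reads.

    For each planted size, ``replicates`` independent reads carry one array
    with 1.5-kb flanks; returns {copies: (planted length in the read,
    mean detected length)} where planted length is averaged over replicates
    (indels make each read's truth length differ slightly).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA88A7]))
    out: dict[int, tuple[int, float]] = {}
    for c in copy_numbers:
        planted_lens: list[int] = []
        detected_lens: list[int] = []
        for _ in range(replicates):
            src = (
                simulate.random_background(1500, 0.65, rng)
                + DEFAULT_MONOMER * c
                + simulate.random_background(1500, 0.65, rng)
            )
            codes = simulate._encode(src)
            noisy, posmap = simulate._apply_long_read_noise(codes, error_rate, 0.6, rng)
            read = simulate._decode(noisy)
            t0, t1 = int(posmap[1500]), int(posmap[1500 + 52 * c])
            planted_lens.append(t1 - t0)
            intervals = longread.detect_arrays(read, DEFAULT_MONOMER)
            detected_lens.append(max((len(iv) for iv in intervals), default=0))
        out[c] = (int(np.mean(planted_lens)), float(np.mean(detected_lens)))
    return out


def run_density_ratio(seed: int, n_reads: int = 800):
    """Clustered vs dispersed long-read density of a planted ~20x difference.

    Two single-species genomes of 120 kb: clustered 5x200 copies, dispersed
    5x10 copies (planted copy ratio 20).  Long reads at 15% error are
    scanned for arrays; returns (planted fold, detected fold) of per-genome
    kb/Mb densities, with the planted fold computed from the truth
    annotations.  The read count keeps the dispersed genome's array-sampling
    noise well inside the comparison tolerance.
    """
    genomes = {
        "clustered": AmplificationProfile(5, 200, 200),
        "dispersed": AmplificationProfile(5, 10, 10),
    }
    planted_frac: dict[str, float] = {}
    detected_density: dict[str, float] = {}
    for name, amp in genomes.items():
        cfg = _single_species_config(
            seed,
            amp,
            background=120_000,
            coverage=1.0,
            long_read=LongReadSpec(n_reads=n_reads, mean_log=8.4, sd_log=0.3),
        )
        pool = simulate.evolve_library(cfg)["sp"]
        genome, truth = simulate.build_genome(pool, cfg, "sp")
        reads, read_truth = simulate.simulate_long_reads(
            genome, cfg, truth.intervals, name
        )
        planted_frac[name] = sum(len(iv) for iv in truth.intervals) / len(genome)
        intervals = []
        total = 0
        for read in reads:
            total += len(read)
            intervals.extend(longread.detect_arrays(read, DEFAULT_MONOMER))
        detected_density[name] = longread.repeat_density(intervals, total).density
    planted_fold = planted_frac["clustered"] / planted_frac["dispersed"]
    detected_fold = detected_density["clustered"] / detected_density["dispersed"]
    return planted_fold, detected_fold


def run_expression_ratio(seed: int, n_reads: int = 30_000):
    """FPKM recovery of a 2x transcription-rate difference.

    RNA reads are sampled from the satellite concatemer at twice the rate of
    an equal-length gene; reads are mapped and FPKM computed per target.
    Returns the satellite/gene FPKM ratio (expected ~2).
    """
    from . import expression

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xF9]))
    concat = profiles.build_concatemer(DEFAULT_MONOMER)
    gene = simulate.random_background(len(concat), 0.5, rng)
    targets = {"sat": concat, "gene": gene}
    reads = simulate.simulate_rna_reads(targets, {"sat": 2.0, "gene": 1.0}, n_reads, seed)
    result = profiles.map_reads(reads, list(targets.items()), mode="global")
    counts = result.counts()
    table = expression.fpkm_table(counts, {t: len(s) for t, s in targets.items()})
    f = dict(zip(table["target"], table["fpkm"]))
    return f["sat"] / f["gene"]
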