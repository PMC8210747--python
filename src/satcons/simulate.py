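"""Synthetic species sets with known satellite content.

The generator follows the library model of satellite evolution: a single
ancestral monomer is inherited by every species, each species' consensus
diverges from the ancestor in proportion to its branch length, and each
lineage independently amplifies the repeat into tandem arrays.  Within a
species, new copies either reproduce the species consensus (concerted-
evolution homogenization, probability ``homogenization``) or carry private
mutations.  Mutations are per-site i.i.d. with a transition bias kappa, the
same process the K2P distance models downstream.

Genomes are random background of a chosen A+T composition with head-to-tail
arrays carved in at uniform non-overlapping positions (either strand), and
every planted array, copy and variant frequency is recorded as ground truth.
Short reads are error-optional 2x101 inward pairs; long reads carry
indel-dominated noise at a PacBio-like rate with truth intervals re-expressed
in read coordinates.  A fixed master seed makes every output byte-identical;
each output stream draws from its own child generator so adding one output
does not perturb the others.
"""

from __future__ import annotations

import zlib
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .seqio import IntervalRecord, SequenceRecord, reverse_complement
from .monomers import MONOMER_LENGTH

__all__ = [
    "SimulationConfig",
    "SpeciesSpec",
    "AmplificationProfile",
    "ShortReadSpec",
    "LongReadSpec",
    "GenomeTruth",
    "ConfigurationError",
    "SizingError",
    "evolve_library",
    "build_genome",
    "simulate_short_reads",
    "simulate_long_reads",
    "simulate_rna_reads",
    "random_background",
    "stream",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class ConfigurationError(ValueError):
    pass


class SizingError(ValueError):
    pass


@dataclass(frozen=True)
class AmplificationProfile:
    """Arrays per genome and the inclusive range of copies per array."""

    n_arrays: int
    copies_min: int
    copies_max: int

    def __post_init__(self) -> None:
        if self.n_arrays < 0 or self.copies_min < 1 or self.copies_max < self.copies_min:
            raise ConfigurationError(f"invalid amplification profile {self}")


@dataclass(frozen=True)
class SpeciesSpec:
    name: str
    branch_length: float  # substitutions/site from the ancestor
    amplification: AmplificationProfile

    def __post_init__(self) -> None:
        if self.branch_length < 0:
            raise ConfigurationError("branch length must be >= 0")


@dataclass(frozen=True)
class ShortReadSpec:
    n_pairs: int
    read_length: int = 101
    error_rate: float = 0.0
    insert_size: int = 300
    insert_sd: float = 30.0


@dataclass(frozen=True)
class LongReadSpec:
    n_reads: int
    mean_log: float = 8.8  # log-normal length law, ~8 kb median with sd_log 0.35
    sd_log: float = 0.35
    min_length: int = 500
    error_rate: float = 0.15
    indel_fraction: float = 0.6


@dataclass(frozen=True)
class SimulationConfig:
    seed: int
    species: tuple[SpeciesSpec, ...]
    ancestral_monomer: str
    substitution_rate: float = 1.0  # per site per unit branch length
    kappa: float = 2.0  # transition:transversion probability ratio
    homogenization: float = 0.5
    background_length: int = 50_000
    background_at: float = 0.65
    short_read: ShortReadSpec = ShortReadSpec(n_pairs=5000)
    long_read: Optional[LongReadSpec] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "species", tuple(self.species))
        if len(self.ancestral_monomer) != MONOMER_LENGTH:
            raise ConfigurationError(
                f"ancestral monomer length {len(self.ancestral_monomer)} != {MONOMER_LENGTH}"
            )
        if set(self.ancestral_monomer) - set("ACGT"):
            raise ConfigurationError("ancestral monomer must be ACGT")
        for name, value in (
            ("homogenization", self.homogenization),
            ("background_at", self.background_at),
        ):
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name}={value} outside [0, 1]")
        if self.substitution_rate < 0 or self.kappa <= 0:
            raise ConfigurationError("substitution_rate >= 0 and kappa > 0 required")
        names = [sp.name for sp in self.species]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate species names")

    def species_by_name(self, name: str) -> SpeciesSpec:
        for sp in self.species:
            if sp.name == name:
                return sp
        raise KeyError(name)


@dataclass
class GenomeTruth:
    """Ground truth for one simulated genome."""

    species: str
    genome_length: int
    intervals: list[IntervalRecord]  # planted arrays, genome coordinates
    variant_frequencies: Counter  # monomer sequence -> planted copy count
    copy_number: int  # total monomer copies per 1C
    gene_intervals: list[IntervalRecord] = field(default_factory=list)


def stream(seed: int, label: str) -> np.random.Generator:
    """Independent child generator derived from the master seed and a label."""
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(label.encode())]))


def random_background(length: int, at_fraction: float, rng: np.random.Generator) -> str:
    """Random sequence with expected A+T composition ``at_fraction``."""
    p = [at_fraction / 2, (1 - at_fraction) / 2, (1 - at_fraction) / 2, at_fraction / 2]
    codes = rng.choice(4, size=length, p=p)
    return _BASES[codes].tobytes().decode("ascii")


def _encode(seq: str) -> np.ndarray:
    lut = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    return lut[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def mutate(seq: str, p_site: float, kappa: float, rng: np.random.Generator) -> str:
    """Per-site i.i.d. mutation with transition probability kappa/(kappa+2).

    Draw order (documented because tests replay it): one uniform per site for
    the hit mask, then per hit one uniform for transition-vs-transversion and
    one integer for the transversion choice.
    """
    codes = _encode(seq)
    hits = np.flatnonzero(rng.random(len(codes)) < p_site)
    for i in hits:
        if rng.random() < kappa / (kappa + 2.0):
            codes[i] = (codes[i] + 2) % 4  # transition: A<->G, C<->T
        else:
            codes[i] = (codes[i] + (1 if rng.integers(2) == 0 else 3)) % 4
    return _decode(codes)


def evolve_library(config: SimulationConfig) -> dict[str, Counter]:
    """Per-species monomer frequency tables under the library model.

    Each species' consensus is the ancestor mutated at per-site probability
    branch_length * substitution_rate; the species pool holds one entry per
    planned copy, each either the consensus (probability ``homogenization``)
    or a privately re-mutated consensus.
    """
    if not config.species:
        raise ConfigurationError("empty species list")
    pools: dict[str, Counter] = {}
    for sp in config.species:
        rng = stream(config.seed, f"library:{sp.name}")
        p = sp.branch_length * config.substitution_rate
        consensus = mutate(config.ancestral_monomer, p, config.kappa, rng)
        amp = sp.amplification
        sizes = rng.integers(amp.copies_min, amp.copies_max + 1, size=amp.n_arrays)
        pool: Counter = Counter()
        for _ in range(int(sizes.sum())):
            if rng.random() < config.homogenization:
                pool[consensus] += 1
            else:
                pool[mutate(consensus, p, config.kappa, rng)] += 1
        if not pool:
            pool[consensus] = 1  # a species always carries >= 1 variant
        pools[sp.name] = pool
    return pools


def _place_segments(
    lengths: Sequence[int],
    background_length: int,
    rng: np.random.Generator,
    occupied: list[tuple[int, int]],
    max_attempts: int = 1000,
    max_restarts: int = 50,
) -> list[int]:
    """Uniform non-overlapping starts by rejection sampling.

    Each segment gets up to ``max_attempts`` uniform draws; if a draw order
    paints the space into a corner the whole set is redrawn (up to
    ``max_restarts`` times) before declaring the request unplaceable.
    Segments are drawn longest-first, which keeps large arrays from being
    squeezed out by earlier small placements.
    """
    if sum(lengths) + sum(e - s for s, e in occupied) > background_length:
        raise SizingError(
            f"segments totalling {sum(lengths)} nt do not fit in "
            f"{background_length} nt of background"
        )
    if any(seg_len > background_length for seg_len in lengths):
        raise SizingError("a segment exceeds the background length")
    order = sorted(range(len(lengths)), key=lambda i: (-lengths[i], i))
    base_occupied = list(occupied)
    for _ in range(max_restarts):
        placed: dict[int, int] = {}
        trial = list(base_occupied)
        for idx in order:
            seg_len = lengths[idx]
            for _attempt in range(max_attempts):
                s = int(rng.integers(0, background_length - seg_len + 1))
                if all(e0 <= s or s + seg_len <= s0 for s0, e0 in trial):
                    break
            else:
                break
            trial.append((s, s + seg_len))
            placed[idx] = s
        if len(placed) == len(lengths):
            occupied[:] = trial
            return [placed[i] for i in range(len(lengths))]
    raise SizingError(
        f"could not place {len(lengths)} segments after {max_restarts} restarts"
    )


def build_genome(
    species_pool: Mapping[str, int],
    config: SimulationConfig,
    species_name: str,
    extra_segments: Sequence[tuple[str, str]] = (),
) -> tuple[str, GenomeTruth]:
    """Carve tandem arrays (and optional single-copy segments) into background.

    Arrays are head-to-tail concatenations of copies sampled from the species
    frequency table, planted on either strand at uniform non-overlapping
    positions.  ``extra_segments`` (label, sequence) plants single-copy loci
    such as normalization genes; their intervals are recorded separately.
    Returns the genome and its :class:`GenomeTruth`.
    """
    if not species_pool:
        raise ConfigurationError("empty species pool")
    rng = stream(config.seed, f"genome:{species_name}")
    spec = config.species_by_name(species_name)
    amp = spec.amplification
    sizes = rng.integers(amp.copies_min, amp.copies_max + 1, size=amp.n_arrays)
    seqs = sorted(species_pool)
    counts = np.array([species_pool[s] for s in seqs], dtype=float)
    probs = counts / counts.sum()

    arrays: list[tuple[str, str, Counter]] = []  # (sequence as planted, strand, copies)
    for n_copies in sizes:
        idx = rng.choice(len(seqs), size=int(n_copies), p=probs)
        copies = Counter(seqs[i] for i in idx)
        array_seq = "".join(seqs[i] for i in idx)
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            array_seq = reverse_complement(array_seq)
        arrays.append((array_seq, strand, copies))

    background = random_background(config.background_length, config.background_at, rng)
    occupied: list[tuple[int, int]] = []
    gene_lengths = [len(seq) for _, seq in extra_segments]
    gene_starts = _place_segments(gene_lengths, config.background_length, rng, occupied)
    array_starts = _place_segments(
        [len(a) for a, _, _ in arrays], config.background_length, rng, occupied
    )

    genome = list(background)
    truth_intervals: list[IntervalRecord] = []
    gene_intervals: list[IntervalRecord] = []
    freqs: Counter = Counter()
    for (label, seq), start in zip(extra_segments, gene_starts):
        genome[start : start + len(seq)] = seq
        gene_intervals.append(IntervalRecord(species_name, start, start + len(seq), label))
    for (array_seq, strand, copies), start in zip(arrays, array_starts):
        genome[start : start + len(array_seq)] = array_seq
        truth_intervals.append(
            IntervalRecord(
                species_name,
                start,
                start + len(array_seq),
                "sat",
                float(sum(copies.values())),
                strand,
            )
        )
        freqs.update(copies)
    truth_intervals.sort()
    gene_intervals.sort()
    truth = GenomeTruth(
        species=species_name,
        genome_length=len(genome),
        intervals=truth_intervals,
        variant_frequencies=freqs,
        copy_number=int(sizes.sum()),
        gene_intervals=gene_intervals,
    )
    return "".join(genome), truth


def _substitute(codes: np.ndarray, error_rate: float, rng: np.random.Generator) -> np.ndarray:
    if error_rate <= 0:
        return codes
    mask = rng.random(codes.size) < error_rate
    n = int(mask.sum())
    if n:
        codes = codes.copy()
        codes[mask] = (codes[mask] + rng.integers(1, 4, size=n)) % 4
    return codes


def simulate_short_reads(
    genome: str,
    config: SimulationConfig,
    label: str = "genome",
) -> list[tuple[SequenceRecord, SequenceRecord]]:
    """Paired 2x``read_length`` reads from inward-facing fragments.

    With error_rate 0 every read is an exact substring of the genome or its
    reverse complement.  Qualities are constant and left implicit (the FASTQ
    writer emits Q40).
    """
    sr = config.short_read
    G = len(genome)
    if G <= sr.read_length:
        raise SizingError(f"genome of {G} nt shorter than read length {sr.read_length}")
    rng = stream(config.seed, f"short:{label}")
    codes = _encode(genome)
    pairs: list[tuple[SequenceRecord, SequenceRecord]] = []
    frag_lens = np.clip(
        np.rint(rng.normal(sr.insert_size, sr.insert_sd, size=sr.n_pairs)).astype(int),
        sr.read_length,
        G,
    )
    starts = (rng.random(sr.n_pairs) * (G - frag_lens + 1)).astype(int)
    flips = rng.random(sr.n_pairs) < 0.5
    for i in range(sr.n_pairs):
        s, f = int(starts[i]), int(frag_lens[i])
        fwd = codes[s : s + sr.read_length]
        rev = 3 - codes[s + f - sr.read_length : s + f][::-1]  # reverse complement
        r1, r2 = (rev, fwd) if flips[i] else (fwd, rev)
        r1 = _substitute(r1, sr.error_rate, rng)
        r2 = _substitute(r2, sr.error_rate, rng)
        name = f"{label}_pair{i:07d}"
        pairs.append(
            (
                SequenceRecord(f"{name}/1", _decode(r1)),
                SequenceRecord(f"{name}/2", _decode(r2)),
            )
        )
    return pairs


def _apply_long_read_noise(
    source: np.ndarray,
    error_rate: float,
    indel_fraction: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Return (read codes, posmap) where posmap[i] is the read position of
    source base i (posmap has length len(source)+1; the last entry is the
    read length)."""
    L = source.size
    u = rng.random(L)
    kind = np.zeros(L, dtype=np.int8)  # 0 keep, 1 sub, 2 ins-after, 3 del
    err = u < error_rate
    v = rng.random(L)
    kind[err & (v >= indel_fraction)] = 1
    kind[err & (v < indel_fraction / 2)] = 2
    kind[err & (v >= indel_fraction / 2) & (v < indel_fraction)] = 3
    subs = rng.integers(1, 4, size=L)
    inserts = rng.integers(0, 4, size=L)
    out = np.empty(L * 2, dtype=np.uint8)
    posmap = np.empty(L + 1, dtype=np.int64)
    n = 0
    for i in range(L):
        posmap[i] = n
        k = kind[i]
        if k == 3:
            continue
        if k == 1:
            out[n] = (source[i] + subs[i]) % 4
        else:
            out[n] = source[i]
        n += 1
        if k == 2:
            out[n] = inserts[i]
            n += 1
    posmap[L] = n
    return out[:n], posmap


def simulate_long_reads(
    genome: str,
    config: SimulationConfig,
    truth_intervals: Sequence[IntervalRecord] = (),
    label: str = "genome",
) -> tuple[list[SequenceRecord], dict[str, list[IntervalRecord]]]:
    """Noisy long reads with truth arrays re-expressed in read coordinates.

    Read lengths follow a log-normal law clipped to [min_length, genome];
    errors hit each base at ``error_rate`` and are split into substitutions
    and (half insertions, half deletions) by ``indel_fraction``.  Returns the
    reads and, per read id, the planted-array intervals it overlaps.
    """
    lr = config.long_read
    if lr is None:
        raise ConfigurationError("config.long_read is not set")
    G = len(genome)
    if G < lr.min_length:
        raise SizingError(f"genome of {G} nt shorter than min read length {lr.min_length}")
    rng = stream(config.seed, f"long:{label}")
    codes = _encode(genome)
    reads: list[SequenceRecord] = []
    read_truth: dict[str, list[IntervalRecord]] = {}
    for i in range(lr.n_reads):
        L = int(np.clip(rng.lognormal(lr.mean_log, lr.sd_log), lr.min_length, G))
        # molecules may run off either genome end (truncated reads), so
        # per-base sampling is uniform with no shadow zones at the edges
        s0 = int(rng.integers(-(L - 1), G))
        s = max(0, s0)
        L = min(G, s0 + L) - s
        if L < 52:
            continue
        source = codes[s : s + L]
        read_strand = "+" if rng.random() < 0.5 else "-"
        if read_strand == "-":
            source = 3 - source[::-1]
        out, posmap = _apply_long_read_noise(source, lr.error_rate, lr.indel_fraction, rng)
        name = f"{label}_read{i:05d}"
        reads.append(SequenceRecord(name, _decode(out)))
        ivs: list[IntervalRecord] = []
        for iv in truth_intervals:
            a, b = max(iv.start, s), min(iv.end, s + L)
            if b - a < 1:
                continue
            if read_strand == "+":
                sa, sb = a - s, b - s
                strand = iv.strand
            else:
                sa, sb = L - (b - s), L - (a - s)
                strand = "-" if iv.strand == "+" else "+"
            ra, rb = int(posmap[sa]), int(posmap[sb])
            if rb - ra >= 1:
                ivs.append(IntervalRecord(name, ra, rb, iv.label, iv.score, strand))
        if ivs:
            read_truth[name] = sorted(ivs)
    return reads, read_truth


def simulate_rna_reads(
    targets: Mapping[str, str],
    rates: Mapping[str, float],
    n_reads: int,
    seed: int,
    read_length: int = 101,
    error_rate: float = 0.0,
    label: str = "rna",
) -> list[SequenceRecord]:
    """Single-end RNA reads sampled from targets at per-target rates.

    A read's target is drawn with probability proportional to
    rate * (length - read_length + 1), so the expected FPKM of equal-length
    targets is proportional to their rates.
    """
    ids = sorted(targets)
    weights = np.array(
        [max(len(targets[t]) - read_length + 1, 0) * rates.get(t, 0.0) for t in ids],
        dtype=float,
    )
    if weights.sum() <= 0:
        raise ConfigurationError("no target is long enough / has positive rate")
    probs = weights / weights.sum()
    rng = stream(seed, f"rna:{label}")
    enc = {t: _encode(targets[t]) for t in ids}
    choices = rng.choice(len(ids), size=n_reads, p=probs)
    reads: list[SequenceRecord] = []
    for i in range(n_reads):
        t = ids[int(choices[i])]
        codes = enc[t]
        s = int(rng.integers(0, codes.size - read_length + 1))
        r = codes[s : s + read_length]
        if rng.random() < 0.5:
            r = 3 - r[::-1]
        r = _substitute(r, error_rate, rng)
        reads.append(SequenceRecord(f"{label}_read{i:07d}", _decode(r)))
    return reads
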