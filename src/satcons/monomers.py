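"""Satellite monomer extraction from short reads, tallying and composition.

The extractor recovers complete monomer copies directly from reads: each read
(both strands) is scanned for the 52-nt window that best matches any rotation
of the consensus; if that window clears the identity floor the read's repeat
phase is locked and every complete in-phase window is emitted.  Variants are
exact canonical-rotation sequences, so copies read in different phases tally
together, and singletons (count 1) are discarded by default, mirroring
standard satellitome practice.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Union

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .seqio import SequenceRecord, reverse_complement

__all__ = [
    "MonomerVariant",
    "VariantPool",
    "canonical_rotation",
    "extract_monomers",
    "phase_align",
    "tally_and_filter",
    "consensus_and_composition",
    "subsample_by_genome_size",
    "MONOMER_LENGTH",
]

MONOMER_LENGTH = 52
_BASES = "ACGT"


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class MonomerVariant:
    """A canonical-rotation monomer sequence with its abundance in a species."""

    sequence: str
    count: int
    species: str

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("variant count must be >= 1")
        if self.sequence != canonical_rotation(self.sequence):
            raise ValueError("variant sequence must be its own canonical rotation")


@dataclass
class VariantPool:
    """Per-species tallies of canonical monomer variants.

    ``species_variants`` maps species name to ``{sequence: count}``;
    provenance records whether monomers came from genomic or transcriptomic
    reads.
    """

    species_variants: dict[str, Counter] = field(default_factory=dict)
    provenance: str = "genomic"

    def add_species(self, species: str, counts: Mapping[str, int]) -> None:
        self.species_variants[species] = Counter(counts)

    def species(self) -> list[str]:
        return list(self.species_variants)

    def counts(self, species: str) -> Counter:
        return self.species_variants[species]

    def total(self, species: str) -> int:
        return sum(self.species_variants[species].values())

    def frequencies(self, species: str) -> dict[str, float]:
        total = self.total(species)
        return {s: c / total for s, c in self.species_variants[species].items()}

    def variants(self, species: str) -> list[MonomerVariant]:
        return [
            MonomerVariant(seq, count, species)
            for seq, count in sorted(self.species_variants[species].items())
        ]


def canonical_rotation(sequence: str) -> str:
    """Lexicographically minimal rotation of ``sequence``.

    Idempotent and invariant over the rotation class; the monomer is short
    enough that direct comparison over all rotations is exact and cheap.
    """
    if not sequence:
        raise ValueError("empty sequence")
    return min(sequence[i:] + sequence[:i] for i in range(len(sequence)))


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def extract_monomers(
    reads: Iterable[Union[str, SequenceRecord]],
    consensus: str,
    min_identity: float = 0.70,
    window_min_identity: float = 0.50,
) -> list[str]:
    """Extract complete in-phase monomer windows from reads.

    For each read and both strands, the best-identity 52-nt window against
    any rotation of ``consensus`` is located (ungapped, identity =
    matches/52).  If it reaches ``min_identity``, the repeat phase is locked
    to the consensus frame: the matched rotation offset shifts the window
    grid so that every emitted window starts at consensus coordinate 0.
    Anchoring the frame this way keeps windows from straddling copy
    boundaries, which would split multi-substitution variants into chimeric
    window sequences.  In-phase windows below ``window_min_identity`` to the
    consensus are discarded (a read overlapping an array edge would
    otherwise emit flanking non-repeat windows), as are windows truncated
    by read ends or containing N.  Returned monomers are raw (in consensus
    frame, not canonicalized).
    """
    m = len(consensus)
    if m != MONOMER_LENGTH:
        raise ConfigurationError(f"consensus length {m} != {MONOMER_LENGTH}")
    rotations = np.stack([_encode(consensus[i:] + consensus[:i]) for i in range(m)])
    min_matches = min_identity * m
    out: list[str] = []
    for read in reads:
        seq = read.sequence if isinstance(read, SequenceRecord) else read
        if len(seq) < m:
            continue
        best_matches = -1
        best_seq = seq
        best_pos = 0
        best_rot = 0
        for strand_seq in (seq, reverse_complement(seq)):
            arr = _encode(strand_seq)
            windows = sliding_window_view(arr, m)
            matches = (windows[:, None, :] == rotations[None, :, :]).sum(axis=2)
            top = int(matches.max())
            if top > best_matches:
                best_matches = top
                best_seq = strand_seq
                flat = int(np.argmax(matches))
                best_pos, best_rot = divmod(flat, m)
        if best_matches < min_matches:
            continue
        # rotation r means read position best_pos sits at consensus
        # coordinate r; shift the window grid onto consensus coordinate 0
        phase = (best_pos - best_rot) % m
        for p in range(phase, len(best_seq) - m + 1, m):
            window = best_seq[p : p + m]
            if "N" in window:
                continue
            w_ident = (_encode(window) == rotations[0]).sum() / m
            if w_ident >= window_min_identity:
                out.append(window)
    return out


def phase_align(counts: Mapping[str, int], consensus: str) -> Counter:
    """Re-key variants to the rotation that best matches ``consensus``.

    Canonical rotation is a stable identity key but not a stable alignment
    frame: a substitution can move the lexicographically minimal rotation,
    so two nearly identical variants may canonicalize into different
    frames.  Columnwise comparisons (Hamming, K2P, logos) therefore first
    rotate every variant onto the consensus frame (maximum ungapped
    identity over rotations; ties take the smallest rotation offset).
    Counts of variants that collide after re-phasing are summed.
    """
    ref = _encode(consensus)
    out: Counter = Counter()
    for seq, count in counts.items():
        if len(seq) != len(consensus):
            raise ValueError("variant/consensus length mismatch")
        rots = np.stack([_encode(seq[i:] + seq[:i]) for i in range(len(seq))])
        best = int(np.argmax((rots == ref).sum(axis=1)))
        out[seq[best:] + seq[:best]] += count
    return out


def tally_and_filter(
    monomers: Iterable[str],
    drop_singletons: bool = True,
) -> Counter:
    """Canonicalize and tally monomers; optionally drop count-1 variants."""
    counts = Counter(canonical_rotation(m) for m in monomers)
    if drop_singletons:
        counts = Counter({s: c for s, c in counts.items() if c > 1})
    return counts


@dataclass
class Composition:
    """Columnwise base-frequency matrix and consensus of a variant pool."""

    matrix: np.ndarray  # (4, L) counts, rows in ACGT order, count-weighted
    consensus: str
    at_fraction: float
    ambiguous_positions: list[int]  # 0-based columns where the majority tied


def consensus_and_composition(counts: Mapping[str, int]) -> Composition:
    """Count-weighted position frequency matrix, majority consensus, A+T.

    Ties in a column fall to the alphabetically first base and the column is
    flagged in ``ambiguous_positions``.  A+T is the fraction of A/T bases in
    the consensus.
    """
    if not counts:
        raise ValueError("empty variant pool")
    lengths = {len(s) for s in counts}
    if len(lengths) != 1:
        raise ValueError(f"mixed monomer lengths: {sorted(lengths)}")
    L = lengths.pop()
    matrix = np.zeros((4, L), dtype=np.int64)
    base_index = {b: i for i, b in enumerate(_BASES)}
    for seq, count in counts.items():
        for pos, base in enumerate(seq):
            matrix[base_index[base], pos] += count
    winners = matrix.argmax(axis=0)
    ambiguous = [
        int(p)
        for p in range(L)
        if (matrix[:, p] == matrix[winners[p], p]).sum() > 1
    ]
    consensus = "".join(_BASES[w] for w in winners)
    at = (consensus.count("A") + consensus.count("T")) / L
    return Composition(matrix, consensus, at, ambiguous)


def subsample_by_genome_size(
    n_reference_pairs: int,
    reference_genome_size: float,
    target_genome_size: float,
) -> int:
    """Read pairs to sample so per-base sampling matches the reference library."""
    if n_reference_pairs <= 0 or reference_genome_size <= 0 or target_genome_size <= 0:
        raise ValueError("all sizes must be positive")
    return int(round(n_reference_pairs * target_genome_size / reference_genome_size))
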