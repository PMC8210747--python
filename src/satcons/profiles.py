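"""Copy-number and variant profiling over a concatemer consensus reference.

Reads are mapped ungapped against a small reference panel: the satellite
consensus repeated k times (so reads spanning a monomer junction map
contiguously) plus single-copy normalization genes.  Mapping is k-mer seeded
and assigns each read to its single best-identity location.  Two modes:

* ``global`` - the whole read must lie inside a reference and identity is
  matches/read-length (the default contract);
* ``local`` - the best-scoring ungapped segment on the seeded diagonal is
  used (Kadane's maximal segment, match +1 / mismatch -3), so reads
  straddling an array boundary or an internal deletion contribute partial
  coverage.  The profiling pipeline uses this mode; copy number estimated
  from aligned bases per monomer is then unbiased even for short arrays.

Copy number = per-monomer satellite depth over the median single-copy gene
depth (median resists a mis-annotated gene).  The variant profile is the
per-position non-reference base fraction; uncovered positions are missing,
not zero.  Valley detection folds the concatemer depth into monomer
coordinates and reports runs of positions below a fraction of the median
folded depth - the signature of a deletion segregating among copies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .seqio import SequenceRecord, reverse_complement
from .monomers import MONOMER_LENGTH

__all__ = [
    "build_concatemer",
    "ReferencePanel",
    "RefProfile",
    "MappingResult",
    "map_reads",
    "copy_number",
    "estimate_copy_number",
    "variant_fraction",
    "profile_correlation",
    "find_valleys",
    "NormalizationError",
    "UndefinedCorrelationError",
]

_BASES = "ACGT"


class NormalizationError(ValueError):
    pass


class UndefinedCorrelationError(ValueError):
    pass


def build_concatemer(consensus: str, k: int = 4) -> str:
    """Consensus repeated k times (k >= 2 so junction reads map contiguously)."""
    if len(consensus) != MONOMER_LENGTH:
        raise ValueError(f"consensus length {len(consensus)} != {MONOMER_LENGTH}")
    if k < 2:
        raise ValueError("concatemer requires k >= 2")
    return consensus * k


def _encode(seq: str) -> np.ndarray:
    lut = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate(b"ACGTN"):
        lut[b] = i if i < 4 else 254  # N matches nothing
    return lut[np.frombuffer(seq.encode(), dtype=np.uint8)]


@dataclass
class RefProfile:
    """Per-position depth and base counts accumulated on one reference."""

    ref_id: str
    length: int
    depth: np.ndarray  # int64 (L,)
    base_counts: np.ndarray  # int64 (4, L), ACGT rows
    n_reads: int = 0

    @property
    def aligned_bases(self) -> int:
        return int(self.depth.sum())

    @property
    def mean_depth(self) -> float:
        return self.aligned_bases / self.length

    @property
    def covered_fraction(self) -> float:
        return float((self.depth > 0).mean())

    @property
    def scaled(self) -> np.ndarray:
        """depth / max(depth), in [0, 1]; zeros if nothing mapped."""
        top = self.depth.max()
        return self.depth / top if top > 0 else self.depth.astype(float)


@dataclass
class MappingResult:
    profiles: dict[str, RefProfile]
    n_assigned: int = 0
    n_unassigned: int = 0

    def counts(self) -> dict[str, int]:
        return {rid: p.n_reads for rid, p in self.profiles.items()}


class ReferencePanel:
    """Encoded references plus a k-mer seed index for diagonal finding."""

    def __init__(self, references: Sequence[tuple[str, str]], seed_k: int = 12):
        ids = [rid for rid, _ in references]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate reference ids")
        self.ids = ids
        self.seqs = [seq for _, seq in references]
        self.arrays = [_encode(seq) for seq in self.seqs]
        self.seed_k = seed_k
        self.index: dict[str, list[tuple[int, int]]] = {}
        for ri, seq in enumerate(self.seqs):
            for pos in range(len(seq) - seed_k + 1):
                self.index.setdefault(seq[pos : pos + seed_k], []).append((ri, pos))


def _best_segment(eq: np.ndarray, mismatch_penalty: int) -> tuple[int, int, int]:
    """Maximal-scoring contiguous segment of match(+1)/mismatch(-penalty).

    Returns (start, end, matches) of the best segment (end exclusive).
    """
    score = np.where(eq, 1, -mismatch_penalty)
    prefix = np.concatenate(([0], np.cumsum(score)))
    running_min = np.minimum.accumulate(prefix[:-1])
    gains = prefix[1:] - running_min
    end = int(np.argmax(gains)) + 1
    start = int(np.argmax(prefix[:end] == running_min[end - 1]))
    matches = int(eq[start:end].sum())
    return start, end, matches


def map_reads(
    reads: Iterable[Union[str, SequenceRecord]],
    references: Sequence[tuple[str, str]],
    min_identity: float = 0.9,
    mode: str = "global",
    seed_k: int = 12,
    seed_step: int = 4,
    min_span: int = 30,
    local_mismatch: int = 3,
    max_segments: int = 1,
    panel: Optional[ReferencePanel] = None,
) -> MappingResult:
    """Assign each read to its best-identity ungapped location.

    Candidate diagonals come from exact k-mer seeds sampled every
    ``seed_step`` bases along the read, both strands.  Ties go to the
    reference listed first, then the leftmost position, then the forward
    strand.  Reads whose best identity is below ``min_identity`` stay
    unassigned.  Depth and per-base counts accumulate over the aligned span
    only.

    In local mode ``max_segments`` > 1 lets one read contribute further
    qualifying segments that are disjoint from the first in read
    coordinates (split mapping).  A read crossing an indel inside a repeat
    continues on a shifted diagonal, so without this an ungapped mapper
    silently drops the far side of every such junction and deflates depth
    around segregating indels.
    """
    if mode not in ("global", "local"):
        raise ValueError(f"unknown mode {mode!r}")
    if panel is None:
        panel = ReferencePanel(references, seed_k)
    profiles = {
        rid: RefProfile(
            rid,
            len(seq),
            np.zeros(len(seq), dtype=np.int64),
            np.zeros((4, len(seq)), dtype=np.int64),
        )
        for rid, seq in zip(panel.ids, panel.seqs)
    }
    n_assigned = n_unassigned = 0
    k = panel.seed_k
    for read in reads:
        seq = read.sequence if isinstance(read, SequenceRecord) else read
        R = len(seq)
        if R < k:
            n_unassigned += 1
            continue
        candidates = []  # (key, ri, ref_start, read_start, span, identity, strand_idx)
        strand_codes = []
        for strand_idx, s in enumerate((seq, reverse_complement(seq))):
            arr = _encode(s)
            strand_codes.append(arr)
            diagonals = set()
            seed_positions = list(range(0, R - k, seed_step)) + [R - k]
            for rp in seed_positions:
                for ri, pos in panel.index.get(s[rp : rp + k], ()):
                    diagonals.add((ri, pos - rp))
            for ri, off in sorted(diagonals):
                ref = panel.arrays[ri]
                L = ref.size
                if mode == "global":
                    if off < 0 or off + R > L:
                        continue
                    eq = arr == ref[off : off + R]
                    matches = int(eq.sum())
                    identity = matches / R
                    key = (-identity, ri, off, strand_idx)
                    candidates.append((key, ri, off, 0, R, identity, strand_idx))
                else:
                    lo, hi = max(off, 0), min(off + R, L)
                    if hi - lo < min_span:
                        continue
                    eq = arr[lo - off : hi - off] == ref[lo:hi]
                    seg_start, seg_end, matches = _best_segment(eq, local_mismatch)
                    span = seg_end - seg_start
                    if span < min_span:
                        continue
                    identity = matches / span
                    score = matches - local_mismatch * (span - matches)
                    key = (-score, -identity, ri, lo + seg_start, strand_idx)
                    candidates.append(
                        (key, ri, lo + seg_start, (lo - off) + seg_start, span, identity, strand_idx)
                    )
        candidates = [c for c in candidates if c[5] >= min_identity]
        if not candidates:
            n_unassigned += 1
            continue
        candidates.sort(key=lambda c: c[0])
        n_keep = 1 if mode == "global" else max_segments
        taken: list[tuple[int, int]] = []  # forward-frame read intervals
        first = True
        for key, ri, ref_start, read_start, span, identity, strand_idx in candidates:
            if len(taken) >= n_keep:
                break
            fwd = (read_start, read_start + span) if strand_idx == 0 else (
                R - read_start - span,
                R - read_start,
            )
            if any(fwd[0] < e and s0 < fwd[1] for s0, e in taken):
                continue
            taken.append(fwd)
            arr = strand_codes[strand_idx]
            prof = profiles[panel.ids[ri]]
            prof.depth[ref_start : ref_start + span] += 1
            read_codes = arr[read_start : read_start + span]
            valid = read_codes < 4
            np.add.at(
                prof.base_counts,
                (read_codes[valid], np.arange(ref_start, ref_start + span)[valid]),
                1,
            )
            if first:
                prof.n_reads += 1
                first = False
        n_assigned += 1
    return MappingResult(profiles, n_assigned, n_unassigned)


def copy_number(sat_mean_depth: float, gene_mean_depths: Sequence[float]) -> float:
    """Satellite depth normalized by the median single-copy gene depth."""
    depths = [d for d in gene_mean_depths if d > 0]
    if not depths:
        raise NormalizationError("all single-copy gene depths are zero")
    return sat_mean_depth / float(np.median(np.asarray(gene_mean_depths, dtype=float)))


def estimate_copy_number(
    result: MappingResult,
    sat_id: str,
    gene_ids: Sequence[str],
    monomer_length: int = MONOMER_LENGTH,
) -> float:
    """Monomer copies per 1C from a mapping result.

    Satellite depth is expressed per monomer (aligned bases / monomer
    length); gene depth is aligned bases over gene length.  With local-mode
    mapping both are unbiased by locus edges, so the ratio recovers the
    planted copy number.
    """
    sat = result.profiles[sat_id]
    gene_depths = [result.profiles[g].mean_depth for g in gene_ids]
    if all(d == 0 for d in gene_depths):
        raise NormalizationError("all single-copy gene depths are zero")
    return copy_number(sat.aligned_bases / monomer_length, gene_depths)


def variant_fraction(profile: RefProfile, reference: str) -> np.ndarray:
    """Per-position non-reference base fraction; uncovered positions are NaN."""
    if len(reference) != profile.length:
        raise ValueError("reference length != profile length")
    ref_codes = _encode(reference)
    depth = profile.depth.astype(float)
    ref_counts = profile.base_counts[ref_codes, np.arange(profile.length)]
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = 1.0 - ref_counts / depth
    frac[depth == 0] = np.nan
    return frac


def profile_correlation(profile_a: np.ndarray, profile_b: np.ndarray) -> float:
    """Pearson correlation of two scaled coverage profiles."""
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("profiles must have equal length")
    if a.std() == 0 or b.std() == 0:
        raise UndefinedCorrelationError("correlation undefined for a constant profile")
    return float(np.corrcoef(a, b)[0, 1])


def find_valleys(
    depth: Union[np.ndarray, RefProfile],
    drop: float = 0.6,
    min_run: int = 2,
    monomer_length: int = MONOMER_LENGTH,
) -> list[tuple[int, int]]:
    """Monomer-coordinate coverage valleys (1-based inclusive intervals).

    The concatemer depth is folded to monomer coordinates by averaging the k
    images of each position; maximal runs of at least ``min_run`` positions
    whose folded depth falls below ``drop`` times the median folded depth are
    reported.  Folding makes the result invariant to the concatemer k.
    """
    d = depth.depth if isinstance(depth, RefProfile) else np.asarray(depth, dtype=float)
    if d.size % monomer_length != 0:
        raise ValueError("profile length is not a multiple of the monomer length")
    folded = d.reshape(-1, monomer_length).mean(axis=0)
    median = float(np.median(folded))
    if median <= 0:
        return []
    low = folded < drop * median
    valleys: list[tuple[int, int]] = []
    start = None
    for i, flag in enumerate(low):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start >= min_run:
                valleys.append((start + 1, i))
            start = None
    if start is not None and len(low) - start >= min_run:
        valleys.append((start + 1, len(low)))
    return valleys
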