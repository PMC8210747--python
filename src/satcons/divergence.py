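"""Kimura 2-parameter divergence, repeat landscapes and summary statistics.

K2P separates transitions (P) and transversions (Q):

    K = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

and is undefined (saturated) when either log argument is non-positive.
Landscapes bin repeat mass (aligned bases, count-weighted) by percent
divergence from the consensus; divergence summaries report abundance-weighted
mean pairwise K within species (intraspecific) and across species
(interspecific), in percent.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .monomers import VariantPool, phase_align

__all__ = [
    "DivergenceEstimate",
    "LandscapeHistogram",
    "SummaryStats",
    "DivergenceSummary",
    "SaturationError",
    "kimura2p",
    "pairwise_k2p_percent",
    "repeat_landscape",
    "divergence_summary",
    "column_summary",
]

_BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(_BASES)}


class SaturationError(ValueError):
    """The observed substitution proportions saturate the K2P correction."""


@dataclass(frozen=True)
class DivergenceEstimate:
    """Transition/transversion proportions and the K2P distance (fraction)."""

    p: float
    q: float
    k: float

    @property
    def percent(self) -> float:
        return 100.0 * self.k


def _encode_rows(seqs: Sequence[str]) -> np.ndarray:
    try:
        return np.array([[_CODE[b] for b in s] for s in seqs], dtype=np.uint8)
    except KeyError as exc:
        raise ValueError(f"non-ACGT base {exc.args[0]!r}") from None


def kimura2p(seq_a: str, seq_b: str) -> DivergenceEstimate:
    """K2P distance between two equal-length ACGT sequences (symmetric)."""
    if len(seq_a) != len(seq_b):
        raise ValueError(f"unequal lengths {len(seq_a)} != {len(seq_b)}")
    X = _encode_rows([seq_a, seq_b])
    a, b = X[0], X[1]
    diff = a != b
    # transitions stay within purines {A,G} = codes {0,2} / pyrimidines {1,3}
    ts = diff & ((a % 2) == (b % 2))
    L = len(seq_a)
    p = float(ts.sum()) / L
    q = float((diff & ~ts).sum()) / L
    return DivergenceEstimate(p, q, _k2p_from_pq(p, q))


def _k2p_from_pq(p: float, q: float) -> float:
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(f"saturated: P={p:.4f}, Q={q:.4f}")
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def pairwise_k2p_percent(
    seqs_a: Sequence[str],
    seqs_b: Optional[Sequence[str]] = None,
) -> np.ndarray:
    """Matrix of K2P distances in percent; saturated pairs are NaN.

    With one argument returns the symmetric self-matrix (zero diagonal);
    with two, the cross-matrix between the sets.  Vectorized over all pairs.
    """
    A = _encode_rows(seqs_a)
    B = A if seqs_b is None else _encode_rows(seqs_b)
    if A.shape[1] != B.shape[1]:
        raise ValueError("sequence length mismatch between sets")
    L = A.shape[1]
    diff = A[:, None, :] != B[None, :, :]
    same_class = (A[:, None, :] % 2) == (B[None, :, :] % 2)
    P = (diff & same_class).sum(axis=2) / L
    Q = (diff & ~same_class).sum(axis=2) / L
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    with np.errstate(invalid="ignore", divide="ignore"):
        K = np.where(
            (w1 > 0) & (w2 > 0),
            -0.5 * np.log(np.where(w1 > 0, w1, 1.0))
            - 0.25 * np.log(np.where(w2 > 0, w2, 1.0)),
            np.nan,
        )
    return 100.0 * K


@dataclass
class LandscapeHistogram:
    """Divergence-binned repeat mass: 1%-wide bins of aligned monomer bases."""

    bin_bases: dict[int, int]  # floor(K%) -> summed bases
    saturated_bases: int = 0

    @property
    def total_bases(self) -> int:
        return sum(self.bin_bases.values()) + self.saturated_bases

    def proportions(self) -> dict[int, float]:
        total = self.total_bases
        return {b: m / total for b, m in sorted(self.bin_bases.items())}


def repeat_landscape(counts: Mapping[str, int], consensus: str) -> LandscapeHistogram:
    """Bin each variant's mass (length x count bases) by K2P% to consensus.

    Variants are first rotated onto the consensus frame so that the
    distance is columnwise-aligned regardless of the tally's rotation
    convention.
    """
    if not counts:
        return LandscapeHistogram({})
    counts = phase_align(counts, consensus)
    seqs = list(counts)
    K = pairwise_k2p_percent(seqs, [consensus])[:, 0]
    bins: dict[int, int] = {}
    saturated = 0
    for seq, k in zip(seqs, K):
        mass = len(seq) * counts[seq]
        if np.isnan(k):
            saturated += mass
        else:
            b = int(math.floor(k))
            bins[b] = bins.get(b, 0) + mass
    return LandscapeHistogram(bins, saturated)


@dataclass
class DivergenceSummary:
    """Copy-weighted mean pairwise K2P (%) within and between species."""

    intraspecific: dict[str, float]
    interspecific: float
    skipped_saturated_pairs: int = 0


def _weighted_mean_k(K: np.ndarray, W: np.ndarray) -> tuple[float, float, int]:
    """Sum of w*K and of w over finite entries, plus saturated count."""
    finite = ~np.isnan(K)
    skipped = int(((~finite) & (W > 0)).sum())
    w = W * finite
    return float(np.nansum(w * np.nan_to_num(K))), float(w.sum()), skipped


def divergence_summary(
    pools: VariantPool, consensus: Optional[str] = None
) -> DivergenceSummary:
    """Table-style divergence summary from per-species variant pools.

    Intraspecific: abundance-weighted (count_i x count_j, i<j over distinct
    variants) mean pairwise K within each species; a single-variant species
    scores 0.  Interspecific: abundance-weighted mean pairwise K over variant
    pairs drawn from different species.  Saturated pairs are skipped and
    counted.  When ``consensus`` is given every pool is first rotated onto
    its frame, so canonically keyed pools compare columnwise-aligned.
    """
    intra: dict[str, float] = {}
    skipped = 0
    species = pools.species()
    per_species: dict[str, tuple[list[str], np.ndarray]] = {}
    for sp in species:
        counts = pools.counts(sp)
        if consensus is not None:
            counts = phase_align(counts, consensus)
        seqs = sorted(counts)
        per_species[sp] = (seqs, np.array([counts[s] for s in seqs], dtype=float))
    for sp in species:
        seqs, c = per_species[sp]
        if len(seqs) < 2:
            intra[sp] = 0.0
            continue
        K = pairwise_k2p_percent(seqs)
        W = np.triu(np.outer(c, c), k=1)
        num, den, sk = _weighted_mean_k(K, W)
        skipped += sk
        intra[sp] = num / den if den > 0 else 0.0
    if len(species) < 2:
        raise ValueError("interspecific divergence needs >= 2 species")
    num = den = 0.0
    for i, sp_a in enumerate(species):
        seqs_a, ca = per_species[sp_a]
        for sp_b in species[i + 1 :]:
            seqs_b, cb = per_species[sp_b]
            K = pairwise_k2p_percent(seqs_a, seqs_b)
            n, d, sk = _weighted_mean_k(K, np.outer(ca, cb))
            num += n
            den += d
            skipped += sk
    if den == 0:
        raise SaturationError("all interspecific pairs saturated")
    return DivergenceSummary(intra, num / den, skipped)


@dataclass(frozen=True)
class SummaryStats:
    """n, mean, sample SD (n-1 denominator) and CV = 100*SD/mean."""

    n: int
    mean: float
    sd: float
    cv: float


def column_summary(values: Iterable[float]) -> SummaryStats:
    x = np.asarray(list(values), dtype=float)
    if x.size < 2:
        raise ValueError("need n >= 2 for a sample SD")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    cv = 100.0 * sd / mean if mean != 0 else float("nan")
    return SummaryStats(int(x.size), mean, sd, cv)
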