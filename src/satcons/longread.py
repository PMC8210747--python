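"""Tandem-array detection in noisy long reads, densities and flanker clusters.

Arrays are found by local alignment of the read against the infinite cyclic
concatenation of the monomer (wraparound dynamic programming).  An
alignment's noise is its edit operations divided by its alignment columns;
alignments above the ``max_noise`` ceiling must not survive, so the penalty
is derived from the ceiling: with match +1, mismatch/indel cost
-(1 - tau')/tau' where tau' = 1.25 x ``max_noise`` (-3 at a 0.20 ceiling).
Scoring against the slightly slackened ratio tau' keeps terminal error
bursts from clipping array ends, regions noisier than tau' are
score-negative so Smith-Waterman locality splits alignments there, and the
final filter enforces ``max_noise`` exactly.  Unit costs would not work: on
random DNA they sit in the score-positive Chvatal-Sankoff regime and
alignments swallow the background between arrays.  Candidate alignments
whose span falls short of ``min_span`` are discarded and overlapping
survivors are resolved greedily by score, then length, then leftmost
start.  Both strands are scanned.

Repeat density is kilobases annotated per megabase sequenced (kb/Mb) after
merging overlapping intervals.  Flanking windows adjacent to detected arrays
are clustered greedily longest-first at an identity threshold (edlib edit
distance), CD-HIT style, to expose sequences recurrently associated with the
satellite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import edlib
import numpy as np

from .seqio import IntervalRecord, SequenceRecord, reverse_complement
from .monomers import MONOMER_LENGTH

__all__ = [
    "RepeatArrayInterval",
    "DensityReport",
    "FlankerCluster",
    "detect_arrays",
    "repeat_density",
    "extract_flankers",
    "cluster_flankers",
]

try:  # numba accelerates the DP ~100x; the numpy scan is the exact fallback
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

# Horizontal (read-gap) relaxation in the numpy scan uses doubling shifts
# 1..32, exact for any gap run on a monomer of up to 64 columns.
_MAX_GAP_DOUBLINGS = 6


@dataclass(frozen=True)
class RepeatArrayInterval:
    """A detected tandem array in read coordinates (0-based half-open)."""

    read_id: str
    start: int
    end: int
    strand: str
    noise: float  # edit operations / alignment columns
    monomer_equivalents: float  # read span / monomer length
    score: int

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class DensityReport:
    kb_annotated: float
    mb_sequenced: float

    @property
    def density(self) -> float:
        """kb annotated per Mb sequenced."""
        return self.kb_annotated / self.mb_sequenced


@dataclass
class FlankerCluster:
    representative: str  # longest member
    members: list[str]

    @property
    def size(self) -> int:
        return len(self.members)


def _encode(seq: str) -> np.ndarray:
    lut = np.full(256, 254, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    return lut[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _wraparound_scan_numpy(
    read_codes: np.ndarray,
    monomer_codes: np.ndarray,
    match: int,
    mismatch: int,
    gap: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-best score, alignment start row and column count of the local
    wraparound DP of the read (rows) against the cyclic monomer (columns).

    Returns arrays of length len(read): for each read prefix end i (1-based
    row, stored at i-1), the best local alignment ending there, its start
    position in the read, and its number of alignment columns.
    """
    m = monomer_codes.size
    L = read_codes.size
    # per-base substitution score rows, precomputed: (4, m)
    sub_lut = np.where(monomer_codes[None, :] == np.arange(4)[:, None], match, mismatch)
    sub_other = np.full(m, mismatch)  # non-ACGT read base mismatches everything
    H = np.zeros(m, dtype=np.int32)
    C = np.zeros(m, dtype=np.int32)
    S = np.zeros(m, dtype=np.int32)
    out_score = np.empty(L, dtype=np.int32)
    out_start = np.empty(L, dtype=np.int32)
    out_cols = np.empty(L, dtype=np.int32)
    for i in range(1, L + 1):
        x = read_codes[i - 1]
        sub = sub_lut[x] if x < 4 else sub_other
        diag = np.roll(H, 1) + sub
        diag_c = np.roll(C, 1) + 1
        diag_s = np.roll(S, 1)
        vert = H + gap
        take_vert = vert > diag
        Hn = np.where(take_vert, vert, diag)
        Cn = np.where(take_vert, C + 1, diag_c)
        Sn = np.where(take_vert, S, diag_s)
        reset = Hn <= 0
        Hn = np.where(reset, 0, Hn)
        Cn = np.where(reset, 0, Cn)
        Sn = np.where(reset, i, Sn)
        shift = 1
        for _ in range(_MAX_GAP_DOUBLINGS):
            cand = np.roll(Hn, shift) + gap * shift
            better = cand > Hn
            if better.any():
                Cn = np.where(better, np.roll(Cn, shift) + shift, Cn)
                Sn = np.where(better, np.roll(Sn, shift), Sn)
                Hn = np.where(better, cand, Hn)
            shift *= 2
        H, C, S = Hn, Cn, Sn
        j = int(np.argmax(H))
        out_score[i - 1] = H[j]
        out_cols[i - 1] = C[j]
        out_start[i - 1] = S[j]
    return out_score, out_start, out_cols


def _wraparound_kernel(read, mono, match, mismatch, gap):
    """Loop form of the scan (numba-compiled when available)."""
    m = mono.size
    L = read.size
    H = np.zeros(m, dtype=np.int32)
    C = np.zeros(m, dtype=np.int32)
    S = np.zeros(m, dtype=np.int32)
    Hp = np.zeros(m, dtype=np.int32)
    Cp = np.zeros(m, dtype=np.int32)
    Sp = np.zeros(m, dtype=np.int32)
    out_score = np.empty(L, dtype=np.int32)
    out_start = np.empty(L, dtype=np.int32)
    out_cols = np.empty(L, dtype=np.int32)
    for i in range(1, L + 1):
        x = read[i - 1]
        Hp, H = H, Hp
        Cp, C = C, Cp
        Sp, S = S, Sp
        for j in range(m):
            jp = j - 1 if j > 0 else m - 1
            s = match if mono[j] == x else mismatch
            h = Hp[jp] + s
            c = Cp[jp] + 1
            st = Sp[jp]
            hv = Hp[j] + gap
            if hv > h:
                h, c, st = hv, Cp[j] + 1, Sp[j]
            if h <= 0:
                h, c, st = 0, 0, i
            H[j], C[j], S[j] = h, c, st
        # horizontal (read-gap) relaxation: two cyclic passes are exact
        for _ in range(2):
            for j in range(m):
                jp = j - 1 if j > 0 else m - 1
                cand = H[jp] + gap
                if cand > H[j]:
                    H[j] = cand
                    C[j] = C[jp] + 1
                    S[j] = S[jp]
        best = 0
        for j in range(1, m):
            if H[j] > H[best]:
                best = j
        out_score[i - 1] = H[best]
        out_cols[i - 1] = C[best]
        out_start[i - 1] = S[best]
    return out_score, out_start, out_cols


if _HAVE_NUMBA:
    _wraparound_kernel_jit = _njit(cache=True, nogil=True)(_wraparound_kernel)


def _wraparound_scan(
    read_codes: np.ndarray,
    monomer_codes: np.ndarray,
    match: int,
    mismatch: int,
    gap: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if _HAVE_NUMBA:
        return _wraparound_kernel_jit(
            read_codes.astype(np.uint8), monomer_codes.astype(np.uint8), match, mismatch, gap
        )
    return _wraparound_scan_numpy(read_codes, monomer_codes, match, mismatch, gap)


def detect_arrays(
    read: Union[str, SequenceRecord],
    monomer: str,
    max_noise: float = 0.20,
    min_span: int = MONOMER_LENGTH,
    match: int = 1,
    mismatch: Optional[int] = None,
    gap: Optional[int] = None,
    read_id: Optional[str] = None,
) -> list[RepeatArrayInterval]:
    """Detect noise-bounded tandem arrays of ``monomer`` in one long read.

    ``mismatch``/``gap`` default to the penalty implied by ``max_noise``
    (see module docstring) and must be equal when given explicitly (edit
    operations are then recoverable from score and column count alone).
    """
    if not 0 < max_noise < 0.5:
        raise ValueError("max_noise must be in (0, 0.5)")
    if mismatch is None and gap is None:
        slack = min(1.25 * max_noise, 0.45)
        mismatch = gap = -max(2, int(np.ceil(match * (1.0 - slack) / slack)))
    if mismatch != gap:
        raise ValueError("mismatch and gap penalties must be equal")
    if isinstance(read, SequenceRecord):
        seq, rid = read.sequence, read.id
    else:
        seq, rid = read, read_id or "read"
    if not seq:
        raise ValueError("empty read")
    if len(monomer) != MONOMER_LENGTH:
        raise ValueError(f"monomer length {len(monomer)} != {MONOMER_LENGTH}")
    if len(seq) < min_span:
        return []
    read_codes = _encode(seq)
    # score floor implied by the noise ceiling at the minimum span
    per_edit = match - mismatch  # score lost per edit relative to a match
    min_score = max(1, int(np.ceil(min_span * (match - per_edit * max_noise))))
    candidates = []
    for strand, mono in (("+", monomer), ("-", reverse_complement(monomer))):
        scores, starts, cols = _wraparound_scan(read_codes, _encode(mono), match, mismatch, gap)
        keep = np.flatnonzero(scores >= min_score)
        for i in keep:
            end = int(i) + 1
            start = int(starts[i])
            candidates.append((int(scores[i]), end - start, start, end, int(cols[i]), strand))
    # greedy non-overlap resolution: score desc, span desc, leftmost, strand
    candidates.sort(key=lambda c: (-c[0], -c[1], c[2], c[5]))
    accepted: list[RepeatArrayInterval] = []
    for score, span, start, end, ncols, strand in candidates:
        if span < min_span or ncols <= 0:
            continue
        edits = (match * ncols - score) / (match - mismatch)
        noise = edits / ncols
        if noise > max_noise:
            continue
        if any(iv.start < end and start < iv.end for iv in accepted):
            continue
        accepted.append(
            RepeatArrayInterval(
                rid, start, end, strand, noise, span / MONOMER_LENGTH, score
            )
        )
    accepted.sort(key=lambda iv: iv.start)
    return accepted


def repeat_density(
    intervals: Iterable[Union[RepeatArrayInterval, IntervalRecord]],
    total_bases_sequenced: int,
) -> DensityReport:
    """kb of annotation per Mb sequenced, merging overlaps per read first."""
    if total_bases_sequenced <= 0:
        raise ValueError("total bases sequenced must be positive")
    by_read: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        rid = iv.read_id if isinstance(iv, RepeatArrayInterval) else iv.sequence_id
        by_read.setdefault(rid, []).append((iv.start, iv.end))
    annotated = 0
    for spans in by_read.values():
        spans.sort()
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                annotated += cur_e - cur_s
                cur_s, cur_e = s, e
        annotated += cur_e - cur_s
    return DensityReport(annotated / 1000.0, total_bases_sequenced / 1e6)


def extract_flankers(
    read: Union[str, SequenceRecord],
    interval: tuple[int, int],
    window: int = 10_000,
) -> tuple[str, str]:
    """10-kb (default) regions upstream/downstream of an array locus.

    Flankers are truncated at read ends; an array touching a read edge gets
    an empty flanker on that side.
    """
    seq = read.sequence if isinstance(read, SequenceRecord) else read
    start, end = interval
    if not (0 <= start < end <= len(seq)):
        raise ValueError(f"interval [{start}, {end}) outside read of length {len(seq)}")
    return seq[max(0, start - window) : start], seq[end : min(len(seq), end + window)]


def _flanker_matches(shorter: str, longer: str, identity: float) -> bool:
    """True if ``shorter`` aligns to ``longer`` at >= identity over at least
    half of itself (edlib infix alignment)."""
    def _hit(query: str) -> bool:
        if not query:
            return False
        res = edlib.align(query, longer, mode="HW", task="distance")
        return 1.0 - res["editDistance"] / len(query) >= identity

    if _hit(shorter):
        return True
    half = len(shorter) // 2
    return half > 0 and (_hit(shorter[:half]) or _hit(shorter[half:]))


def cluster_flankers(
    sequences: Sequence[str],
    min_size: int = 3,
    identity: float = 0.8,
    keep_small: bool = False,
) -> list[FlankerCluster]:
    """Greedy longest-first incremental clustering at an identity threshold.

    Each sequence joins the first existing cluster whose representative it
    matches (identity over at least half the shorter sequence), otherwise it
    founds a new cluster.  Clusters below ``min_size`` are dropped from the
    report unless ``keep_small``.
    """
    if not sequences:
        raise ValueError("no sequences to cluster")
    order = sorted(range(len(sequences)), key=lambda i: (-len(sequences[i]), i))
    clusters: list[FlankerCluster] = []
    for idx in order:
        seq = sequences[idx]
        if not seq:
            continue
        for cluster in clusters:
            rep = cluster.representative
            shorter, longer = (seq, rep) if len(seq) <= len(rep) else (rep, seq)
            if _flanker_matches(shorter, longer, identity):
                cluster.members.append(seq)
                break
        else:
            clusters.append(FlankerCluster(seq, [seq]))
    if keep_small:
        return clusters
    return [c for c in clusters if c.size >= min_size]
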