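"""Transcription quantification: FPKM, Welch's t, and qPCR relative quantities.

FPKM = count / (length/1000 * total/1e6), with fragments counted as read
pairs for paired input and as reads for single-end input.  Group comparisons
use Welch's unequal-variance t with Welch-Satterthwaite degrees of freedom.
qPCR relative quantification follows the Livak method: replicate Ct values
are averaged arithmetically, dCt = Ct_target - Ct_reference, RQ = 2^-dCt,
and, against a calibrator sample, ddCt and fold = 2^-ddCt.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "fpkm",
    "fold_difference",
    "welch_t",
    "qpcr_relative",
    "fpkm_table",
    "WelchResult",
]


def fpkm(count: float, length_bp: float, total_fragments: float) -> float:
    """Fragments per kilobase of transcript per million mapped fragments."""
    if length_bp <= 0 or total_fragments <= 0:
        raise ValueError("target length and library total must be positive")
    return count / ((length_bp / 1000.0) * (total_fragments / 1e6))


def fold_difference(group_a: Iterable[float], group_b: Iterable[float]) -> float:
    """Ratio of group means, a over b."""
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if b.size == 0 or b.mean() <= 0:
        raise ValueError("denominator group mean must be positive")
    return float(a.mean() / b.mean())


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float


def welch_t(xs: Iterable[float], ys: Iterable[float]) -> WelchResult:
    """Welch's unequal-variance two-sample t test (two-sided).

    t = (mean_x - mean_y) / sqrt(s1^2/n1 + s2^2/n2), df by the
    Welch-Satterthwaite approximation.
    """
    x = np.asarray(list(xs), dtype=float)
    y = np.asarray(list(ys), dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    if v1 == 0 and v2 == 0:
        raise ValueError("both groups have zero variance")
    se1, se2 = v1 / n1, v2 / n2
    t = (x.mean() - y.mean()) / np.sqrt(se1 + se2)
    df = (se1 + se2) ** 2 / (se1**2 / (n1 - 1) + se2**2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return WelchResult(float(t), float(df), float(p))


def qpcr_relative(
    ct_table: pd.DataFrame,
    target: str,
    reference: str,
    calibrator: Optional[str] = None,
) -> pd.DataFrame:
    """Livak relative quantification from a long-form Ct table.

    ``ct_table`` needs columns ``sample``, ``target``, ``ct`` (a ``replicate``
    column is allowed and averaged out).  Returns one row per sample with
    ``delta_ct`` and ``rq``; with a calibrator sample also ``ddelta_ct`` and
    ``fold``.
    """
    required = {"sample", "target", "ct"}
    missing = required - set(ct_table.columns)
    if missing:
        raise ValueError(f"ct table missing columns {sorted(missing)}")
    means = ct_table.groupby(["sample", "target"])["ct"].mean().unstack()
    for name in (target, reference):
        if name not in means.columns:
            raise ValueError(f"no Ct values for {name!r}")
    if means[reference].isna().any():
        bad = means.index[means[reference].isna()].tolist()
        raise ValueError(f"missing reference Ct for samples {bad}")
    if means[target].isna().any():
        bad = means.index[means[target].isna()].tolist()
        raise ValueError(f"missing target Ct for samples {bad}")
    out = pd.DataFrame(index=means.index)
    out["delta_ct"] = means[target] - means[reference]
    out["rq"] = 2.0 ** (-out["delta_ct"])
    if calibrator is not None:
        if calibrator not in means.index:
            raise ValueError(f"calibrator sample {calibrator!r} not in table")
        out["ddelta_ct"] = out["delta_ct"] - out.loc[calibrator, "delta_ct"]
        out["fold"] = 2.0 ** (-out["ddelta_ct"])
    return out.reset_index()


def fpkm_table(
    counts: Mapping[str, float],
    lengths: Mapping[str, float],
    library_id: str = "library",
) -> pd.DataFrame:
    """Per-target FPKM table; the library total is the sum of mapped counts."""
    total = float(sum(counts.values()))
    rows = []
    for tid in counts:
        rows.append(
            {
                "target": tid,
                "library": library_id,
                "count": counts[tid],
                "length_bp": lengths[tid],
                "total_mapped": total,
                "fpkm": fpkm(counts[tid], lengths[tid], total) if total > 0 else 0.0,
            }
        )
    return pd.DataFrame(rows)
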