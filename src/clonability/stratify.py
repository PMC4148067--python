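"""Chromosomal-quartile and clone-length stratification.

Repeat elements are unevenly distributed along chromosomes: in
C. elegans the autosome arms are repeat-rich and the centers repeat-poor.
To control for clone location, each chromosome is partitioned into four
equal-size quarters; the two extreme quarters (arms) are summarized
together and the two middle ones together.  A second stratification
splits each clone type at its median length.  Group comparisons use
Welch's unequal-variance t-test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .annotation_io import CloneRecord
from .intervals import ChromSizes

EXTREME = "extreme"
MIDDLE = "middle"


def locate_quartile(clone: CloneRecord, sizes: ChromSizes) -> str:
    """'extreme' (quarters 1 and 4) or 'middle' (2 and 3) by clone midpoint.

    The midpoint's relative position p = (start+end)/2 ÷ chromosome length
    maps to extreme when p < 0.25 or p ≥ 0.75; boundaries are half-open,
    so a midpoint exactly at 0.25 is middle and one at 0.75 extreme.
    """
    iv = clone.interval
    if iv.chrom not in sizes:
        raise KeyError(f"clone {clone.clone_id}: unknown chromosome {iv.chrom!r}")
    length = sizes[iv.chrom]
    if iv.end > length:
        raise ValueError(
            f"clone {clone.clone_id} extends past {iv.chrom} end ({iv.end} > {length})"
        )
    p = (iv.start + iv.end) / 2 / length
    return EXTREME if (p < 0.25 or p >= 0.75) else MIDDLE


def split_by_quartile(
    clones: Sequence[CloneRecord], sizes: ChromSizes
) -> Tuple[List[CloneRecord], List[CloneRecord]]:
    """(extreme, middle) partition; every clone lands in exactly one."""
    extreme = [c for c in clones if locate_quartile(c, sizes) == EXTREME]
    middle = [c for c in clones if locate_quartile(c, sizes) == MIDDLE]
    return extreme, middle


@dataclass
class LocationHistogram:
    """Fraction of items starting at each percent point of their chromosome.

    ``fractions[i]`` is the fraction of items starting in percent bin
    ``[i, i+1)``, averaged over chromosomes; ``cumulative[i]`` is the
    fraction starting at that point or further (monotone non-increasing).
    """

    fractions: np.ndarray  # shape (100,)
    cumulative: np.ndarray  # shape (100,)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "percent_bin": np.arange(100),
                "fraction": self.fractions,
                "cumulative_at_or_after": self.cumulative,
            }
        )


def location_histogram(
    clones: Sequence[CloneRecord],
    sizes: ChromSizes,
    weight: str = "equal",
) -> LocationHistogram:
    """Histogram of relative start positions in 100 percent bins.

    Per-chromosome histograms are normalized then averaged — with equal
    chromosome weight by default, or weighted by chromosome length with
    ``weight='length'``.
    """
    if not clones:
        raise ValueError("need at least one clone")
    if weight not in ("equal", "length"):
        raise ValueError(f"bad weight {weight!r}")
    per_chrom: Dict[str, np.ndarray] = {}
    for c in clones:
        chrom = c.interval.chrom
        if chrom not in sizes:
            raise KeyError(f"unknown chromosome {chrom!r}")
        bins = per_chrom.setdefault(chrom, np.zeros(100))
        b = int(100 * c.interval.start / sizes[chrom])
        bins[min(b, 99)] += 1
    stacked = []
    weights = []
    for chrom, bins in sorted(per_chrom.items()):
        stacked.append(bins / bins.sum())
        weights.append(1.0 if weight == "equal" else sizes[chrom])
    w = np.array(weights) / np.sum(weights)
    fractions = np.tensordot(w, np.vstack(stacked), axes=1)
    cumulative = fractions[::-1].cumsum()[::-1]
    return LocationHistogram(fractions=fractions, cumulative=cumulative)


def split_by_median_length(
    clones: Sequence[CloneRecord],
) -> Tuple[List[CloneRecord], List[CloneRecord]]:
    """(below median, at-or-above median) by clone length.

    The median is the lower of the two middle order statistics for even n;
    'below' is strictly less than the median.
    """
    if len(clones) < 2:
        raise ValueError("need at least two clones to split at the median")
    lengths = sorted(c.length for c in clones)
    median = lengths[(len(lengths) - 1) // 2]
    below = [c for c in clones if c.length < median]
    above = [c for c in clones if c.length >= median]
    return below, above


def welch_t(group_a: Sequence[float], group_b: Sequence[float]) -> Tuple[float, float]:
    """Welch's unequal-variance t-test, two-sided.

    Returns (t, p) with Welch–Satterthwaite degrees of freedom.  When both
    groups have zero variance: p = 1 if the means are equal, else p = 0
    (complete separation).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("groups must contain finite values only")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    if se2 == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float("inf") if a.mean() > b.mean() else float("-inf"), 0.0
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * _sps.t.sf(abs(t), df)
    return float(t), float(p)
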