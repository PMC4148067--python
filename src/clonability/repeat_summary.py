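"""Per-clone and per-library repeat-content profiling.

Mirrors the summary RepeatMasker prints per masked sequence: for each
clone, element counts and base-pair coverage per top-level repeat
category, plus the overall "bases masked" (union across every category)
and "total interspersed repeats" (union over retroelements, DNA
transposons, rolling-circles and unclassified interspersed repeats —
i.e. excluding small RNA, satellites, simple repeats and low-complexity).

Counts follow annotation rows — two overlapping same-category elements
count as two — while bp coverage always uses per-base unions, matching
RepeatMasker's own table semantics.  Elements spanning a clone boundary
are counted once with their span clipped to the clone, as RepeatMasker run
on the clone's sequence alone would see only the clipped part.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .annotation_io import CloneRecord, RepeatAnnotation

logger = logging.getLogger(__name__)

#: top-level categories, in report order
CATEGORIES = (
    "Retroelements",
    "DNA_transposons",
    "Rolling_circles",
    "Unclassified",
    "Small_RNA",
    "Satellites",
    "Simple_repeats",
    "Low_complexity",
)

#: categories whose union forms "total interspersed repeats"
INTERSPERSED = ("Retroelements", "DNA_transposons", "Rolling_circles", "Unclassified")

_SMALL_RNA_CLASSES = {"snrna", "trna", "rrna", "scrna", "srprna", "small_rna"}


@dataclass(frozen=True)
class RepeatCategory:
    label: str
    subclass: Optional[str] = None

    def __post_init__(self):
        if self.label not in CATEGORIES:
            raise ValueError(f"unknown repeat category {self.label!r}")


def classify_repeat(annotation: RepeatAnnotation) -> RepeatCategory:
    """Map a RepeatMasker class/family string to a top-level category.

    Unknown class strings fall back to ``Unclassified`` with a warning —
    elements are never dropped.
    """
    cls = annotation.repeat_class
    head, _, tail = cls.partition("/")
    sub = tail or None
    h = head.strip()
    hl = h.lower()
    if hl in ("line", "sine", "ltr", "retroposon"):
        return RepeatCategory("Retroelements", sub)
    if hl == "dna":
        return RepeatCategory("DNA_transposons", sub)
    if hl == "rc":
        return RepeatCategory("Rolling_circles", sub)
    if hl in ("unknown", "unspecified"):
        return RepeatCategory("Unclassified", sub)
    if hl in _SMALL_RNA_CLASSES:
        return RepeatCategory("Small_RNA", sub)
    if hl == "satellite":
        return RepeatCategory("Satellites", sub)
    if hl == "simple_repeat":
        return RepeatCategory("Simple_repeats", sub)
    if hl == "low_complexity":
        return RepeatCategory("Low_complexity", sub)
    logger.warning("unmapped repeat class %r → Unclassified", cls)
    return RepeatCategory("Unclassified", sub)


@dataclass
class CloneRepeatProfile:
    """Repeat content of one clone: counts, bp and percent per category."""

    clone_id: str
    length_bp: int
    count: Dict[str, int] = field(default_factory=dict)
    bp: Dict[str, int] = field(default_factory=dict)
    bases_masked_bp: int = 0
    total_interspersed_bp: int = 0

    def pct(self, category: str) -> float:
        return 100.0 * self.bp.get(category, 0) / self.length_bp

    @property
    def bases_masked_pct(self) -> float:
        return 100.0 * self.bases_masked_bp / self.length_bp

    @property
    def total_interspersed_pct(self) -> float:
        return 100.0 * self.total_interspersed_bp / self.length_bp


class RepeatIndex:
    """Per-chromosome sorted repeat annotations for fast clone queries."""

    def __init__(self, annotations: Iterable[RepeatAnnotation]):
        by_chrom: Dict[str, list] = {}
        for a in annotations:
            by_chrom.setdefault(a.interval.chrom, []).append(a)
        self._starts: Dict[str, np.ndarray] = {}
        self._ends: Dict[str, np.ndarray] = {}
        self._cats: Dict[str, np.ndarray] = {}
        self._maxlen: Dict[str, int] = {}
        for chrom, anns in by_chrom.items():
            anns.sort(key=lambda a: (a.interval.start, a.interval.end))
            self._starts[chrom] = np.array([a.interval.start for a in anns], dtype=np.int64)
            self._ends[chrom] = np.array([a.interval.end for a in anns], dtype=np.int64)
            cats = [classify_repeat(a).label for a in anns]
            self._cats[chrom] = np.array([CATEGORIES.index(c) for c in cats], dtype=np.int8)
            self._maxlen[chrom] = int((self._ends[chrom] - self._starts[chrom]).max())

    def query(self, chrom: str, start: int, end: int) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(starts, ends, category codes) of annotations overlapping [start, end)."""
        if chrom not in self._starts:
            e = np.empty(0, dtype=np.int64)
            return e, e, np.empty(0, dtype=np.int8)
        s, ends, cats = self._starts[chrom], self._ends[chrom], self._cats[chrom]
        lo = np.searchsorted(s, start - self._maxlen[chrom], side="left")
        hi = np.searchsorted(s, end, side="left")
        sel = slice(lo, hi)
        mask = ends[sel] > start
        return s[sel][mask], ends[sel][mask], cats[sel][mask]


def _union_bp(starts: np.ndarray, ends: np.ndarray) -> int:
    if len(starts) == 0:
        return 0
    order = np.argsort(starts, kind="stable")
    s, e = starts[order], ends[order]
    run_end = np.maximum.accumulate(e)
    new_run = np.empty(len(s), dtype=bool)
    new_run[0] = True
    new_run[1:] = s[1:] > run_end[:-1]
    idx = np.flatnonzero(new_run)
    return int((np.maximum.reduceat(e, idx) - s[idx]).sum())


def profile_clone(clone: CloneRecord, index: RepeatIndex) -> CloneRepeatProfile:
    """Repeat profile of one clone against an annotation index.

    Element spans are clipped to the clone; a category's bp is the union of
    its clipped spans, "bases masked" the union across all categories.
    """
    iv = clone.interval
    starts, ends, cats = index.query(iv.chrom, iv.start, iv.end)
    starts = np.maximum(starts, iv.start)
    ends = np.minimum(ends, iv.end)
    profile = CloneRepeatProfile(clone.clone_id, iv.length)
    for ci, cat in enumerate(CATEGORIES):
        m = cats == ci
        profile.count[cat] = int(m.sum())
        profile.bp[cat] = _union_bp(starts[m], ends[m])
    profile.bases_masked_bp = _union_bp(starts, ends)
    inter = np.isin(cats, [CATEGORIES.index(c) for c in INTERSPERSED])
    profile.total_interspersed_bp = _union_bp(starts[inter], ends[inter])
    return profile


def profile_library(
    clones: Sequence[CloneRecord], index: RepeatIndex, *, by_parent: bool = True
) -> List[CloneRepeatProfile]:
    """Profile every clone; trimmed pieces sharing a parent are combined.

    A YAC that was trimmed into several exclusive pieces contributes one
    profile (counts and bp summed, length = total exclusive bp), so clone
    counts and per-clone means are per parent clone, while the interval
    math stays per piece.
    """
    profiles = [profile_clone(c, index) for c in clones]
    if not by_parent:
        return profiles
    combined: Dict[str, CloneRepeatProfile] = {}
    order: List[str] = []
    for clone, prof in zip(clones, profiles):
        key = clone.parent_id or clone.clone_id
        if key not in combined:
            prof.clone_id = key
            combined[key] = prof
            order.append(key)
        else:
            acc = combined[key]
            acc.length_bp += prof.length_bp
            for cat in CATEGORIES:
                acc.count[cat] += prof.count[cat]
                acc.bp[cat] += prof.bp[cat]  # pieces are disjoint: unions add
            acc.bases_masked_bp += prof.bases_masked_bp
            acc.total_interspersed_bp += prof.total_interspersed_bp
    return [combined[k] for k in order]


@dataclass
class LibraryRepeatSummary:
    """Across-clone statistics of per-clone repeat profiles."""

    library: str
    n_clones: int
    total_coverage_bp: int
    table: pd.DataFrame  # rows: field; columns: mean, median, min, max, nonzero_mean


_STAT_NAMES = ("mean", "median", "min", "max", "nonzero_mean")


def _stats(values: np.ndarray) -> dict:
    nz = values[values > 0]
    return {
        "mean": float(values.mean()),
        "median": float(np.median(values)),
        "min": float(values.min()),
        "max": float(values.max()),
        "nonzero_mean": float(nz.mean()) if len(nz) else 0.0,
    }


def summarize_library(
    profiles: Sequence[CloneRepeatProfile], library: str = "library"
) -> LibraryRepeatSummary:
    """Aggregate per-clone profiles into library-level statistics.

    For every category the element count, bp occupied and percent of
    sequence are each summarized by mean, median, min, max and the
    non-zero mean (mean over clones with a strictly positive value).
    Total coverage is the sum of clone lengths (clone intervals within a
    library are disjoint after trimming).
    """
    if not profiles:
        raise ValueError("cannot summarize an empty library")
    rows = {}
    for cat in CATEGORIES:
        rows[f"{cat}.count"] = np.array([p.count.get(cat, 0) for p in profiles], dtype=float)
        rows[f"{cat}.bp"] = np.array([p.bp.get(cat, 0) for p in profiles], dtype=float)
        rows[f"{cat}.pct"] = np.array([p.pct(cat) for p in profiles])
    rows["Total_interspersed.bp"] = np.array([p.total_interspersed_bp for p in profiles], dtype=float)
    rows["Total_interspersed.pct"] = np.array([p.total_interspersed_pct for p in profiles])
    rows["Bases_masked.pct"] = np.array([p.bases_masked_pct for p in profiles])
    table = pd.DataFrame(
        {name: _stats(vals) for name, vals in rows.items()}
    ).T.loc[:, list(_STAT_NAMES)]
    table.index.name = "field"
    return LibraryRepeatSummary(
        library=library,
        n_clones=len(profiles),
        total_coverage_bp=int(sum(p.length_bp for p in profiles)),
        table=table,
    )


def library_mean(summary: LibraryRepeatSummary, field_name: str) -> float:
    """Convenience accessor: across-clone mean of one profile field."""
    return float(summary.table.loc[field_name, "mean"])


def summary_frame(summaries: Sequence[LibraryRepeatSummary]) -> pd.DataFrame:
    """Side-by-side report: one row per field, stat columns per library."""
    parts = []
    for s in summaries:
        t = s.table.copy()
        t.columns = [f"{s.library}.{c}" for c in t.columns]
        parts.append(t)
    out = pd.concat(parts, axis=1)
    out.insert(0, "field", out.index)
    return out.reset_index(drop=True)
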