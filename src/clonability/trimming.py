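"""Derivation of YAC-exclusive segments.

YACs were used to bridge genomic regions that resisted cloning in
bacteria; their ends often overlap finished cosmid/fosmid sequence.  To
analyse only the bacteria-unclonable territory, each YAC is trimmed by
subtracting the union of all cosmid+fosmid spans.  A YAC whose interior is
covered yields multiple exclusive pieces, all attributed to the parent
clone; a YAC fully covered by finished sequence yields no pieces and is
reported in the fully-covered list.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

from .annotation_io import CloneRecord
from .intervals import IntervalSet, covered_bp_in, subtract


@dataclass
class OverlapStats:
    """Per-YAC overlap with the merged finished (cosmid+fosmid) set."""

    per_yac_fraction: Dict[str, float] = field(default_factory=dict)
    fully_covered: List[str] = field(default_factory=list)
    yacs_with_exclusive: int = 0

    @property
    def mean_fraction(self) -> float:
        if not self.per_yac_fraction:
            return 0.0
        return sum(self.per_yac_fraction.values()) / len(self.per_yac_fraction)


def clone_interval_set(clones: Iterable[CloneRecord]) -> IntervalSet:
    """Merged union of the clones' genomic spans."""
    return IntervalSet(c.interval for c in clones).merged()


def derive_exclusive(
    yacs: Sequence[CloneRecord],
    finished: Sequence[CloneRecord],
) -> Tuple[List[CloneRecord], OverlapStats]:
    """Trim each YAC against the merged finished set.

    Returns the YAC-exclusive pieces (``parent_id`` = original YAC id,
    piece ids suffixed ``.1``, ``.2``, … when a YAC splits) and the
    per-YAC overlap statistics.  Conservation holds exactly: for every
    YAC, length = exclusive bp + overlapped bp.
    """
    finished_set = clone_interval_set(finished)
    pieces: List[CloneRecord] = []
    stats = OverlapStats()
    for yac in yacs:
        if yac.clone_type != "yac":
            raise ValueError(f"clone {yac.clone_id!r} is {yac.clone_type}, expected yac")
        overlapped = covered_bp_in(yac.interval, finished_set)
        frac = overlapped / yac.length
        stats.per_yac_fraction[yac.clone_id] = frac
        if overlapped == yac.length:
            stats.fully_covered.append(yac.clone_id)
            continue
        exclusive = subtract(IntervalSet([yac.interval]), finished_set)
        ivs = list(exclusive)
        stats.yacs_with_exclusive += 1
        if len(ivs) == 1:
            pieces.append(CloneRecord(yac.clone_id, "yac", ivs[0], parent_id=yac.clone_id))
        else:
            for k, iv in enumerate(ivs, 1):
                pieces.append(
                    CloneRecord(f"{yac.clone_id}.{k}", "yac", iv, parent_id=yac.clone_id)
                )
    return pieces, stats


def split_clones_by_type(
    clones: Sequence[CloneRecord],
) -> Tuple[List[CloneRecord], List[CloneRecord], List[CloneRecord]]:
    """(cosmids, fosmids, yacs) partition of a mixed clone table."""
    cosmids = [c for c in clones if c.clone_type == "cosmid"]
    fosmids = [c for c in clones if c.clone_type == "fosmid"]
    yacs = [c for c in clones if c.clone_type == "yac"]
    return cosmids, fosmids, yacs
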