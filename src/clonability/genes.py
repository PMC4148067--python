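"""Gene categorization, density, 21U-piRNA composition and region analyses.

Genes are assigned to clone libraries (finished cosmid/fosmid territory
vs YAC-exclusive territory) and compared by category — protein-coding
(CDS), ncRNA, tRNA, rRNA — via counts, densities per megabase, length
statistics, 21U-piRNA composition, per-chromosome breakdowns (including
re-ratios after excluding a chromosome, mirroring the dominance of the
piRNA-cluster chromosome), and repeat-masked percentages of named
regions such as piRNA clusters.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .annotation_io import CloneRecord, GeneRecord, RepeatAnnotation
from .intervals import GenomicInterval, IntervalSet, covered_bp_in

logger = logging.getLogger(__name__)

GENE_CATEGORIES = ("CDS", "ncRNA", "tRNA", "rRNA", "other")

_21U_NAME = re.compile(r"^21ur-", re.IGNORECASE)


def is_21u(gene: GeneRecord) -> bool:
    """True iff the gene is an ncRNA and carries the 21U-piRNA naming flag.

    A gene whose id matches ``21ur-*`` but whose category is not ncRNA is
    malformed annotation: it is not counted as 21U and a warning is
    logged.
    """
    named_21u = bool(_21U_NAME.match(gene.gene_id)) or gene.is_21u
    if named_21u and gene.category != "ncRNA":
        logger.warning(
            "gene %s looks like a 21U-RNA but has category %s; ignoring 21U flag",
            gene.gene_id, gene.category,
        )
        return False
    return named_21u


def assign_genes_to_library(
    genes: Sequence[GeneRecord],
    libraries: Dict[str, Sequence[CloneRecord]],
    assign: str = "midpoint",
) -> Dict[str, List[GeneRecord]]:
    """Partition genes among clone libraries.

    ``assign='midpoint'`` (default) places a gene in a library when its
    interval midpoint falls inside any clone of that library — a gene
    straddling a boundary is never duplicated as long as the library
    interval sets are disjoint (they are, after trimming).
    ``'contained'`` requires the full gene inside the library's coverage;
    ``'any-overlap'`` admits one overlapping base.  Membership is decided
    per library independently: libraries with overlapping territories
    (cosmids and fosmids) may share genes, while disjoint territories
    (finished vs YAC-exclusive after trimming) never duplicate a gene.
    Genes matching no library are returned under the key ``"unassigned"``.
    """
    if assign not in ("midpoint", "contained", "any-overlap"):
        raise ValueError(f"bad assignment mode {assign!r}")
    lib_sets = {name: IntervalSet(c.interval for c in clones).merged()
                for name, clones in libraries.items()}
    out: Dict[str, List[GeneRecord]] = {name: [] for name in libraries}
    out["unassigned"] = []
    for g in genes:
        iv = g.interval
        hit_any = False
        for name, iset in lib_sets.items():
            if assign == "midpoint":
                mid = (iv.start + iv.end) // 2
                probe = GenomicInterval(iv.chrom, mid, mid + 1)
                hit = covered_bp_in(probe, iset) == 1
            elif assign == "contained":
                hit = covered_bp_in(iv, iset) == iv.length
            else:
                hit = covered_bp_in(iv, iset) > 0
            if hit:
                out[name].append(g)
                hit_any = True
        if not hit_any:
            out["unassigned"].append(g)
    return out


def density_per_mb(count: int, coverage_bp: int) -> float:
    """Genes per megabase of library coverage."""
    if coverage_bp <= 0:
        raise ValueError("coverage must be positive")
    return count / (coverage_bp / 1e6)


def composition_fraction(sub_count: int, total_count: int) -> float:
    """Percentage of a subset within a total (e.g. 21U among ncRNAs)."""
    if total_count <= 0:
        raise ValueError("total count must be positive")
    return 100.0 * sub_count / total_count


def gene_length_stats(genes: Sequence[GeneRecord]) -> Tuple[int, float, float, float]:
    """(count, mean, median, SD) of gene lengths; SD uses n−1."""
    if not genes:
        raise ValueError("empty gene set")
    lengths = np.array([g.length for g in genes], dtype=float)
    sd = float(lengths.std(ddof=1)) if len(lengths) > 1 else 0.0
    return len(lengths), float(lengths.mean()), float(np.median(lengths)), sd


def per_chromosome_counts(genes: Sequence[GeneRecord], category: str = "ncRNA") -> Dict[str, int]:
    counts: Dict[str, int] = {}
    for g in genes:
        if g.category == category:
            counts[g.interval.chrom] = counts.get(g.interval.chrom, 0) + 1
    return counts


@dataclass
class ExclusionResult:
    """Library feature counts recomputed after dropping one chromosome."""

    excluded_chrom: str
    counts: Dict[str, int]  # library -> remaining count
    densities: Dict[str, float]  # library -> per-MB density on remaining bp
    ratio: Optional[float]  # first library : second library, None if undefined


def exclude_chromosome(
    per_library_genes: Dict[str, Sequence[GeneRecord]],
    per_library_coverage: Dict[str, Dict[str, int]],
    chrom: str,
    category: str = "ncRNA",
    ratio_of: Tuple[str, str] = ("cosmid", "yac"),
) -> ExclusionResult:
    """Recompute category counts/densities over all chromosomes but one.

    ``per_library_coverage`` maps library -> {chrom -> covered bp}.  The
    reported ratio is counts[ratio_of[0]] / counts[ratio_of[1]].
    """
    all_chroms = set()
    for cov in per_library_coverage.values():
        all_chroms.update(cov)
    if chrom not in all_chroms:
        raise KeyError(f"unknown chromosome {chrom!r}")
    counts: Dict[str, int] = {}
    densities: Dict[str, float] = {}
    for lib in per_library_coverage:  # libraries without coverage (e.g.
        genes = per_library_genes.get(lib, ())  # "unassigned") are skipped
        kept = [g for g in genes if g.category == category and g.interval.chrom != chrom]
        counts[lib] = len(kept)
        cov = sum(bp for c, bp in per_library_coverage[lib].items() if c != chrom)
        densities[lib] = density_per_mb(len(kept), cov) if cov > 0 else float("nan")
    a, b = ratio_of
    ratio = counts[a] / counts[b] if counts.get(b) else None
    return ExclusionResult(chrom, counts, densities, ratio)


def region_masked_pct(region: GenomicInterval, repeats: Iterable[RepeatAnnotation]) -> float:
    """Percent of a region's bases covered by the union of repeat spans."""
    iset = IntervalSet(r.interval for r in repeats
                       if r.interval.chrom == region.chrom).merged()
    return 100.0 * covered_bp_in(region, iset) / region.length


@dataclass
class GeneLibrarySummary:
    """Per-library, per-category gene statistics (counts, lengths, 21U)."""

    library: str
    coverage_bp: int
    table: pd.DataFrame  # one row per category: count, density, length stats
    ncrna_21u_count: int
    ncrna_21u_fraction_pct: Optional[float]
    per_chrom_ncrna: Dict[str, int] = field(default_factory=dict)


def summarize_gene_library(
    library: str, genes: Sequence[GeneRecord], coverage_bp: int
) -> GeneLibrarySummary:
    rows = []
    for cat in GENE_CATEGORIES:
        sub = [g for g in genes if g.category == cat]
        if sub:
            n, mean, median, sd = gene_length_stats(sub)
        else:
            n, mean, median, sd = 0, float("nan"), float("nan"), float("nan")
        rows.append(
            {
                "category": cat,
                "count": n,
                "per_mb": density_per_mb(n, coverage_bp),
                "mean_length": mean,
                "median_length": median,
                "length_sd": sd,
            }
        )
    ncrnas = [g for g in genes if g.category == "ncRNA"]
    n21 = sum(1 for g in ncrnas if is_21u(g))
    frac = composition_fraction(n21, len(ncrnas)) if ncrnas else None
    return GeneLibrarySummary(
        library=library,
        coverage_bp=coverage_bp,
        table=pd.DataFrame(rows),
        ncrna_21u_count=n21,
        ncrna_21u_fraction_pct=frac,
        per_chrom_ncrna=per_chromosome_counts(genes, "ncRNA"),
    )


def longest_clones_table(clones: Sequence[CloneRecord], n: int = 15) -> pd.DataFrame:
    """The n longest clones: id, chromosome, 1-based coordinates, length in kb."""
    ranked = sorted(clones, key=lambda c: (-c.length, c.clone_id))[:n]
    return pd.DataFrame(
        {
            "clone_id": [c.parent_id or c.clone_id for c in ranked],
            "chrom": [c.interval.chrom for c in ranked],
            "start_1based": [c.interval.start + 1 for c in ranked],
            "end_1based": [c.interval.end for c in ranked],
            "length_kb": [round(c.length / 1000) for c in ranked],
        }
    )
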