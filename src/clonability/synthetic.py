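"""Self-contained synthetic genome + annotation + clone-library generator.

Emulates the statistical structure the analysis assumes, so every
pipeline stage is testable without any external download:

* each chromosome carries *gap regions* — territory covered by no
  cosmid/fosmid — bridged by YAC clones whose ends extend a little into
  the surrounding finished sequence (per-YAC overlap fraction drawn from
  a Beta distribution with mean ~7%, ranging from ~0 to ~100%);
* cosmids tile all non-gap territory with small neighbor overlaps, so
  trimming a YAC against the cosmid/fosmid union recovers its gap
  exactly;
* repeat elements are planted with arm enrichment (the two extreme
  chromosome quarters are repeat-rich), DNA transposons are planted
  denser inside gaps than outside, and one chromosome carries a dense
  piRNA cluster of short 21U ncRNA genes in otherwise low-repeat
  sequence;
* genes (CDS / ncRNA / tRNA / rRNA) are planted per-territory with
  Poisson counts and uniform placement.

A ``truth.tsv`` records every planted interval and, computed directly
from per-base bitmaps (independently of the interval-arithmetic used by
the pipeline), the realized territory statistics the recovery tests
compare against.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import MISSING, dataclass, field, fields
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .annotation_io import (
    CloneRecord,
    GeneRecord,
    RepeatAnnotation,
    write_chrom_sizes,
    write_clone_table,
    write_gff3_genes,
    write_repeatmasker_out,
)
from .intervals import ChromSizes, GenomicInterval

_ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X"]

_DNA_CLASSES = (("DNA/PiggyBac", 0.15), ("DNA/TcMar-Tc1", 0.40),
                ("DNA/hAT-Ac", 0.25), ("DNA/MULE-MuDR", 0.20))

# non-transposon repeat classes: (class, weight, length mean, length sd)
_OTHER_CLASSES = (
    ("LINE/CR1", 0.15, 400.0, 150.0),
    ("LTR/Gypsy", 0.08, 450.0, 150.0),
    ("Satellite", 0.20, 600.0, 200.0),
    ("Simple_repeat", 0.30, 80.0, 30.0),
    ("Low_complexity", 0.17, 60.0, 20.0),
    ("Unknown", 0.10, 300.0, 100.0),
)


@dataclass(frozen=True)
class FeatureLengthModel:
    """Normal length model for planted features, truncated by clipping."""

    mean: float
    sd: float
    min: int = 1
    max: Optional[int] = None


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic genome; defaults are the study conditions.

    Lengths in bp, densities per kb or per MB as named; ``seed`` is
    mandatory — every generated bundle is a pure function of its config.
    """

    seed: int
    n_chroms: int = 5
    chrom_length: int = 2_000_000
    # gaps (bacteria-unclonable territory)
    gap_fraction: float = 0.15
    gap_length_median: float = 23_700.0
    gap_length_sigma: float = 0.6  # sigma of log-length
    gap_min_length: int = 6_000
    gap_max_length: int = 120_000
    gap_arm_prob: float = 0.77  # fraction of gaps placed on extreme quarters
    gap_margin: int = 45_000  # min spacing between gaps and from chrom ends
    # finished libraries
    cosmid_length_mean: float = 32_500.0
    cosmid_length_sd: float = 4_000.0
    cosmid_min_length: int = 18_000
    cosmid_overlap: int = 2_000  # neighbor overlap in the tiling path
    fosmid_count: int = 15
    fosmid_length_mean: float = 38_000.0
    fosmid_length_sd: float = 2_000.0
    # YAC end overlap into finished sequence
    yac_overlap_mean: float = 0.07  # mean per-YAC overlapped fraction
    yac_overlap_beta_a: float = 0.5  # Beta shape a (b follows from the mean)
    fully_covered_yacs: int = 3  # YACs planted wholly inside finished territory
    # repeats
    dna_per_kb_gap: float = 0.44  # DNA-transposon elements per kb inside gaps
    dna_gap_to_nongap_ratio: float = 2.0
    dna_length_mean: float = 250.0
    dna_length_sd: float = 80.0
    other_repeat_per_kb_middle: float = 0.15
    arm_repeat_multiplier: float = 3.0
    smallrna_per_kb: float = 0.002
    # piRNA cluster
    cluster_chrom: str = "chrIV"
    cluster_span: int = 300_000  # 0 disables the cluster
    cluster_pirna_count: int = 2_000
    cluster_repeat_multiplier: float = 0.4  # repeat suppression inside cluster
    # genes
    cds_per_mb: float = 220.0
    cds_length_median: float = 948.0
    cds_length_sigma: float = 0.7
    ncrna_per_mb: float = 100.0
    ncrna_length_median: float = 83.0
    ncrna_length_sigma: float = 0.7
    ncrna_21u_fraction: float = 0.4  # 21U share of background ncRNAs
    pirna_length: int = 21
    trna_per_mb_gap: float = 4.2
    trna_per_mb_nongap: float = 1.5
    rrna_per_mb_gap: float = 0.45
    rrna_per_mb_nongap: float = 0.15
    write_fasta: bool = True

    def validate(self) -> None:
        if not (0 < self.gap_fraction < 1):
            raise ValueError("gap_fraction must be in (0,1)")
        if self.n_chroms < 1 or self.n_chroms > len(_ROMAN):
            raise ValueError(f"n_chroms must be in 1..{len(_ROMAN)}")
        if self.cluster_span:
            if self.cluster_chrom not in self.chrom_names:
                raise ValueError(f"cluster_chrom {self.cluster_chrom!r} not among chromosomes")
            quarter = self.chrom_length // 4
            if self.cluster_span > quarter - 2 * self.gap_margin:
                raise ValueError(
                    f"cluster_span {self.cluster_span} does not fit an extreme "
                    f"quarter ({quarter} bp) with margins"
                )
        for f in ("gap_length_median", "cosmid_length_mean", "dna_per_kb_gap",
                  "other_repeat_per_kb_middle", "cds_per_mb", "ncrna_per_mb"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be non-negative")
        if not (0 <= self.yac_overlap_mean < 1):
            raise ValueError("yac_overlap_mean must be in [0,1)")

    @property
    def chrom_names(self) -> List[str]:
        return [f"chr{_ROMAN[i]}" for i in range(self.n_chroms)]

    # -- flat key=value config files ----------------------------------

    def to_file(self, path) -> None:
        with open(path, "wt") as fh:
            for f in fields(self):
                fh.write(f"{f.name}={getattr(self, f.name)}\n")

    @classmethod
    def from_file(cls, path, **overrides) -> "SyntheticConfig":
        kwargs: Dict[str, object] = {}
        types = {f.name: f.type for f in fields(cls)}
        defaults = {f.name: f.default for f in fields(cls)}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected key=value, got {line!r}")
                key, _, value = line.partition("=")
                key = key.strip()
                if key not in types:
                    raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
                proto = defaults[key]
                if proto is MISSING:  # the mandatory integer seed
                    kwargs[key] = int(value)
                elif isinstance(proto, bool):
                    kwargs[key] = value.strip().lower() in ("1", "true", "yes")
                elif isinstance(proto, int):
                    kwargs[key] = int(value)
                elif isinstance(proto, float):
                    kwargs[key] = float(value)
                else:
                    kwargs[key] = value.strip()
        kwargs.update(overrides)
        return cls(**kwargs)  # type: ignore[arg-type]


@dataclass
class SyntheticBundle:
    """In-memory result of one generation run plus the truth record."""

    config: SyntheticConfig
    sizes: ChromSizes
    clones: List[CloneRecord]
    repeats: List[RepeatAnnotation]
    genes: List[GeneRecord]
    gaps: List[GenomicInterval]
    cluster: Optional[GenomicInterval]
    truth: Dict[str, float]
    paths: Dict[str, Path] = field(default_factory=dict)

    @property
    def cosmids(self) -> List[CloneRecord]:
        return [c for c in self.clones if c.clone_type == "cosmid"]

    @property
    def fosmids(self) -> List[CloneRecord]:
        return [c for c in self.clones if c.clone_type == "fosmid"]

    @property
    def yacs(self) -> List[CloneRecord]:
        return [c for c in self.clones if c.clone_type == "yac"]


def plant_feature_track(
    regions: Sequence[GenomicInterval],
    density_per_kb: float,
    length_model: FeatureLengthModel,
    rng: np.random.Generator | int,
) -> List[GenomicInterval]:
    """Plant Poisson-count features uniformly within each region.

    Feature count per region ~ Poisson(density × region kb); lengths are
    clipped normal draws; features never cross region boundaries
    (regions shorter than the minimum feature length get none).
    """
    if density_per_kb < 0:
        raise ValueError("density must be non-negative")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    out: List[GenomicInterval] = []
    for region in regions:
        if region.length < length_model.min:
            continue
        count = rng.poisson(density_per_kb * region.length / 1000.0)
        if count == 0:
            continue
        hi = min(length_model.max or region.length, region.length)
        lengths = np.clip(
            np.rint(rng.normal(length_model.mean, length_model.sd, size=count)),
            length_model.min, hi,
        ).astype(np.int64)
        starts = region.start + (rng.random(count) * (region.length - lengths + 1)).astype(np.int64)
        order = np.argsort(starts, kind="stable")
        for s, ln in zip(starts[order], lengths[order]):
            out.append(GenomicInterval(region.chrom, int(s), int(s + ln)))
    return out


# ---------------------------------------------------------------------------
# generation internals


def _place_gaps(cfg: SyntheticConfig, chrom: str, rng: np.random.Generator,
                preplaced: Sequence[Tuple[int, int]]) -> List[Tuple[int, int]]:
    """Rejection-sample non-overlapping gap intervals on one chromosome."""
    L = cfg.chrom_length
    margin = cfg.gap_margin
    placed = list(preplaced)
    placed_bp = sum(e - s for s, e in placed)
    target = cfg.gap_fraction * L
    mu = math.log(cfg.gap_length_median)
    quarter = L // 4
    arm_pieces = [(margin, quarter), (3 * quarter, L - margin)]
    mid_pieces = [(quarter, 3 * quarter)]
    attempts = 0
    while placed_bp < target and attempts < 20_000:
        attempts += 1
        length = int(round(rng.lognormal(mu, cfg.gap_length_sigma)))
        length = min(max(length, cfg.gap_min_length), cfg.gap_max_length)
        if placed_bp + length > target * 1.15:
            length = int(target - placed_bp)
            if length < cfg.gap_min_length:
                break
        pieces = arm_pieces if rng.random() < cfg.gap_arm_prob else mid_pieces
        weights = np.array([max(e - s - length, 0) for s, e in pieces], dtype=float)
        if weights.sum() == 0:
            continue
        ps, pe = pieces[int(rng.choice(len(pieces), p=weights / weights.sum()))]
        start = int(ps + rng.random() * (pe - ps - length))
        end = start + length
        if any(start - margin < e and end + margin > s for s, e in placed):
            continue
        placed.append((start, end))
        placed_bp += length
    return sorted(placed)


def _tile_cosmids(cfg: SyntheticConfig, chrom: str, segments: Sequence[Tuple[int, int]],
                  rng: np.random.Generator, counter: List[int]) -> List[CloneRecord]:
    """Tile every non-gap segment wall-to-wall with overlapping cosmids."""
    clones: List[CloneRecord] = []
    for seg_start, seg_end in segments:
        cur = seg_start
        seg_clones: List[List[int]] = []
        while cur < seg_end:
            length = int(np.clip(
                round(rng.normal(cfg.cosmid_length_mean, cfg.cosmid_length_sd)),
                cfg.cosmid_min_length, 1.5 * cfg.cosmid_length_mean,
            ))
            end = min(cur + length, seg_end)
            if seg_clones and end - cur < cfg.cosmid_min_length:
                seg_clones[-1][1] = seg_end  # extend the previous cosmid instead
                break
            seg_clones.append([cur, end])
            overlap = int(max(0, rng.normal(cfg.cosmid_overlap, cfg.cosmid_overlap / 4)))
            cur = end - overlap
            if cur >= seg_end:
                break
        for s, e in seg_clones:
            counter[0] += 1
            clones.append(CloneRecord(f"cos{counter[0]}", "cosmid", GenomicInterval(chrom, s, e)))
    return clones


def _bridge_yacs(cfg: SyntheticConfig, chrom: str, gaps: Sequence[Tuple[int, int]],
                 rng: np.random.Generator, counter: List[int]) -> List[CloneRecord]:
    """One YAC per gap, extending into finished territory on both ends."""
    L = cfg.chrom_length
    yacs: List[CloneRecord] = []
    bounds = [(0, 0)] + list(gaps) + [(L, L)]
    a = cfg.yac_overlap_beta_a
    b = a * (1.0 - cfg.yac_overlap_mean) / max(cfg.yac_overlap_mean, 1e-9)
    for i in range(1, len(bounds) - 1):
        gs, ge = bounds[i]
        gap_len = ge - gs
        f = float(rng.beta(a, b)) if cfg.yac_overlap_mean > 0 else 0.0
        total_ext = int(round(gap_len * f / (1.0 - f))) if f < 1 else gap_len
        u = rng.random()
        left = int(round(total_ext * u))
        right = total_ext - left
        # never reach into a neighboring gap or off the chromosome
        left = min(left, gs - bounds[i - 1][1] - 1000, gs)
        right = min(right, bounds[i + 1][0] - ge - 1000, L - ge)
        left, right = max(left, 0), max(right, 0)
        counter[0] += 1
        yacs.append(CloneRecord(
            f"yac{counter[0]}", "yac", GenomicInterval(chrom, gs - left, ge + right)
        ))
    return yacs


def _weighted_class(rng: np.random.Generator, table) -> tuple:
    w = np.array([t[1] for t in table])
    return table[int(rng.choice(len(table), p=w / w.sum()))]


def _plant_repeats(cfg: SyntheticConfig, chrom: str, gaps, cluster,
                   rng: np.random.Generator) -> List[RepeatAnnotation]:
    L = cfg.chrom_length
    quarter = L // 4
    out: List[RepeatAnnotation] = []

    def in_cluster(s, e):
        return cluster is not None and cluster.chrom == chrom and \
            s >= cluster.start and e <= cluster.end

    # --- DNA transposons: gap vs non-gap density, suppressed in the cluster
    nongap_density = cfg.dna_per_kb_gap / cfg.dna_gap_to_nongap_ratio
    gap_regions = [GenomicInterval(chrom, s, e) for s, e in gaps]
    nongap_regions = _complement(chrom, gaps, L)
    lm_dna = FeatureLengthModel(cfg.dna_length_mean, cfg.dna_length_sd, min=50)
    for regions, dens in ((gap_regions, cfg.dna_per_kb_gap), (nongap_regions, nongap_density)):
        for region in regions:
            d = dens * (cfg.cluster_repeat_multiplier if in_cluster(region.start, region.end) else 1.0)
            for iv in plant_feature_track([region], d, lm_dna, rng):
                cls, _ = _weighted_class(rng, _DNA_CLASSES)
                out.append(RepeatAnnotation(iv, cls.split("/")[1] + "-elt", cls, 1000.0))

    # --- other repeat classes: arm-enriched, suppressed in the cluster
    pieces = _split_pieces(chrom, L, quarter, cluster)
    for (ps, pe, on_arm, in_cl) in pieces:
        base = cfg.other_repeat_per_kb_middle * (cfg.arm_repeat_multiplier if on_arm else 1.0)
        if in_cl:
            base *= cfg.cluster_repeat_multiplier
        for cls, weight, lmean, lsd in _OTHER_CLASSES:
            lm = FeatureLengthModel(lmean, lsd, min=20)
            for iv in plant_feature_track(
                [GenomicInterval(chrom, ps, pe)], base * weight, lm, rng
            ):
                out.append(RepeatAnnotation(iv, cls.split("/")[-1] + "-elt", cls, 500.0))

    # --- small RNA repeats, sparse and uniform
    lm_srna = FeatureLengthModel(100.0, 20.0, min=40)
    for iv in plant_feature_track(
        [GenomicInterval(chrom, 0, L)], cfg.smallrna_per_kb, lm_srna, rng
    ):
        out.append(RepeatAnnotation(iv, "srna-elt", "snRNA", 300.0))
    out.sort(key=lambda a: (a.interval.start, a.interval.end))
    return out


def _split_pieces(chrom, L, quarter, cluster):
    """(start, end, on_arm, in_cluster) pieces partitioning a chromosome."""
    cuts = {0, quarter, 3 * quarter, L}
    if cluster is not None and cluster.chrom == chrom:
        cuts.update((cluster.start, cluster.end))
    edges = sorted(cuts)
    pieces = []
    for s, e in zip(edges[:-1], edges[1:]):
        mid = (s + e) // 2
        on_arm = mid < quarter or mid >= 3 * quarter
        in_cl = cluster is not None and cluster.chrom == chrom \
            and s >= cluster.start and e <= cluster.end
        pieces.append((s, e, on_arm, in_cl))
    return pieces


def _complement(chrom: str, intervals: Sequence[Tuple[int, int]], L: int) -> List[GenomicInterval]:
    out = []
    cur = 0
    for s, e in sorted(intervals):
        if s > cur:
            out.append(GenomicInterval(chrom, cur, s))
        cur = max(cur, e)
    if cur < L:
        out.append(GenomicInterval(chrom, cur, L))
    return out


def _plant_genes(cfg: SyntheticConfig, chrom: str, gaps, cluster,
                 rng: np.random.Generator, counters: Dict[str, int]) -> List[GeneRecord]:
    L = cfg.chrom_length
    genes: List[GeneRecord] = []
    gap_regions = [GenomicInterval(chrom, s, e) for s, e in gaps]
    nongap_regions = _complement(chrom, gaps, L)
    cluster_here = cluster if (cluster is not None and cluster.chrom == chrom) else None
    noncluster_regions = [
        r for r in gap_regions + nongap_regions
        if not (cluster_here and r.start >= cluster_here.start and r.end <= cluster_here.end)
    ]

    def next_id(prefix):
        counters[prefix] = counters.get(prefix, 0) + 1
        return f"{prefix}-{counters[prefix]}"

    # protein-coding genes, uniform outside the cluster
    lm_cds = FeatureLengthModel(0, 0, min=200, max=10_000)
    for region in noncluster_regions:
        count = rng.poisson(cfg.cds_per_mb * region.length / 1e6)
        for _ in range(count):
            ln = int(np.clip(round(rng.lognormal(math.log(cfg.cds_length_median),
                                                 cfg.cds_length_sigma)),
                             lm_cds.min, min(lm_cds.max, region.length)))
            s = region.start + int(rng.random() * (region.length - ln + 1))
            genes.append(GeneRecord(next_id("gene"), GenomicInterval(chrom, s, s + ln), "CDS"))

    # background ncRNAs (a configurable share are 21U-RNAs)
    for region in noncluster_regions:
        count = rng.poisson(cfg.ncrna_per_mb * region.length / 1e6)
        for _ in range(count):
            if rng.random() < cfg.ncrna_21u_fraction:
                ln = cfg.pirna_length
                gid = next_id("21ur")
                flag = True
            else:
                ln = int(np.clip(round(rng.lognormal(math.log(cfg.ncrna_length_median),
                                                     cfg.ncrna_length_sigma)), 20, 2000))
                gid = next_id("ncrna")
                flag = False
            ln = min(ln, region.length)
            s = region.start + int(rng.random() * (region.length - ln + 1))
            genes.append(GeneRecord(gid, GenomicInterval(chrom, s, s + ln), "ncRNA", flag))

    # the piRNA cluster: exactly the configured number of 21U genes
    if cluster_here is not None:
        ln = cfg.pirna_length
        starts = cluster_here.start + (
            rng.random(cfg.cluster_pirna_count) * (cluster_here.length - ln)
        ).astype(np.int64)
        for s in np.sort(starts):
            genes.append(GeneRecord(next_id("21ur"),
                                    GenomicInterval(chrom, int(s), int(s) + ln), "ncRNA", True))

    # tRNA / rRNA with gap vs non-gap densities
    for category, lm, dens_gap, dens_nongap in (
        ("tRNA", FeatureLengthModel(75, 5, min=60, max=120), cfg.trna_per_mb_gap, cfg.trna_per_mb_nongap),
        ("rRNA", FeatureLengthModel(1200, 150, min=100, max=5000), cfg.rrna_per_mb_gap, cfg.rrna_per_mb_nongap),
    ):
        for regions, dens in ((gap_regions, dens_gap), (nongap_regions, dens_nongap)):
            for iv in plant_feature_track(regions, dens / 1000.0, lm, rng):
                genes.append(GeneRecord(next_id(category.lower()), iv, category))

    genes.sort(key=lambda g: (g.interval.start, g.interval.end, g.gene_id))
    return genes


# ---------------------------------------------------------------------------
# truth bookkeeping (per-base bitmaps, independent of the interval module)


def _truth_stats(cfg, per_chrom_gaps, cluster, clones, repeats, genes) -> Dict[str, float]:
    from .repeat_summary import classify_repeat

    L = cfg.chrom_length
    stats: Dict[str, float] = {}
    tot = {k: 0 for k in ("gap_bp", "nongap_bp", "gap_masked", "nongap_masked",
                          "gap_dna", "nongap_dna")}
    pirna_gap = pirna_nongap = ncrna_gap = ncrna_nongap = 0
    ncrna_gap_ex = ncrna_nongap_ex = 0  # excluding the cluster chromosome
    by_chrom_rep: Dict[str, list] = {}
    for r in repeats:
        by_chrom_rep.setdefault(r.interval.chrom, []).append(r)
    for chrom in cfg.chrom_names:
        gapmask = np.zeros(L, dtype=bool)
        for s, e in per_chrom_gaps.get(chrom, ()):
            gapmask[s:e] = True
        repmask = np.zeros(L, dtype=bool)
        dnamask = np.zeros(L, dtype=bool)
        for r in by_chrom_rep.get(chrom, ()):
            repmask[r.interval.start:r.interval.end] = True
            if classify_repeat(r).label == "DNA_transposons":
                dnamask[r.interval.start:r.interval.end] = True
        tot["gap_bp"] += int(gapmask.sum())
        tot["nongap_bp"] += int((~gapmask).sum())
        tot["gap_masked"] += int((repmask & gapmask).sum())
        tot["nongap_masked"] += int((repmask & ~gapmask).sum())
        tot["gap_dna"] += int((dnamask & gapmask).sum())
        tot["nongap_dna"] += int((dnamask & ~gapmask).sum())
        if cluster is not None and chrom == cluster.chrom:
            span = repmask[cluster.start:cluster.end]
            stats["cluster_masked_pct"] = 100.0 * span.sum() / len(span)
            stats["cluster_chrom_masked_pct"] = 100.0 * repmask.sum() / L
        for g in genes:
            if g.interval.chrom != chrom or g.category != "ncRNA":
                continue
            mid = (g.interval.start + g.interval.end) // 2
            in_gap = bool(gapmask[mid])
            ncrna_gap += in_gap
            ncrna_nongap += not in_gap
            if cluster is None or chrom != cluster.chrom:
                ncrna_gap_ex += in_gap
                ncrna_nongap_ex += not in_gap
            if g.is_21u:
                pirna_gap += in_gap
                pirna_nongap += not in_gap
    stats["gap_bp"] = tot["gap_bp"]
    stats["nongap_bp"] = tot["nongap_bp"]
    stats["gap_masked_pct"] = 100.0 * tot["gap_masked"] / max(tot["gap_bp"], 1)
    stats["nongap_masked_pct"] = 100.0 * tot["nongap_masked"] / max(tot["nongap_bp"], 1)
    stats["gap_dna_pct"] = 100.0 * tot["gap_dna"] / max(tot["gap_bp"], 1)
    stats["nongap_dna_pct"] = 100.0 * tot["nongap_dna"] / max(tot["nongap_bp"], 1)
    stats["gap_ncrna_count"] = ncrna_gap
    stats["nongap_ncrna_count"] = ncrna_nongap
    stats["gap_ncrna_count_excl_cluster_chrom"] = ncrna_gap_ex
    stats["nongap_ncrna_count_excl_cluster_chrom"] = ncrna_nongap_ex
    stats["gap_pirna_count"] = pirna_gap
    stats["nongap_pirna_count"] = pirna_nongap
    stats["gap_pirna_per_mb"] = pirna_gap / max(tot["gap_bp"], 1) * 1e6
    stats["nongap_pirna_per_mb"] = pirna_nongap / max(tot["nongap_bp"], 1) * 1e6
    # realized YAC overlap fractions (bridging YACs only)
    fracs = []
    for c in clones:
        if c.clone_type != "yac" or c.clone_id.startswith("yacF"):
            continue
        chrom = c.interval.chrom
        gap_bp = sum(min(e, c.interval.end) - max(s, c.interval.start)
                     for s, e in per_chrom_gaps.get(chrom, ())
                     if s < c.interval.end and e > c.interval.start)
        fracs.append(1.0 - gap_bp / c.length)
    stats["mean_yac_overlap_fraction"] = float(np.mean(fracs)) if fracs else 0.0
    stats["n_bridging_yacs"] = len(fracs)
    return stats


def _write_truth(path, cfg, per_chrom_gaps, cluster, stats: Dict[str, float]) -> None:
    with open(path, "wt") as fh:
        fh.write("kind\tname\tchrom\tstart\tend\tvalue\n")
        for f in fields(cfg):
            fh.write(f"param\t{f.name}\t.\t.\t.\t{getattr(cfg, f.name)}\n")
        for chrom in cfg.chrom_names:
            for s, e in per_chrom_gaps.get(chrom, ()):
                fh.write(f"gap\t.\t{chrom}\t{s}\t{e}\t.\n")
        if cluster is not None:
            fh.write(f"cluster\t.\t{cluster.chrom}\t{cluster.start}\t{cluster.end}\t.\n")
        for name in sorted(stats):
            fh.write(f"stat\t{name}\t.\t.\t.\t{stats[name]:.10g}\n")


def read_truth(path) -> Tuple[Dict[str, float], List[GenomicInterval], Optional[GenomicInterval]]:
    """(stats, gap intervals, cluster interval) from a truth.tsv."""
    stats: Dict[str, float] = {}
    gaps: List[GenomicInterval] = []
    cluster = None
    with open(path) as fh:
        next(fh)
        for line in fh:
            kind, name, chrom, start, end, value = line.rstrip("\n").split("\t")
            if kind == "stat":
                stats[name] = float(value)
            elif kind == "gap":
                gaps.append(GenomicInterval(chrom, int(start), int(end)))
            elif kind == "cluster":
                cluster = GenomicInterval(chrom, int(start), int(end))
    return stats, gaps, cluster


def _write_fasta(path, cfg: SyntheticConfig, rng: np.random.Generator) -> None:
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    with open(path, "wb") as fh:
        for chrom in cfg.chrom_names:
            fh.write(f">{chrom}\n".encode())
            seq = alphabet[rng.integers(0, 4, size=cfg.chrom_length)]
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80].tobytes() + b"\n")


# ---------------------------------------------------------------------------
# top-level generation


def generate(config: SyntheticConfig, outdir=None) -> SyntheticBundle:
    """Generate the full bundle; write files when *outdir* is given.

    Files written: ``genome.fa`` (optional), ``chrom.sizes``,
    ``clones.tsv``, ``repeats.out``, ``genes.gff3``, ``truth.tsv`` and
    the config itself as ``config.txt``.  Byte-identical across runs with
    the same config.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    rngs = {name: np.random.default_rng(s) for name, s in zip(
        ("gaps", "clones", "repeats", "genes", "fasta"), root.spawn(5))}

    sizes = ChromSizes((c, config.chrom_length) for c in config.chrom_names)

    # gap layout (the cluster is itself a gap on its chromosome)
    cluster: Optional[GenomicInterval] = None
    per_chrom_gaps: Dict[str, List[Tuple[int, int]]] = {}
    for chrom in config.chrom_names:
        pre: List[Tuple[int, int]] = []
        if config.cluster_span and chrom == config.cluster_chrom:
            L, q, m = config.chrom_length, config.chrom_length // 4, config.gap_margin
            lo, hi = 3 * q + m, config.chrom_length - m - config.cluster_span
            start = int(lo + rngs["gaps"].random() * max(hi - lo, 1))
            cluster = GenomicInterval(chrom, start, start + config.cluster_span)
            pre.append((cluster.start, cluster.end))
        per_chrom_gaps[chrom] = _place_gaps(config, chrom, rngs["gaps"], pre)

    clones: List[CloneRecord] = []
    cos_counter, yac_counter = [0], [0]
    all_segments: Dict[str, List[Tuple[int, int]]] = {}
    for chrom in config.chrom_names:
        segments = [(iv.start, iv.end)
                    for iv in _complement(chrom, per_chrom_gaps[chrom], config.chrom_length)]
        all_segments[chrom] = segments
        clones.extend(_tile_cosmids(config, chrom, segments, rngs["clones"], cos_counter))
    # fosmids: uniform within non-gap territory
    seg_list = [(c, s, e) for c, segs in all_segments.items() for s, e in segs]
    seg_w = np.array([e - s for _, s, e in seg_list], dtype=float)
    for i in range(config.fosmid_count):
        ln = int(max(5000, rngs["clones"].normal(config.fosmid_length_mean, config.fosmid_length_sd)))
        for _ in range(100):
            k = int(rngs["clones"].choice(len(seg_list), p=seg_w / seg_w.sum()))
            c, s, e = seg_list[k]
            if e - s > ln:
                start = int(s + rngs["clones"].random() * (e - s - ln))
                clones.append(CloneRecord(f"fos{i + 1}", "fosmid",
                                          GenomicInterval(c, start, start + ln)))
                break
    for chrom in config.chrom_names:
        clones.extend(_bridge_yacs(config, chrom, per_chrom_gaps[chrom],
                                   rngs["clones"], yac_counter))
    # planted fully-covered YACs (inside finished territory)
    for i in range(config.fully_covered_yacs):
        ln = int(max(8000, rngs["clones"].normal(20_000, 5_000)))
        for _ in range(100):
            k = int(rngs["clones"].choice(len(seg_list), p=seg_w / seg_w.sum()))
            c, s, e = seg_list[k]
            if e - s > ln + 2000:
                start = int(s + 1000 + rngs["clones"].random() * (e - s - ln - 2000))
                clones.append(CloneRecord(f"yacF{i + 1}", "yac",
                                          GenomicInterval(c, start, start + ln)))
                break

    repeats: List[RepeatAnnotation] = []
    genes: List[GeneRecord] = []
    gene_counters: Dict[str, int] = {}
    for chrom in config.chrom_names:
        repeats.extend(_plant_repeats(config, chrom, per_chrom_gaps[chrom], cluster, rngs["repeats"]))
        genes.extend(_plant_genes(config, chrom, per_chrom_gaps[chrom], cluster,
                                  rngs["genes"], gene_counters))

    truth = _truth_stats(config, per_chrom_gaps, cluster, clones, repeats, genes)
    gaps_flat = [GenomicInterval(c, s, e) for c in config.chrom_names
                 for s, e in per_chrom_gaps[c]]
    bundle = SyntheticBundle(config, sizes, clones, repeats, genes, gaps_flat, cluster, truth)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "chrom_sizes": outdir / "chrom.sizes",
            "clones": outdir / "clones.tsv",
            "repeats": outdir / "repeats.out",
            "genes": outdir / "genes.gff3",
            "truth": outdir / "truth.tsv",
            "config": outdir / "config.txt",
        }
        write_chrom_sizes(sizes, paths["chrom_sizes"])
        write_clone_table(clones, paths["clones"])
        write_repeatmasker_out(repeats, paths["repeats"])
        write_gff3_genes(genes, paths["genes"])
        _write_truth(paths["truth"], config, per_chrom_gaps, cluster, truth)
        config.to_file(paths["config"])
        if config.write_fasta:
            paths["fasta"] = outdir / "genome.fa"
            _write_fasta(paths["fasta"], config, rngs["fasta"])
        bundle.paths = paths
    return bundle
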