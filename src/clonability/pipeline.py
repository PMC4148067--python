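"""End-to-end analysis: trim → profile → stratify → genes → null tests.

Wires the stages into the full clone-library comparison and writes
deterministic TSV reports plus a JSON run manifest.  All randomness
derives from one top-level seed, split deterministically per stage, so a
rerun with the same inputs and seed produces byte-identical reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .annotation_io import (
    CloneRecord,
    GeneRecord,
    read_chrom_sizes,
    read_clone_table,
    read_gff3_genes,
    read_repeatmasker_out,
    write_clone_table,
    write_report,
)
from .genes import (
    GeneLibrarySummary,
    assign_genes_to_library,
    exclude_chromosome,
    longest_clones_table,
    region_masked_pct,
    summarize_gene_library,
)
from .intervals import ChromSizes, GenomicInterval, IntervalSet
from .null_model import enrichment_test, fit_length_model
from .repeat_summary import (
    RepeatIndex,
    library_mean,
    profile_library,
    summarize_library,
    summary_frame,
)
from .stratify import (
    location_histogram,
    split_by_median_length,
    split_by_quartile,
    welch_t,
)
from .trimming import derive_exclusive, split_clones_by_type

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, naming the stage and the offending input."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class RunManifest:
    """Inputs, digests, seed and parameters that produced a report bundle."""

    inputs: Dict[str, str]
    digests: Dict[str, str]
    seed: int
    version: str
    parameters: Dict[str, object] = field(default_factory=dict)

    def write(self, path) -> None:
        with open(path, "wt") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _require(path, name: str, stage: str):
    if path is None or not Path(path).exists():
        raise PipelineError(stage, f"missing input file for {name}: {path}")
    return Path(path)


def library_coverage_by_chrom(clones: Sequence[CloneRecord]) -> Dict[str, int]:
    """Union coverage bp per chromosome of a clone library."""
    iset = IntervalSet(c.interval for c in clones).merged()
    return {chrom: int((iset.array(chrom)[:, 1] - iset.array(chrom)[:, 0]).sum())
            for chrom in iset.chroms}


class _MidpointCounter:
    """Fast per-chromosome midpoint-in-set counting for library statistics."""

    def __init__(self, genes: Sequence[GeneRecord]):
        mids: Dict[str, list] = {}
        for g in genes:
            mids.setdefault(g.interval.chrom, []).append(
                (g.interval.start + g.interval.end) // 2
            )
        self._mids = {c: np.sort(np.array(v, dtype=np.int64)) for c, v in mids.items()}

    def count_in(self, iset: IntervalSet) -> int:
        total = 0
        m = iset.merged()
        for chrom, mids in self._mids.items():
            arr = m.array(chrom)
            if len(arr) == 0:
                continue
            idx = np.searchsorted(arr.ravel(), mids, side="right")
            total += int((idx % 2 == 1).sum())
        return total


def run_all(
    chrom_sizes_path,
    clones_path,
    repeats_path,
    gff3_path,
    outdir,
    seed: int = 0,
    replicates: int = 100,
    clusters_bed: Optional[str] = None,
    exclude_chrom: Optional[str] = None,
    histogram_weight: str = "equal",
) -> Dict[str, Path]:
    """Run the full pipeline and write the report bundle under *outdir*.

    Reports: ``overlap_stats.tsv``, ``yac_exclusive.tsv``,
    ``repeat_summary.tsv`` (observed libraries), ``random_controls.tsv``
    (matched random libraries), ``quartile_summary.tsv``,
    ``location_histograms.tsv``, ``length_split.tsv``,
    ``gene_summary.tsv``, ``ncrna_per_chrom.tsv``,
    ``chromosome_exclusion.tsv``, ``longest_yacs.tsv``,
    ``enrichment.tsv``, optional ``cluster_repeatness.tsv``, and
    ``manifest.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # ---- load --------------------------------------------------------
    stage = "load"
    sizes = read_chrom_sizes(_require(chrom_sizes_path, "chrom.sizes", stage))
    clones = read_clone_table(_require(clones_path, "clone table", stage), sizes)
    repeats = read_repeatmasker_out(_require(repeats_path, "RepeatMasker .out", stage))
    genes = read_gff3_genes(_require(gff3_path, "GFF3 genes", stage))
    inputs = {
        "chrom_sizes": str(chrom_sizes_path),
        "clones": str(clones_path),
        "repeats": str(repeats_path),
        "gff3": str(gff3_path),
    }
    if clusters_bed:
        inputs["clusters_bed"] = str(clusters_bed)

    # ---- trim --------------------------------------------------------
    stage = "trim"
    cosmids, fosmids, yacs = split_clones_by_type(clones)
    if not yacs:
        raise PipelineError(stage, f"no YAC clones in {clones_path}")
    pieces, overlap_stats = derive_exclusive(yacs, cosmids + fosmids)
    overlap_rows = pd.DataFrame(
        {
            "yac_id": list(overlap_stats.per_yac_fraction),
            "overlap_fraction": [overlap_stats.per_yac_fraction[y]
                                 for y in overlap_stats.per_yac_fraction],
        }
    )
    overlap_rows["fully_covered"] = overlap_rows["yac_id"].isin(overlap_stats.fully_covered)
    tables: Dict[str, pd.DataFrame] = {"overlap_stats": overlap_rows}
    write_clone_table(pieces, outdir / "yac_exclusive.tsv")

    # ---- profile -----------------------------------------------------
    stage = "profile"
    index = RepeatIndex(repeats)
    libraries = {"cosmid": cosmids, "fosmid": fosmids, "yac": pieces}
    profiles = {name: profile_library(lib, index)
                for name, lib in libraries.items() if lib}
    summaries = {name: summarize_library(p, name) for name, p in profiles.items()}
    tables["repeat_summary"] = summary_frame(list(summaries.values()))

    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    control_summaries = []
    from .null_model import sample_random_library

    for name, lib in libraries.items():
        if not lib:
            continue
        model = fit_length_model(lib)
        rand = sample_random_library(sizes, model, rng)
        control_summaries.append(
            summarize_library(profile_library(rand, index), f"random_{name}")
        )
    tables["random_controls"] = summary_frame(control_summaries)

    # ---- stratify ----------------------------------------------------
    stage = "stratify"
    q_rows = []
    comparable = {"cosmid": cosmids, "yac": pieces}
    masked_by_stratum: Dict[str, Dict[str, list]] = {}
    for name, lib in comparable.items():
        extreme, middle = split_by_quartile(lib, sizes)
        masked_by_stratum[name] = {}
        for stratum, sub in (("extreme", extreme), ("middle", middle)):
            if not sub:
                continue
            prof = profile_library(sub, index)
            masked = [p.bases_masked_pct for p in prof]
            dna = [p.pct("DNA_transposons") for p in prof]
            masked_by_stratum[name][stratum] = masked
            q_rows.append(
                {
                    "library": name,
                    "stratum": stratum,
                    "n_clones": len(prof),
                    "mean_masked_pct": float(np.mean(masked)),
                    "mean_dna_pct": float(np.mean(dna)),
                }
            )
    all_masked = {
        s: masked_by_stratum["cosmid"].get(s, []) + masked_by_stratum["yac"].get(s, [])
        for s in ("extreme", "middle")
    }
    if len(all_masked["extreme"]) >= 2 and len(all_masked["middle"]) >= 2:
        t, p = welch_t(all_masked["extreme"], all_masked["middle"])
    else:
        t, p = float("nan"), float("nan")
    q_rows.append(
        {
            "library": "all",
            "stratum": "extreme_vs_middle_welch",
            "n_clones": len(all_masked["extreme"]) + len(all_masked["middle"]),
            "mean_masked_pct": t,
            "mean_dna_pct": p,
        }
    )
    tables["quartile_summary"] = pd.DataFrame(q_rows)

    hist_frames = []
    for name, lib in comparable.items():
        if not lib:
            continue
        h = location_histogram(lib, sizes, weight=histogram_weight).to_frame()
        h.insert(0, "library", name)
        hist_frames.append(h)
    rep_clones = [CloneRecord(f"rep{i}", "cosmid", r.interval)
                  for i, r in enumerate(repeats)]
    if rep_clones:
        h = location_histogram(rep_clones, sizes, weight=histogram_weight).to_frame()
        h.insert(0, "library", "repeats")
        hist_frames.append(h)
    tables["location_histograms"] = pd.concat(hist_frames, ignore_index=True)

    len_rows = []
    for name, lib in comparable.items():
        if len(lib) < 2:
            continue
        below, above = split_by_median_length(lib)
        for stratum, sub in (("below_median", below), ("at_or_above_median", above)):
            if not sub:
                continue
            prof = profile_library(sub, index)
            len_rows.append(
                {
                    "library": name,
                    "stratum": stratum,
                    "n_clones": len(prof),
                    "median_length_bp": float(np.median([c.length for c in sub])),
                    "mean_masked_pct": float(np.mean([p.bases_masked_pct for p in prof])),
                    "mean_dna_pct": float(np.mean([p.pct("DNA_transposons") for p in prof])),
                }
            )
    tables["length_split"] = pd.DataFrame(len_rows)

    # ---- genes -------------------------------------------------------
    stage = "genes"
    assignment = assign_genes_to_library(genes, {"cosmid": cosmids,
                                                 "fosmid": fosmids,
                                                 "yac": pieces})
    coverage = {name: library_coverage_by_chrom(lib)
                for name, lib in libraries.items() if lib}
    gene_summaries: Dict[str, GeneLibrarySummary] = {}
    gs_frames = []
    for name in ("cosmid", "fosmid", "yac"):
        if name not in coverage:
            continue
        s = summarize_gene_library(name, assignment[name], sum(coverage[name].values()))
        gene_summaries[name] = s
        frame = s.table.copy()
        frame.insert(0, "library", name)
        frame["ncrna_21u_count"] = s.ncrna_21u_count
        frame["ncrna_21u_pct"] = (
            s.ncrna_21u_fraction_pct if s.ncrna_21u_fraction_pct is not None else float("nan")
        )
        gs_frames.append(frame)
    tables["gene_summary"] = pd.concat(gs_frames, ignore_index=True)

    pc_rows = []
    for name, s in gene_summaries.items():
        for chrom in sorted(s.per_chrom_ncrna):
            pc_rows.append({"library": name, "chrom": chrom,
                            "ncrna_count": s.per_chrom_ncrna[chrom]})
    tables["ncrna_per_chrom"] = pd.DataFrame(pc_rows)

    # chromosome exclusion: the requested chromosome, else the one richest
    # in YAC ncRNAs (the piRNA-cluster chromosome in the default design)
    yac_pc = gene_summaries.get("yac")
    target_chrom = exclude_chrom
    if target_chrom is None and yac_pc is not None and yac_pc.per_chrom_ncrna:
        target_chrom = max(sorted(yac_pc.per_chrom_ncrna),
                           key=lambda c: yac_pc.per_chrom_ncrna[c])
    excl_rows = []
    if target_chrom is not None and "cosmid" in coverage and "yac" in coverage:
        full_counts = {
            name: sum(1 for g in assignment[name] if g.category == "ncRNA")
            for name in ("cosmid", "yac")
        }
        res = exclude_chromosome(
            {n: assignment[n] for n in ("cosmid", "yac")},
            {n: coverage[n] for n in ("cosmid", "yac")},
            target_chrom,
        )
        excl_rows.append(
            {
                "excluded_chrom": target_chrom,
                "cosmid_ncrna_full": full_counts["cosmid"],
                "yac_ncrna_full": full_counts["yac"],
                "cosmid_ncrna_excl": res.counts["cosmid"],
                "yac_ncrna_excl": res.counts["yac"],
                "cosmid_to_yac_ratio_excl": res.ratio if res.ratio is not None else float("nan"),
            }
        )
    tables["chromosome_exclusion"] = pd.DataFrame(excl_rows)

    tables["longest_yacs"] = longest_clones_table(pieces)

    if clusters_bed:
        cluster_rows = []
        with open(clusters_bed) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip() or line.startswith("#"):
                    continue
                f = line.split("\t")
                region = GenomicInterval(f[0], int(f[1]), int(f[2]))
                name = f[3].strip() if len(f) > 3 else f"cluster{lineno}"
                chrom_pct = region_masked_pct(
                    GenomicInterval(region.chrom, 0, sizes[region.chrom]), repeats
                )
                cluster_rows.append(
                    {
                        "region": name,
                        "chrom": region.chrom,
                        "start": region.start,
                        "end": region.end,
                        "masked_pct": region_masked_pct(region, repeats),
                        "chrom_masked_pct": chrom_pct,
                    }
                )
        tables["cluster_repeatness"] = pd.DataFrame(cluster_rows)

    # ---- null tests --------------------------------------------------
    stage = "nulltest"
    ncrna_counter = _MidpointCounter([g for g in genes if g.category == "ncRNA"])
    pirna_counter = _MidpointCounter(
        [g for g in genes if g.category == "ncRNA" and g.is_21u]
    )

    def masked_stat(lib):
        return float(np.mean([p.bases_masked_pct for p in profile_library(lib, index)]))

    def dna_stat(lib):
        return float(np.mean([p.pct("DNA_transposons") for p in profile_library(lib, index)]))

    def _per_mb(counter: _MidpointCounter) -> Callable:
        def stat(lib):
            iset = IntervalSet(c.interval for c in lib).merged()
            return counter.count_in(iset) / (iset.total_bp() / 1e6)
        return stat

    stat_fns = {
        "masked_pct": masked_stat,
        "dna_pct": dna_stat,
        "ncrna_per_mb": _per_mb(ncrna_counter),
        "pirna_per_mb": _per_mb(pirna_counter),
    }
    enr_rows = []
    stage_seeds = np.random.SeedSequence(seed).spawn(1 + len(stat_fns))
    for (stat_name, fn), ss in zip(stat_fns.items(), stage_seeds[1:]):
        sub_seed = int(ss.generate_state(1)[0] % (2**31))
        res = enrichment_test(pieces, fn, sizes, fit_length_model(pieces),
                              replicates=replicates, seed=sub_seed)
        enr_rows.append(
            {
                "statistic": stat_name,
                "observed": res.observed,
                "null_mean": res.null_mean,
                "null_sd": res.null_sd,
                "z": res.z,
                "empirical_p": res.p_value,
                "replicates": res.replicates,
            }
        )
    tables["enrichment"] = pd.DataFrame(enr_rows)

    # ---- write -------------------------------------------------------
    written = write_report(tables, outdir)
    digests = {name: _sha256(path) for name, path in inputs.items()}
    manifest = RunManifest(
        inputs=inputs,
        digests=digests,
        seed=seed,
        version=__version__,
        parameters={
            "replicates": replicates,
            "exclude_chrom": exclude_chrom,
            "histogram_weight": histogram_weight,
        },
    )
    manifest.write(outdir / "manifest.json")
    out = {p.stem: p for p in written}
    out["manifest"] = outdir / "manifest.json"
    out["yac_exclusive"] = outdir / "yac_exclusive.tsv"
    return out
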