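# Methods

This note documents the models, conventions and numerical choices behind
`clonability`, in the spirit of a methods appendix: what is computed, under
which assumptions, and where the design was genuinely open.

## Coordinates and interval algebra

All internal coordinates are 0-based half-open `[start, end)`; readers
convert at the file boundary (RepeatMasker `.out` and GFF3 are 1-based
inclusive, the BED-like clone table and chrom.sizes are native). Interval
sets are kept per chromosome as sorted integer arrays; `merge` produces the
canonical form (sorted, pairwise disjoint, non-adjacent — adjacent
intervals coalesce because the semantics are per-base coverage, not
records). `subtract`, `intersect`, `total_bp` and `overlap_fraction` are
exact integer computations, property-tested against a naive per-base
boolean-bitmap oracle. Cross-chromosome operations are per-chromosome
independent, and all analyses are strand-agnostic.

## YAC trimming

The finished set is the merged union of all cosmid and fosmid intervals;
each YAC is trimmed by interval subtraction. A YAC covered in its interior
yields multiple exclusive pieces, all attributed to the parent clone
(piece ids `Y.1`, `Y.2`, …). Downstream, pieces are units for interval
math but are re-aggregated to the parent for per-clone statistics, so
"number of clones" counts parents and a split YAC contributes one profile
whose length is its total exclusive bp. YACs with overlap fraction 1.0
yield no pieces and are reported in the fully-covered list. YAC–YAC
overlaps are *not* removed by default; `trim --dedupe-yacs` drops YACs
already fully covered by earlier YACs in input order, for libraries where
double-counting matters.

## Repeat profiling

`classify_repeat` maps RepeatMasker class/family strings by their prefix:
LINE/SINE/LTR/Retroposon → retroelements, DNA → DNA transposons (subclass
from the suffix, e.g. PiggyBac), RC → rolling-circles, Unknown/Unspecified
→ unclassified, the small-RNA classes (snRNA, tRNA, rRNA, scRNA, srpRNA) →
small RNA, plus satellites, simple repeats and low complexity. Unmapped
strings fall back to unclassified with a warning; elements are never
dropped. Elements spanning a clone boundary are counted once and clipped —
RepeatMasker run on the clone's own sequence would see only the clipped
part. Category bp is the union of clipped spans; element counts follow
annotation rows (two overlapping same-category rows count twice), matching
RepeatMasker's summary-table semantics. "Bases masked" is the union across
all categories (RepeatMasker's own convention, rather than a sum of
category bp which can double-count overlaps); "total interspersed repeats"
is the union over retroelements, DNA transposons, rolling-circles and
unclassified, i.e. excluding small RNA, satellites, simple repeats and low
complexity. Library summaries report mean, median, min, max and the
non-zero mean (mean over clones with a strictly positive value) of every
per-clone field; fractional element counts in reports are per-clone means
printed to two decimals.

## Matched random libraries and significance

The null for a library statistic is re-sampling: the same number of
clones, lengths drawn from Normal(mean, SD) of the observed library —
truncated by redraw (not clipping) to `[floor, longest chromosome]`, with
floor defaulting to 500 bp to avoid degenerate fragments — chromosome
chosen with probability proportional to its length (genome-uniform
placement), start uniform so the clone fits. Random clones may overlap one
another: no exclusion rule is imposed, and at genome scale the effect on
library statistics is negligible. The empirical p-value uses add-one
smoothing, `p = (1 + #{null ≥ obs}) / (1 + R)`, right-tailed by default
with a two-sided option (doubled smaller tail, capped at 1); a z-score
against the null mean/SD is reported alongside. With R replicates the
smallest attainable p is `1/(R+1)`; calibration (type-I error at the
nominal level under a uniform-feature null) is verified in the test suite
over 500 simulated tests.

## Stratification

Chromosomes are partitioned into four equal quarters; quarters 1 and 4
("extreme", the repeat-rich autosome arms) are summarized together against
quarters 2 and 3 ("middle"). A clone is assigned by the relative position
of its midpoint — containment-based assignment would double-count clones
spanning a boundary — with half-open conventions: p < 0.25 or p ≥ 0.75 is
extreme, so a midpoint exactly at 0.25 is middle. Location histograms bin
relative start positions into 100 percent bins per chromosome and average
the per-chromosome histograms with equal chromosome weight (each
chromosome contributes equally regardless of clone count); length
weighting is available via `--weight length`. The cumulative curve gives,
per percent point, the fraction starting at that point or further. The
median-length split takes the lower middle order statistic for even n;
"below" is strictly less than the median, so a library of equal lengths
degenerates to an empty below-group. Group comparisons use Welch's
unequal-variance t with Welch–Satterthwaite degrees of freedom (clone
libraries have visibly unequal variances, making the pooled-variance
variant inappropriate); both groups constant and equal gives p = 1 by
convention, and the unit of observation is the clone.

## Gene analyses

GFF3 gene-like features become records with category CDS / ncRNA / tRNA /
rRNA / other. The category comes from the `biotype`/`gene_biotype`
attribute when present (protein_coding → CDS, tRNA/rRNA literal, any other
"*RNA*" → ncRNA, else other) and otherwise from the feature type; a
`gene` feature with an mRNA/CDS child is CDS. A gene is a 21U-piRNA when
it is an ncRNA and either its name matches the `21ur-` convention
(case-insensitive) or its biotype is `piRNA`; a 21U-named non-ncRNA is
treated as malformed annotation — warned about and not counted. Genes are
assigned to library territory by interval midpoint (default; `contained`
and `any-overlap` are available). Membership is evaluated per library
independently, so overlapping territories (cosmids vs fosmids) may share a
gene while the disjoint finished vs YAC-exclusive territories never
duplicate one. Densities divide counts by union coverage in Mb; length
statistics use the n−1 SD. The chromosome-exclusion analysis recomputes
counts, densities and the cosmid:YAC ratio over the remaining chromosomes;
`run_all` defaults the excluded chromosome to the one richest in
YAC-library ncRNAs, which in cluster-bearing genomes is the
piRNA-cluster chromosome. piRNA-cluster regions are supplied as a BED file
and summarized by repeat-masked percent against their whole chromosome.

## The synthetic genome

The generator emulates the statistical structure the analysis assumes and
nothing more; its defaults are the package's study conditions:

| parameter | default | meaning |
|---|---|---|
| n_chroms × chrom_length | 5 × 2 Mb | genome scale (minutes on one CPU) |
| gap_fraction | 0.15 | bacteria-unclonable territory per chromosome |
| gap_length_median / sigma | 23.7 kb / 0.6 | lognormal gap lengths (median matches real trimmed-YAC segments) |
| gap_arm_prob | 0.77 | share of gaps placed on extreme quarters |
| cosmid_length_mean / sd | 32.5 kb / 4 kb | tiling-path cosmids, ~2 kb neighbor overlap |
| yac_overlap_mean | 0.07 | mean per-YAC overlapped fraction, Beta(0.5, ·) so individual overlaps range ~0–100% |
| fully_covered_yacs | 3 | YACs planted wholly inside finished territory |
| dna_per_kb_gap / ratio | 0.44 / 2.0 | DNA-transposon element density in gaps vs elsewhere |
| other_repeat_per_kb_middle / arm multiplier | 0.15 / 3.0 | arm enrichment of non-transposon repeats |
| cluster (chrom, span, count) | chrIV, 300 kb, 2000 | piRNA cluster of 21-bp 21U genes inside one gap |
| cluster_repeat_multiplier | 0.4 | repeat suppression inside the cluster ("dense piRNAs in low-repeat sequence") |
| gene densities | 220 CDS/Mb, 100 ncRNA/Mb (40% 21U), tRNA 4.2 vs 1.5 /Mb and rRNA 0.45 vs 0.15 /Mb (gap vs non-gap) | background annotation |

Cosmids tile all non-gap territory wall-to-wall, so trimming recovers each
gap exactly; one YAC bridges each gap with Beta-drawn end extensions into
cosmid territory, clipped so it never reaches a neighboring gap. Feature
tracks are planted with Poisson counts per region and uniform placement,
never crossing region boundaries. A `truth.tsv` records every planted
interval and the realized territory statistics, computed from per-base
bitmaps independently of the package's interval arithmetic — recovery
tests compare the pipeline's output against these. The FASTA is uniform
random A/C/G/T: the pipeline never reads bases, the file exists to
exercise I/O end-to-end.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: realistic repeat sequence content or divergence,
clone-placement noise (synthetic placements are exact, real ones come from
alignment), biases of real annotation pipelines, chromosome-scale
heterogeneity beyond the arm/center dichotomy, and the cloning biology
itself. Tests on the bundle demonstrate that the statistical machinery
recovers planted structure, not that the biological conclusions transfer.

## Determinism and problem sizes

Every stage takes an explicit seed; the pipeline splits one top-level seed
deterministically per stage (`numpy` `SeedSequence.spawn`), reports are
written with fixed column order and 2-decimal float formatting, and a
rerun with identical inputs and seed is byte-identical. Default problem
sizes — a 10-Mb synthetic genome, ~280 cosmids, ~50 YACs, 100–200 null
replicates — were chosen so a full run takes seconds while keeping
per-library statistics stable to a few percent; all are configurable
upward.

## Known limitations

* The resampling null matches clone number and length distribution only;
  GC- or gap-matched covariate nulls are out of scope.
* Empirical p-values are bounded below by 1/(R+1); claims beyond that
  resolution require more replicates.
* Library "total coverage" sums clone lengths and therefore counts
  overlapping cosmid bases twice; gene densities instead use union
  coverage, which is the correct denominator when territories overlap.
* The GFF3 reader handles gene-level features with flat attributes; it is
  not a general-purpose GFF3 validator.
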