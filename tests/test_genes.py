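"""Gene assignment, densities, 21U composition, exclusion and regions."""

import numpy as np
import pytest

from clonability.annotation_io import CloneRecord, GeneRecord, RepeatAnnotation
from clonability.genes import (
    assign_genes_to_library,
    composition_fraction,
    density_per_mb,
    exclude_chromosome,
    gene_length_stats,
    is_21u,
    longest_clones_table,
    region_masked_pct,
)
from clonability.intervals import GenomicInterval


def gene(gid, s, e, category="ncRNA", is21=False, chrom="chrI"):
    return GeneRecord(gid, GenomicInterval(chrom, s, e), category, is21)


def clone(s, e, ctype="cosmid", i="C1", chrom="chrI"):
    return CloneRecord(i, ctype, GenomicInterval(chrom, s, e))


class TestAssignment:
    def test_midpoint_never_duplicates_across_disjoint_libraries(self):
        libs = {"cosmid": [clone(0, 100)], "yac": [clone(100, 200, "yac", "Y1")]}
        # gene straddles the boundary; midpoint at 95 → cosmid
        g = gene("g1", 90, 101, "CDS")
        out = assign_genes_to_library([g], libs)
        assert out["cosmid"] == [g] and out["yac"] == []
        # midpoint at 105 → yac
        g2 = gene("g2", 100, 111, "CDS")
        out = assign_genes_to_library([g2], libs)
        assert out["yac"] == [g2] and out["cosmid"] == []

    def test_uncovered_gene_unassigned(self):
        out = assign_genes_to_library([gene("g", 500, 600, "CDS")], {"cosmid": [clone(0, 100)]})
        assert out["unassigned"] == [gene("g", 500, 600, "CDS")]

    def test_contained_vs_any_overlap(self):
        libs = {"cosmid": [clone(0, 100)]}
        g = gene("g", 90, 150, "CDS")
        assert assign_genes_to_library([g], libs, assign="contained")["cosmid"] == []
        assert assign_genes_to_library([g], libs, assign="any-overlap")["cosmid"] == [g]


class TestIs21U:
    def test_naming_convention(self):
        assert is_21u(gene("21ur-1523", 0, 21))
        assert is_21u(gene("21UR-7", 0, 21))  # case-insensitive
        assert not is_21u(gene("mir-35", 0, 21))

    def test_biotype_flag(self):
        assert is_21u(gene("px-1", 0, 21, is21=True))

    def test_malformed_category_warns_and_declines(self, caplog):
        g = GeneRecord("21ur-9", GenomicInterval("chrI", 0, 75), "tRNA")
        with caplog.at_level("WARNING"):
            assert not is_21u(g)
        assert "21ur-9" in caplog.text


class TestPublishedWorkedExamples:
    """Density/fraction/ratio arithmetic reproduces the printed study numbers."""

    def test_ncrna_densities(self):
        assert round(density_per_mb(10_799, 22_327_861)) == 484
        assert round(density_per_mb(11_108, 77_668_781)) == 143

    def test_trna_rrna_densities(self):
        assert round(density_per_mb(94, 22_327_861), 1) == 4.2
        assert round(density_per_mb(114, 77_668_781), 1) == 1.5
        assert round(density_per_mb(10, 22_327_861), 2) == 0.45

    def test_21u_composition(self):
        assert round(composition_fraction(4_713, 11_108), 1) == 42.4
        assert round(composition_fraction(9_879, 10_799)) == 91

    def test_exclusion_ratio(self):
        assert round(6_182 / 702, 1) == 8.8

    def test_zero_numerators(self):
        assert density_per_mb(0, 1_000_000) == 0.0
        assert composition_fraction(0, 10) == 0.0

    def test_zero_denominators_rejected(self):
        with pytest.raises(ValueError):
            density_per_mb(1, 0)
        with pytest.raises(ValueError):
            composition_fraction(1, 0)


def test_density_homogeneous():
    assert density_per_mb(200, 2_000_000) == density_per_mb(100, 1_000_000)


class TestExcludeChromosome:
    def _fixture(self):
        genes_by_lib = {
            "cosmid": [gene(f"c{i}", 0, 30, chrom="chrI") for i in range(8)]
            + [gene(f"c4_{i}", 0, 30, chrom="chrIV") for i in range(2)],
            "yac": [gene(f"y{i}", 0, 30, chrom="chrIV") for i in range(20)]
            + [gene("y_other", 0, 30, chrom="chrI")],
        }
        coverage = {
            "cosmid": {"chrI": 4_000_000, "chrIV": 4_000_000},
            "yac": {"chrI": 500_000, "chrIV": 500_000},
        }
        return genes_by_lib, coverage

    def test_ratio_flips_when_cluster_chrom_removed(self):
        genes_by_lib, coverage = self._fixture()
        full_yac = sum(1 for g in genes_by_lib["yac"])
        full_cos = sum(1 for g in genes_by_lib["cosmid"])
        assert full_yac > full_cos  # YAC-dominated with the cluster chrom
        res = exclude_chromosome(genes_by_lib, coverage, "chrIV")
        assert res.counts == {"cosmid": 8, "yac": 1}
        assert res.ratio == pytest.approx(8.0)  # cosmid-dominated without it

    def test_excluding_featureless_chrom_changes_nothing(self):
        genes_by_lib, coverage = self._fixture()
        coverage = {k: {**v, "chrX": 1_000} for k, v in coverage.items()}
        res = exclude_chromosome(genes_by_lib, coverage, "chrX")
        assert res.counts == {"cosmid": 10, "yac": 21}

    def test_unknown_chrom_rejected(self):
        genes_by_lib, coverage = self._fixture()
        with pytest.raises(KeyError):
            exclude_chromosome(genes_by_lib, coverage, "chrZ")


class TestRegionMaskedPct:
    def test_extremes(self):
        region = GenomicInterval("chrI", 0, 100)
        assert region_masked_pct(region, []) == 0.0
        full = [RepeatAnnotation(GenomicInterval("chrI", 0, 100), "r", "Satellite")]
        assert region_masked_pct(region, full) == 100.0

    def test_matches_bitmap(self, rng):
        from helpers_bitmap import bitmap, random_pairs

        size = 5_000
        pairs = random_pairs(rng, 40, size)
        anns = [RepeatAnnotation(GenomicInterval("chrI", s, e), "r", "Unknown")
                for s, e in pairs]
        region = GenomicInterval("chrI", 1_000, 4_000)
        want = 100.0 * bitmap(pairs, size)[1_000:4_000].sum() / 3_000
        assert region_masked_pct(region, anns) == pytest.approx(want)


class TestGeneLengthStats:
    def test_single_gene(self):
        assert gene_length_stats([gene("g", 0, 948, "CDS")]) == (1, 948.0, 948.0, 0.0)

    def test_closed_form(self):
        gs = [gene(f"g{i}", 0, ln, "CDS") for i, ln in enumerate((800, 1000, 1200))]
        assert gene_length_stats(gs) == (3, 1000.0, 1000.0, 200.0)

    def test_planted_ncrna_lengths_recovered(self, default_bundle):
        ncrnas = [g for g in default_bundle.genes
                  if g.category == "ncRNA" and not g.is_21u]
        n, mean, median, sd = gene_length_stats(ncrnas)
        # lognormal with the configured median; check median within 2 SE
        se = 1.2533 * sd / np.sqrt(n)
        assert abs(median - default_bundle.config.ncrna_length_median) < 2 * se + 5


def test_exact_pirna_cluster_count_recovery():
    """Counting is exact: a planted cluster of c piRNA genes in YAC-only
    territory yields exactly c YAC-library 21U genes."""
    from clonability.synthetic import SyntheticConfig, generate
    from clonability.trimming import derive_exclusive, split_clones_by_type

    cfg = SyntheticConfig(seed=9, ncrna_per_mb=0.0, cluster_pirna_count=500,
                          write_fasta=False)
    bundle = generate(cfg)
    cos, fos, yacs = split_clones_by_type(bundle.clones)
    pieces, _ = derive_exclusive(yacs, cos + fos)
    out = assign_genes_to_library(
        [g for g in bundle.genes if g.category == "ncRNA"],
        {"finished": cos + fos, "yac": pieces},
    )
    assert sum(1 for g in out["yac"] if is_21u(g)) == 500
    assert sum(1 for g in out["finished"] if is_21u(g)) == 0


def test_longest_clones_table_ranks_by_length():
    clones = [clone(0, ln, "yac", f"Y{ln}") for ln in (100, 5_000, 3_000)]
    t = longest_clones_table(clones, n=2)
    assert list(t["clone_id"]) == ["Y5000", "Y3000"]
    assert list(t["start_1based"]) == [1, 1]
    assert list(t["length_kb"]) == [5, 3]
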