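"""Quartile/length stratification, location histograms and Welch's t."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from clonability.annotation_io import CloneRecord
from clonability.intervals import ChromSizes, GenomicInterval
from clonability.stratify import (
    locate_quartile,
    location_histogram,
    split_by_median_length,
    split_by_quartile,
    welch_t,
)

SIZES = ChromSizes({"chrI": 1_000_000})


def clone(s, e, i="C", chrom="chrI"):
    return CloneRecord(i, "cosmid", GenomicInterval(chrom, s, e))


class TestQuartile:
    @pytest.mark.parametrize(
        "midpoint_pct,expected",
        [(10, "extreme"), (50, "middle"), (80, "extreme"),
         (25, "middle"), (75, "extreme")],  # half-open boundary convention
    )
    def test_midpoint_assignment(self, midpoint_pct, expected):
        mid = midpoint_pct * 10_000
        c = clone(mid - 500, mid + 500)
        assert locate_quartile(c, SIZES) == expected

    def test_partition_is_exhaustive(self, rng):
        clones = [clone(int(s), int(s) + 100, f"c{i}")
                  for i, s in enumerate(rng.integers(0, 999_800, size=200))]
        extreme, middle = split_by_quartile(clones, SIZES)
        assert len(extreme) + len(middle) == len(clones)
        assert not set(c.clone_id for c in extreme) & set(c.clone_id for c in middle)

    def test_clone_past_chrom_end_rejected(self):
        small = ChromSizes({"chrI": 1_000})
        with pytest.raises(ValueError, match="past"):
            locate_quartile(clone(900, 1_100), small)


class TestLocationHistogram:
    def test_all_starting_at_zero(self):
        h = location_histogram([clone(0, 100, f"c{i}") for i in range(5)], SIZES)
        assert h.fractions[0] == 1.0
        assert h.fractions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_single_clone_near_end_cumulative(self):
        h = location_histogram([clone(999_000, 999_500)], SIZES)
        assert h.cumulative[99] == 1.0

    def test_cumulative_monotone_and_uniform_starts_flat(self, rng):
        starts = rng.integers(0, 999_900, size=20_000)
        clones = [clone(int(s), int(s) + 100, f"c{i}") for i, s in enumerate(starts)]
        h = location_histogram(clones, SIZES)
        assert (np.diff(h.cumulative) <= 1e-12).all()
        assert np.allclose(h.fractions, 0.01, atol=0.004)

    def test_equal_chromosome_weighting(self):
        sizes = ChromSizes({"chrI": 1_000_000, "chrII": 1_000_000})
        # 9 clones at the start of chrI, 1 at the end of chrII: equal weight
        clones = [clone(0, 100, f"a{i}") for i in range(9)]
        clones.append(clone(995_000, 996_000, "b", chrom="chrII"))
        h = location_histogram(clones, sizes)
        assert h.fractions[0] == pytest.approx(0.5)
        assert h.fractions[99] == pytest.approx(0.5)


class TestMedianSplit:
    def test_odd_count(self):
        below, above = split_by_median_length(
            [clone(0, 1, "a"), clone(0, 2, "b"), clone(0, 3, "c")]
        )
        assert [c.clone_id for c in below] == ["a"]
        assert sorted(c.clone_id for c in above) == ["b", "c"]

    def test_even_count_uses_lower_middle(self):
        below, above = split_by_median_length(
            [clone(0, n, str(n)) for n in (10, 20, 30, 40)]
        )
        assert [c.length for c in below] == [10]
        assert sorted(c.length for c in above) == [20, 30, 40]

    def test_all_equal_degenerate(self):
        below, above = split_by_median_length([clone(0, 5, str(i)) for i in range(4)])
        assert below == []
        assert len(above) == 4

    def test_generator_hits_target_medians(self):
        from clonability.synthetic import SyntheticConfig, generate
        from clonability.trimming import derive_exclusive, split_clones_by_type

        cfg = SyntheticConfig(seed=6, n_chroms=8, gap_length_sigma=0.3,
                              cluster_span=0, fully_covered_yacs=0,
                              write_fasta=False)
        bundle = generate(cfg)
        cos, fos, yacs = split_clones_by_type(bundle.clones)
        pieces, _ = derive_exclusive(yacs, cos + fos)
        yac_median = np.median([p.length for p in pieces])
        cos_median = np.median([c.length for c in cos])
        assert yac_median == pytest.approx(cfg.gap_length_median, rel=0.05)
        assert cos_median == pytest.approx(cfg.cosmid_length_mean, rel=0.05)


class TestWelchT:
    def test_identical_groups(self):
        t, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_separated_groups(self):
        a = [0.0, 1e-6, -1e-6, 0.0]
        b = [1.0, 1.0 + 1e-6, 1.0 - 1e-6, 1.0]
        _, p = welch_t(a, b)
        assert p < 1e-4

    def test_zero_variance_equal_means(self):
        assert welch_t([2.0, 2.0], [2.0, 2.0]) == (0.0, 1.0)

    @given(
        a=st.lists(st.floats(-50, 50), min_size=3, max_size=20),
        b=st.lists(st.floats(-50, 50), min_size=3, max_size=20),
    )
    def test_matches_reference_implementation(self, a, b):
        if np.var(a) == 0 and np.var(b) == 0:
            return
        t, p = welch_t(a, b)
        ref = sps.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [1.0, 2.0])


def test_arm_enrichment_and_persistence_on_synthetic(default_bundle):
    """Extreme quarters are more repetitive than middle quarters, and the
    YAC > cosmid repetitiveness contrast persists within both strata."""
    from clonability.repeat_summary import RepeatIndex, profile_library
    from clonability.trimming import derive_exclusive, split_clones_by_type

    cos, fos, yacs = split_clones_by_type(default_bundle.clones)
    pieces, _ = derive_exclusive(yacs, cos + fos)
    idx = RepeatIndex(default_bundle.repeats)
    ext, mid = split_by_quartile(cos + pieces, default_bundle.sizes)
    masked_ext = [p.bases_masked_pct for p in profile_library(ext, idx)]
    masked_mid = [p.bases_masked_pct for p in profile_library(mid, idx)]
    t, p = welch_t(masked_ext, masked_mid)
    assert np.mean(masked_ext) > np.mean(masked_mid)
    assert p < 0.01
    cos_ext, cos_mid = split_by_quartile(cos, default_bundle.sizes)
    yac_ext, yac_mid = split_by_quartile(pieces, default_bundle.sizes)
    for cos_part, yac_part in ((cos_ext, yac_ext), (cos_mid, yac_mid)):
        m_c = np.mean([p.bases_masked_pct for p in profile_library(cos_part, idx)])
        m_y = np.mean([p.bases_masked_pct for p in profile_library(yac_part, idx)])
        assert m_y > m_c
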