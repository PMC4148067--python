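"""Repeat classification and per-clone/per-library profiling."""

import numpy as np
import pytest

from clonability.annotation_io import CloneRecord, RepeatAnnotation
from clonability.intervals import GenomicInterval
from clonability.repeat_summary import (
    CATEGORIES,
    RepeatIndex,
    classify_repeat,
    library_mean,
    profile_clone,
    profile_library,
    summarize_library,
)
from helpers_bitmap import bitmap


def ann(s, e, cls, chrom="chrI"):
    return RepeatAnnotation(GenomicInterval(chrom, s, e), "elt", cls)


def clone(s, e, i="C1", chrom="chrI", parent=None):
    return CloneRecord(i, "cosmid", GenomicInterval(chrom, s, e), parent)


class TestClassify:
    @pytest.mark.parametrize(
        "cls,label,sub",
        [
            ("DNA/PiggyBac", "DNA_transposons", "PiggyBac"),
            ("DNA/TcMar-Tc1", "DNA_transposons", "TcMar-Tc1"),
            ("LINE/CR1", "Retroelements", "CR1"),
            ("SINE", "Retroelements", None),
            ("LTR/Gypsy", "Retroelements", "Gypsy"),
            ("RC/Helitron", "Rolling_circles", "Helitron"),
            ("Unknown", "Unclassified", None),
            ("snRNA", "Small_RNA", None),
            ("tRNA", "Small_RNA", None),
            ("Satellite", "Satellites", None),
            ("Simple_repeat", "Simple_repeats", None),
            ("Low_complexity", "Low_complexity", None),
        ],
    )
    def test_mapping(self, cls, label, sub):
        cat = classify_repeat(ann(0, 10, cls))
        assert (cat.label, cat.subclass) == (label, sub)

    def test_unmapped_falls_back_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            assert classify_repeat(ann(0, 10, "FooBar")).label == "Unclassified"
        assert "FooBar" in caplog.text


class TestProfileClone:
    def test_repeat_free_clone_all_zero(self):
        p = profile_clone(clone(0, 1000), RepeatIndex([]))
        assert p.bases_masked_bp == 0
        assert all(p.count[c] == 0 for c in CATEGORIES)

    def test_overlapping_same_category_counts_rows_bp_union(self):
        idx = RepeatIndex([ann(0, 100, "DNA/Tc1"), ann(50, 150, "DNA/Tc1")])
        p = profile_clone(clone(0, 1000), idx)
        assert p.count["DNA_transposons"] == 2
        assert p.bp["DNA_transposons"] == 150
        assert p.pct("DNA_transposons") == pytest.approx(15.0)

    def test_boundary_elements_clipped_once(self):
        idx = RepeatIndex([ann(950, 1100, "Satellite")])
        p = profile_clone(clone(0, 1000), idx)
        assert p.count["Satellites"] == 1
        assert p.bp["Satellites"] == 50

    def test_translation_invariance_of_percents(self):
        anns = [ann(10, 60, "DNA/Tc1"), ann(40, 200, "Satellite")]
        shifted = [ann(10 + 5000, 60 + 5000, "DNA/Tc1"), ann(40 + 5000, 200 + 5000, "Satellite")]
        p0 = profile_clone(clone(0, 1000), RepeatIndex(anns))
        p1 = profile_clone(clone(5000, 6000), RepeatIndex(shifted))
        for c in CATEGORIES:
            assert p0.pct(c) == p1.pct(c)

    def test_bp_matches_bitmap_oracle(self, rng):
        size = 10_000
        classes = ["DNA/Tc1", "LINE/CR1", "Satellite", "Simple_repeat", "Unknown"]
        for _ in range(20):
            anns = []
            for _ in range(50):
                s = int(rng.integers(0, size - 10))
                e = s + int(rng.integers(5, 500))
                anns.append(ann(s, e, classes[int(rng.integers(0, len(classes)))]))
            c = clone(2000, 9000)
            p = profile_clone(c, RepeatIndex(anns))
            for cls_label in set(classify_repeat(a).label for a in anns):
                pairs = [
                    (max(a.interval.start, 2000), min(a.interval.end, 9000))
                    for a in anns
                    if classify_repeat(a).label == cls_label
                    and a.interval.start < 9000 and a.interval.end > 2000
                ]
                want = int(bitmap([p_ for p_ in pairs if p_[0] < p_[1]], size).sum())
                assert p.bp[cls_label] == want
            all_pairs = [
                (max(a.interval.start, 2000), min(a.interval.end, 9000))
                for a in anns if a.interval.start < 9000 and a.interval.end > 2000
            ]
            assert p.bases_masked_bp == int(bitmap(all_pairs, size).sum())

    def test_interspersed_excludes_simple_and_satellites(self):
        idx = RepeatIndex(
            [ann(0, 100, "DNA/Tc1"), ann(200, 300, "Satellite"),
             ann(400, 450, "Simple_repeat"), ann(500, 520, "Low_complexity"),
             ann(600, 700, "Unknown")]
        )
        p = profile_clone(clone(0, 1000), idx)
        assert p.total_interspersed_bp == 200  # DNA + Unclassified only
        assert p.bases_masked_bp == 370
        assert sum(p.bp.values()) >= p.bases_masked_bp


class TestSummarize:
    def test_single_clone_degenerate_stats(self):
        p = profile_clone(clone(0, 1000), RepeatIndex([ann(0, 100, "DNA/Tc1")]))
        s = summarize_library([p], "lib")
        row = s.table.loc["DNA_transposons.pct"]
        assert row["mean"] == row["median"] == row["min"] == row["max"] == 10.0

    def test_nonzero_mean(self):
        idx = RepeatIndex([ann(0, 100, "DNA/Tc1")])
        p1 = profile_clone(clone(0, 1000, "A"), idx)
        p2 = profile_clone(clone(5000, 6000, "B"), idx)
        s = summarize_library([p1, p2], "lib")
        assert s.table.loc["DNA_transposons.pct", "mean"] == pytest.approx(5.0)
        assert s.table.loc["DNA_transposons.pct", "nonzero_mean"] == pytest.approx(10.0)
        assert s.n_clones == 2
        assert s.total_coverage_bp == 2000

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            summarize_library([], "lib")

    def test_pieces_aggregate_to_parent(self):
        idx = RepeatIndex([ann(0, 100, "DNA/Tc1"), ann(900, 1000, "DNA/Tc1")])
        pieces = [clone(0, 500, "Y1.1", parent="Y1"), clone(500, 1000, "Y1.2", parent="Y1")]
        profs = profile_library(pieces, idx)
        assert len(profs) == 1
        assert profs[0].clone_id == "Y1"
        assert profs[0].length_bp == 1000
        assert profs[0].count["DNA_transposons"] == 2
        assert profs[0].bp["DNA_transposons"] == 200


def test_planted_gap_transposon_contrast_recovered():
    """Planted DNA-transposon density d in gaps vs d/2 elsewhere shows up as
    a ~2x YAC:cosmid ratio of mean DNA-transposon percent."""
    from clonability.synthetic import SyntheticConfig, generate
    from clonability.trimming import derive_exclusive, split_clones_by_type

    cfg = SyntheticConfig(seed=5, n_chroms=8, cluster_span=0,
                          fully_covered_yacs=0, write_fasta=False)
    bundle = generate(cfg)
    cosmids, fosmids, yacs = split_clones_by_type(bundle.clones)
    pieces, _ = derive_exclusive(yacs, cosmids + fosmids)
    assert len(pieces) + len(cosmids) >= 200
    idx = RepeatIndex(bundle.repeats)
    s_yac = summarize_library(profile_library(pieces, idx), "yac")
    s_cos = summarize_library(profile_library(cosmids, idx), "cosmid")
    ratio = library_mean(s_yac, "DNA_transposons.pct") / library_mean(
        s_cos, "DNA_transposons.pct"
    )
    assert ratio == pytest.approx(cfg.dna_gap_to_nongap_ratio, rel=0.10)


def test_random_libraries_indistinguishable_under_uniform_annotations(rng):
    """With uniformly placed repeats, YAC-sized and cosmid-sized random
    libraries have statistically indistinguishable masked percentages."""
    from clonability.intervals import ChromSizes
    from clonability.null_model import LengthModel, sample_random_library
    from clonability.stratify import welch_t

    sizes = ChromSizes({"chrI": 2_000_000})
    anns = []
    starts = rng.integers(0, 2_000_000 - 500, size=2000)
    for s in starts:
        anns.append(ann(int(s), int(s) + int(rng.integers(50, 500)), "DNA/Tc1"))
    idx = RepeatIndex(anns)
    g = np.random.default_rng(77)
    yac_like = sample_random_library(sizes, LengthModel(150, 24_000, 6_000), g)
    cos_like = sample_random_library(sizes, LengthModel(300, 33_000, 4_000), g)
    m_yac = [p.bases_masked_pct for p in profile_library(yac_like, idx)]
    m_cos = [p.bases_masked_pct for p in profile_library(cos_like, idx)]
    _, p = welch_t(m_yac, m_cos)
    assert p > 0.01
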