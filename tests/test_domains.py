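import numpy as np
import pandas as pd
import pytest

from mdlseg import (
    Domain,
    LabelRule,
    RegionSet,
    build_domains,
    classify,
    default_label_rules,
    detect_dmrs,
    domains_to_region_set,
    overlap_fraction,
    pelt_segment,
    read_domains,
    region_coverage,
    segment_track,
    select_overlapping,
    write_domains,
)
from mdlseg.changepoint import Segmentation

from conftest import make_track


def regions(*triples):
    rows = [(c, s, e, lab) for c, s, e, *rest in triples for lab in [rest[0] if rest else "."]]
    return RegionSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "label"]))


def seg_from(values, cps):
    values = np.asarray(values, float)
    bounds = [0, *cps, len(values)]
    means = np.array([values[a:b].mean() for a, b in zip(bounds[:-1], bounds[1:])])
    costs = np.array(
        [np.sum((values[a:b] - values[a:b].mean()) ** 2) for a, b in zip(bounds[:-1], bounds[1:])]
    )
    return Segmentation(len(values), np.asarray(cps, np.int64), means, costs, 1.0)


class TestBuildDomains:
    def test_single_segment_chromosome(self):
        track = make_track([100, 200, 300], [9, 8, 10], [10, 10, 10])
        levels = [0.9, 0.8, 1.0]
        doms = build_domains(track, {"chr1": seg_from(levels, [])})
        (d,) = doms
        assert (d.start, d.end, d.n_cpg) == (100, 302, 3)
        assert d.mean_meth == pytest.approx(0.9)

    def test_split_leaves_genomic_gap(self):
        track = make_track([100, 200, 300], [9, 8, 10], [10, 10, 10])
        doms = build_domains(track, {"chr1": seg_from([0.9, 0.8, 1.0], [1])})
        assert [(d.start, d.end, d.n_cpg) for d in doms] == [(100, 102, 1), (200, 302, 2)]

    def test_domains_partition_retained_sites(self, rng):
        n = 500
        total = rng.poisson(10, n) + 1
        meth = rng.binomial(total, 0.7)
        track = make_track(np.cumsum(rng.integers(2, 300, n)), meth, total)
        seg = pelt_segment(track.chroms["chr1"].levels, 0.5)
        doms = build_domains(track, {"chr1": seg})
        assert sum(d.n_cpg for d in doms) == n
        starts = [d.start for d in doms]
        assert starts == sorted(starts)
        assert all(a.end <= b.start for a, b in zip(doms, doms[1:]))

    def test_mismatched_segmentation_length_rejected(self):
        track = make_track([100, 200], [1, 1], [2, 2])
        with pytest.raises(ValueError):
            build_domains(track, {"chr1": seg_from([0.5, 0.5, 0.5], [])})

    def test_left_boundary_penalties_attached(self):
        track = make_track([100, 200, 300], [0, 10, 10], [10, 10, 10])
        doms = build_domains(
            track, {"chr1": seg_from([0.0, 1.0, 1.0], [1])}, {"chr1": {1: 3.2}}
        )
        assert doms[0].max_penalty is None
        assert doms[1].max_penalty == 3.2


class TestClassify:
    def test_large_mid_level_domain_is_pmd_like(self):
        d = Domain("chr1", 0, 12_000, 100, 0.50)
        assert "PMD-like" in classify(d)

    def test_large_low_level_domain_is_dmv_like(self):
        d = Domain("chr1", 0, 6_000, 50, 0.10)
        labels = classify(d)
        assert "DMV-like" in labels and "PMD-like" not in labels

    def test_small_high_level_domain_unlabelled(self):
        assert classify(Domain("chr1", 0, 500, 5, 0.95)) == set()

    def test_labels_may_co_occur(self):
        d = Domain("chr1", 0, 2_000, 20, 0.05)
        assert "UMR-like" in classify(d)

    def test_loosening_a_threshold_never_removes_labels(self):
        d = Domain("chr1", 0, 9_000, 70, 0.60)
        tight = {"PMD-like": LabelRule(size_gt=10_000, meth_lt=0.70)}
        loose = {"PMD-like": LabelRule(size_gt=8_000, meth_lt=0.70)}
        assert classify(d, tight) <= classify(d, loose)


class TestOverlap:
    def test_full_and_half_overlap(self):
        d = Domain("chr1", 0, 100, 5, 0.5)
        assert overlap_fraction(d, regions(("chr1", 0, 100))) == 1.0
        assert overlap_fraction(d, regions(("chr1", 50, 200))) == 0.5
        assert overlap_fraction(d, regions(("chr2", 0, 100))) == 0.0

    def test_matches_per_base_brute_force(self, rng):
        for _ in range(20):
            s = int(rng.integers(0, 5000))
            d = Domain("chr1", s, s + int(rng.integers(1, 2000)), 3, 0.5)
            iv = []
            for _ in range(int(rng.integers(0, 8))):
                a = int(rng.integers(0, 8000))
                iv.append(("chr1", a, a + int(rng.integers(1, 1500))))
            rs = regions(*iv) if iv else regions(("chr2", 0, 1))
            base = np.zeros(10_000, bool)
            for _, a, b in iv:
                base[a:b] = True
            expected = base[d.start : d.end].sum() / d.size
            assert overlap_fraction(d, rs) == pytest.approx(expected)

    def test_selection_is_strictly_above_threshold(self):
        doms = [Domain("chr1", 0, 100, 5, 0.5), Domain("chr1", 200, 300, 5, 0.5)]
        rs = regions(("chr1", 0, 80), ("chr1", 200, 301))
        assert select_overlapping(doms, rs, 0.8) == [doms[1]]

    def test_region_coverage_identical_and_disjoint(self):
        a = regions(("chr1", 0, 100), ("chr2", 50, 150))
        assert region_coverage(a, a) == (1.0, 1.0)
        b = regions(("chr1", 500, 600))
        assert region_coverage(a, b) == (0.0, 0.0)

    def test_region_coverage_matches_per_base_count(self, rng):
        def random_set():
            iv = []
            for _ in range(int(rng.integers(1, 10))):
                s = int(rng.integers(0, 9000))
                iv.append(("chr1", s, s + int(rng.integers(1, 1200))))
            return regions(*iv)

        for _ in range(10):
            a, b = random_set(), random_set()
            mask_a, mask_b = np.zeros(11_000, bool), np.zeros(11_000, bool)
            for row in a.df.itertuples():
                mask_a[row.start : row.end] = True
            for row in b.df.itertuples():
                mask_b[row.start : row.end] = True
            expected = ((mask_a & mask_b).sum() / mask_a.sum(), (mask_a & mask_b).sum() / mask_b.sum())
            got = region_coverage(a, b)
            assert got[0] == pytest.approx(expected[0])
            assert got[1] == pytest.approx(expected[1])


class TestDetectDmrs:
    def test_identical_segmentations_give_nothing(self):
        doms = [Domain("chr1", 0, 1000, 10, 0.9), Domain("chr1", 1000, 2000, 10, 0.1)]
        assert detect_dmrs(doms, doms) == []

    def test_opposite_levels_over_shared_domain(self):
        a = [Domain("chr1", 0, 1000, 10, 0.9)]
        b = [Domain("chr1", 0, 1000, 10, 0.1)]
        (d,) = detect_dmrs(a, b)
        assert (d.chrom, d.start, d.end) == ("chr1", 0, 1000)
        assert d.mean_a == pytest.approx(0.9) and d.mean_b == pytest.approx(0.1)

    def test_shifted_boundary_reports_the_disputed_atom(self):
        a = [Domain("chr1", 0, 1000, 10, 0.9), Domain("chr1", 1000, 2000, 10, 0.1)]
        b = [Domain("chr1", 0, 1500, 15, 0.9), Domain("chr1", 1500, 2000, 5, 0.1)]
        (d,) = detect_dmrs(a, b)
        assert (d.start, d.end) == (1000, 1500)
        assert d.mean_a == pytest.approx(0.1) and d.mean_b == pytest.approx(0.9)

    def test_uncovered_gap_splits_runs(self):
        a = [Domain("chr1", 0, 1000, 10, 0.9), Domain("chr1", 2000, 3000, 10, 0.9)]
        b = [Domain("chr1", 0, 3000, 30, 0.1)]
        out = detect_dmrs(a, b)
        assert [(d.start, d.end) for d in out] == [(0, 1000), (2000, 3000)]


class TestDomainFiles:
    def test_round_trip_with_labels(self, tmp_path, rng):
        track = make_track(np.cumsum(rng.integers(50, 500, 100)), rng.integers(0, 5, 100),
                           np.full(100, 10))
        doms = segment_track(track, 1.0)
        p = tmp_path / "doms.tsv"
        write_domains(doms, p, rules=default_label_rules(), header_lines=["params: test"])
        again = read_domains(p)
        assert [(d.chrom, d.start, d.end, d.n_cpg) for d in again] == [
            (d.chrom, d.start, d.end, d.n_cpg) for d in doms
        ]
        assert np.allclose(
            [d.mean_meth for d in again], [d.mean_meth for d in doms], atol=1e-6
        )

    def test_domains_to_region_set_total(self):
        doms = [Domain("chr1", 0, 100, 2, 0.5), Domain("chr1", 300, 400, 2, 0.5)]
        assert domains_to_region_set(doms).total_bp == 200
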