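import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from poolscan import (
    DataError,
    GenomeLayout,
    ScrRegion,
    build_scr,
    classify_groups,
    combine_within,
    extend_scr,
    make_windows,
    significant_windows,
    ztransform,
)
from poolscan.datasets import OAR6_MERGE_PARTS
from poolscan.window_engine import Window


class TestZtransform:
    def test_unit_spaced_values(self):
        assert ztransform([1.0, 2.0, 3.0]) == pytest.approx([-1.0, 0.0, 1.0])

    def test_constant_vector_rejected(self):
        with pytest.raises(DataError):
            ztransform([2.0, 2.0, 2.0])

    def test_nan_entries_carry_no_z(self):
        z = ztransform([1.0, np.nan, 3.0])
        assert np.isnan(z[1]) and not np.isnan(z[[0, 2]]).any()

    @settings(max_examples=100, deadline=None)
    @given(values=st.lists(st.floats(-1e3, 1e3), min_size=3, max_size=50))
    def test_output_standardized(self, values):
        if len(set(values)) < 2 or np.std(values, ddof=1) == 0.0:
            # constant input (or variance underflow) is rejected, not normalized
            with pytest.raises(DataError):
                ztransform(values)
            return
        z = ztransform(values)
        assert np.mean(z) == pytest.approx(0.0, abs=1e-9)
        assert np.std(z, ddof=1) == pytest.approx(1.0, rel=1e-9)


class TestSignificantWindows:
    @pytest.mark.parametrize("z,direction,expected", [
        (-6.1, "lower", True),
        (-6.0, "lower", False),  # strict inequality at the cut-off
        (6.5, "upper", True),
        (6.0, "upper", False),
        (np.nan, "lower", False),
    ])
    def test_cutoff_semantics(self, z, direction, expected):
        assert significant_windows([z], 6.0, direction)[0] == expected

    @settings(max_examples=50, deadline=None)
    @given(
        zs=st.lists(st.floats(-10, 10), min_size=1, max_size=50),
        t=st.tuples(st.floats(0, 8), st.floats(0, 8)),
    )
    def test_count_monotone_in_threshold(self, zs, t):
        lo, hi = min(t), max(t)
        assert (significant_windows(zs, hi, "lower").sum()
                <= significant_windows(zs, lo, "lower").sum())


class TestCombineWithin:
    @pytest.mark.parametrize("hp,d,mode,expected", [
        ([True], [False], "union", [True]),
        ([True], [False], "intersection", [False]),
        ([True], [True], "union", [True]),
        ([True], [True], "intersection", [True]),
    ])
    def test_modes(self, hp, d, mode, expected):
        assert list(combine_within(hp, d, mode)) == expected

    def test_length_mismatch(self):
        with pytest.raises(DataError):
            combine_within([True], [True, False])


def grid(length=120_000_000, size=200_000, step=50_000, chrom="6"):
    layout = GenomeLayout([chrom], {chrom: length})
    return make_windows(layout, size, step)


def mask_for_spans(windows, spans):
    """Significant iff the window lies inside one of the spans."""
    return [
        any(w.chrom == c and w.start >= s and w.end <= e for c, s, e in spans)
        for w in windows
    ]


class TestBuildScr:
    def test_three_stretch_merge_with_one_and_two_step_gaps(self):
        """Stretches separated by one and two 50-kb steps collapse into a
        single 1.95 Mb region spanning the gaps."""
        windows = grid()
        regions = build_scr(windows, mask_for_spans(windows, OAR6_MERGE_PARTS))
        assert [(r.chrom, r.core_start, r.core_end) for r in regions] == [
            ("6", 36_450_000, 38_400_000)
        ]
        assert regions[0].core_length == 1_950_000

    def test_three_step_gap_keeps_regions_apart(self):
        # non-overlapping windows so span gaps equal index gaps
        windows = grid(length=2_000_000, size=100_000, step=100_000, chrom="1")
        mask = [False] * len(windows)
        mask[2] = True
        mask[6] = True  # 3 non-significant windows between
        regions = build_scr(windows, mask, max_gap_windows=2)
        assert len(regions) == 2

    def test_two_step_gap_merges(self):
        windows = grid(length=2_000_000, size=100_000, step=100_000, chrom="1")
        mask = [False] * len(windows)
        mask[2] = True
        mask[5] = True  # 2 non-significant windows between
        (region,) = build_scr(windows, mask, max_gap_windows=2)
        assert (region.core_start, region.core_end) == (200_000, 600_000)
        assert region.member_indices == (2, 5)  # gap windows are not members

    def test_single_window_region(self):
        windows = grid(length=1_000_000, size=200_000, step=50_000, chrom="1")
        mask = [False] * len(windows)
        mask[4] = True
        (region,) = build_scr(windows, mask)
        assert (region.core_start, region.core_end) == (200_000, 400_000)

    def test_empty_mask_gives_no_regions(self):
        windows = grid(length=1_000_000, chrom="1")
        assert build_scr(windows, [False] * len(windows)) == []

    def test_regions_disjoint_sorted_and_cover_all_significant(self):
        rng = np.random.default_rng(7)
        windows = grid(length=30_000_000, chrom="1")
        mask = rng.random(len(windows)) < 0.05
        regions = build_scr(windows, mask)
        for a, b in zip(regions, regions[1:]):
            assert a.core_end <= b.core_start or a.chrom != b.chrom
        members = sorted(i for r in regions for i in r.member_indices)
        assert members == sorted(np.flatnonzero(mask))

    def test_idempotent_on_own_output(self):
        rng = np.random.default_rng(11)
        windows = grid(length=30_000_000, chrom="1")
        mask = rng.random(len(windows)) < 0.05
        regions = build_scr(windows, mask)
        spans = [(r.chrom, r.core_start, r.core_end) for r in regions]
        again = build_scr(windows, mask_for_spans(windows, spans))
        assert [(r.chrom, r.core_start, r.core_end) for r in again] == spans


class TestExtendScr:
    def layout(self):
        return GenomeLayout(["1"], {"1": 60_000_000})

    def test_flank_added_both_sides(self):
        (r,) = extend_scr([ScrRegion("1", 22_050_000, 22_250_000)], self.layout())
        assert (r.ext_start, r.ext_end) == (21_950_000, 22_350_000)

    def test_clipped_at_chromosome_start(self):
        (r,) = extend_scr([ScrRegion("1", 30_000, 200_000)], self.layout())
        assert r.ext_start == 0

    def test_zero_flank_is_identity(self):
        (r,) = extend_scr([ScrRegion("1", 100_000, 300_000)], self.layout(), flank=0)
        assert (r.ext_start, r.ext_end) == (100_000, 300_000)


class TestClassifyGroups:
    def test_focal_specific_becomes_group_a(self):
        focal = [ScrRegion("4", 1_000_000, 1_400_000)]
        out = classify_groups(focal, [], [], [])
        assert [(r.group, r.chrom) for r in out] == [("A", "4")]

    def test_focal_overlapping_sister_excluded_from_a(self):
        focal = [ScrRegion("6", 1_000_000, 1_400_000)]
        sister = [ScrRegion("6", 1_399_999, 1_600_000)]  # 1 bp overlap
        assert classify_groups(focal, sister, [], []) == []

    def test_sister_overlap_merged_as_group_b(self):
        s1 = [ScrRegion("6", 36_450_000, 37_500_000)]
        s2 = [ScrRegion("6", 37_000_000, 38_400_000)]
        (r,) = classify_groups([], s1, s2, [])
        assert (r.group, r.core_start, r.core_end) == ("B", 36_450_000, 38_400_000)

    def test_identical_sister_cores_give_one_region(self):
        s = [ScrRegion("1", 100_000, 300_000)]
        out = classify_groups([], s, list(s), [])
        assert len(out) == 1 and out[0].group == "B"

    def test_between_scan_regions_are_group_c(self):
        between = [ScrRegion("15", 46_150_000, 46_350_000)]
        s1 = [ScrRegion("15", 46_150_000, 46_350_000)]
        out = classify_groups([], s1, [], between)
        assert [r.group for r in out] == ["C"]
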