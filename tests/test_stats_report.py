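"""Distances, KS comparison, overlap classification, extents, percentages."""

import itertools

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import LineString

from pallidotrace import (
    build_grid,
    center_distances,
    classify_boxes,
    contingency_percentage,
    fit_two_gaussians,
    ks_compare,
    overlap_percentages,
    projection_extent,
)
from pallidotrace.density import DensityGrid
from pallidotrace.trace_io import ValidationError

from conftest import one_trace_dataset


def make_fit(c1, c2, channel="GFP"):
    rng = np.random.default_rng(0)
    pts = np.vstack(
        [
            np.asarray(c1) + 1e-4 * rng.standard_normal((30, 3)),
            np.asarray(c2) + 1e-4 * rng.standard_normal((30, 3)),
        ]
    )
    return fit_two_gaussians(pts, np.ones(len(pts)), channel=channel)


def make_grid(entries, channel="GFP", box_size=0.04):
    """DensityGrid from {(section, row, col): length}."""
    if entries:
        table = pd.DataFrame(
            [
                {"section_index": s, "row": r, "col": c, "length_mm": v}
                for (s, r, c), v in sorted(entries.items())
            ]
        )
    else:
        table = pd.DataFrame(columns=["section_index", "row", "col", "length_mm"])
    return DensityGrid(
        channel=channel, box_size=box_size, origin=(0.0, 0.0), table=table,
        section_ml={0: 1.9},
    )


class TestCenterDistances:
    def test_identical_fits_have_zero_cross_distance(self):
        f = make_fit((-0.35, -3.2, 1.9), (-0.55, -3.4, 1.9))
        d = center_distances(f, f)
        assert d.g1_r1 == 0.0 and d.g2_r2 == 0.0
        assert d.g1_g2 > 0.2

    def test_pythagorean_offset(self):
        a = make_fit((-0.35, -3.2, 1.9), (-0.55, -3.4, 1.9))
        b = make_fit(
            (-0.35 + 0.003, -3.2 + 0.004, 1.9 + 0.012),
            (-0.55 + 0.003, -3.4 + 0.004, 1.9 + 0.012),
        )
        d = center_distances(a, b)
        assert d.g1_r1 == pytest.approx(0.013, abs=1e-4)
        assert d.g2_r2 == pytest.approx(0.013, abs=1e-4)


class TestKsCompare:
    def test_identical_samples(self):
        d, p = ks_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert d == 0.0 and p == 1.0

    def test_fully_separated_triples_match_enumeration(self):
        d, p = ks_compare([0.0, 0.0, 0.0], [1.0, 1.0, 1.0], method="exact")
        assert d == 1.0
        # exhaustive permutation oracle over all C(6,3) assignments
        pooled = [0.0, 0.0, 0.0, 1.0, 1.0, 1.0]
        count = 0
        total = 0
        for idx in itertools.combinations(range(6), 3):
            a = np.sort([pooled[i] for i in idx])
            b = np.sort([pooled[i] for i in range(6) if i not in idx])
            grid = np.concatenate([a, b])
            dd = max(
                abs(np.searchsorted(a, g, side="right") / 3
                    - np.searchsorted(b, g, side="right") / 3)
                for g in grid
            )
            total += 1
            if dd >= 1.0 - 1e-12:
                count += 1
        assert p == pytest.approx(count / total, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_exact_p_matches_enumeration_for_small_samples(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=4)
        b = rng.normal(loc=0.5, size=4)
        d_obs, p = ks_compare(a, b, method="exact")
        pooled = np.concatenate([a, b])
        count = total = 0
        for idx in itertools.combinations(range(8), 4):
            aa = np.sort(pooled[list(idx)])
            bb = np.sort(pooled[[i for i in range(8) if i not in idx]])
            dd = max(
                abs(np.searchsorted(aa, g, side="right") / 4
                    - np.searchsorted(bb, g, side="right") / 4)
                for g in pooled
            )
            total += 1
            if dd >= d_obs - 1e-12:
                count += 1
        assert p == pytest.approx(count / total, abs=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            ks_compare([], [1.0])


class TestClassifyBoxes:
    def test_identical_grids_are_all_both(self):
        g = make_grid({(0, 0, 0): 0.1, (0, 1, 2): 0.2})
        summary = classify_boxes(g, make_grid(g.entries(), channel="RFP"))
        assert summary.percentages()["both"] == 100.0
        assert summary.counts == {"gfp_only": 0, "rfp_only": 0, "both": 2}

    def test_disjoint_grids_have_no_both(self):
        g = make_grid({(0, 0, 0): 0.1})
        r = make_grid({(0, 5, 5): 0.3}, channel="RFP")
        pct = classify_boxes(g, r).percentages()
        assert pct["both"] == 0.0
        assert pct["gfp_only"] + pct["rfp_only"] == pytest.approx(100.0)

    def test_random_grids_match_set_oracle(self):
        rng = np.random.default_rng(3)
        keys = [(0, int(r), int(c)) for r in range(10) for c in range(10)]
        g_keys = {k for k in keys if rng.random() < 0.3}
        r_keys = {k for k in keys if rng.random() < 0.5}
        g = make_grid({k: rng.uniform(0.01, 1) for k in g_keys})
        r = make_grid({k: rng.uniform(0.01, 1) for k in r_keys}, channel="RFP")
        s = classify_boxes(g, r)
        assert s.counts["both"] == len(g_keys & r_keys)
        assert s.counts["gfp_only"] == len(g_keys - r_keys)
        assert s.counts["rfp_only"] == len(r_keys - g_keys)

    def test_presence_threshold_drops_weak_boxes(self):
        g = make_grid({(0, 0, 0): 0.005, (0, 1, 1): 0.1})
        r = make_grid({(0, 1, 1): 0.1}, channel="RFP")
        s = classify_boxes(g, r, presence_threshold=0.01)
        assert s.counts == {"gfp_only": 0, "rfp_only": 0, "both": 1}

    def test_channel_swap_symmetry(self):
        rng = np.random.default_rng(4)
        g = make_grid({(0, r, c): rng.uniform(0.01, 1)
                       for r in range(5) for c in range(5)
                       if rng.random() < 0.4})
        r_ = make_grid({(0, r, c): rng.uniform(0.01, 1)
                        for r in range(5) for c in range(5)
                        if rng.random() < 0.4}, channel="RFP")
        s1 = classify_boxes(g, r_)
        s2 = classify_boxes(r_, g)
        assert s1.counts["both"] == s2.counts["both"]
        assert s1.counts["gfp_only"] == s2.counts["rfp_only"]
        assert s1.counts["rfp_only"] == s2.counts["gfp_only"]

    def test_mismatched_lattice_rejected(self):
        g = make_grid({(0, 0, 0): 0.1})
        r = make_grid({(0, 0, 0): 0.1}, box_size=0.02, channel="RFP")
        with pytest.raises(ValidationError):
            classify_boxes(g, r)

    def test_areas_and_percentage_sum(self):
        g = make_grid({(0, 0, 0): 0.1, (0, 0, 1): 0.1})
        r = make_grid({(0, 0, 1): 0.1, (0, 0, 2): 0.1}, channel="RFP")
        s = classify_boxes(g, r)
        assert sum(s.percentages().values()) == pytest.approx(100.0, abs=1e-9)
        for cls, n in s.counts.items():
            assert s.areas_mm2()[cls] == n * 0.04**2


class TestOverlapPercentages:
    def test_single_mouse_flagged(self):
        g = make_grid({(0, 0, 0): 0.1})
        r = make_grid({(0, 0, 0): 0.1}, channel="RFP")
        out = overlap_percentages([classify_boxes(g, r)])
        assert out["single_mouse"] is True
        assert out["both"]["sd"] == 0.0

    def test_two_mouse_mean_and_sd(self):
        summaries = []
        for frac_both in (2, 3):  # 40% and 60% of 5 boxes
            g = make_grid({(0, 0, c): 0.1 for c in range(5)})
            r = make_grid(
                {(0, 0, c): 0.1 for c in range(frac_both)}
                | {(0, 9, c): 0.1 for c in range(5 - frac_both)},
                channel="RFP",
            )
            summaries.append(classify_boxes(g, r))
        out = overlap_percentages(summaries)
        # both-class percentages per mouse: 2/5 of 8 occupied... compute directly
        p = [s.percentages()["both"] for s in summaries]
        assert out["both"]["mean"] == pytest.approx(np.mean(p))
        assert out["both"]["sd"] == pytest.approx(np.std(p, ddof=1))

    def test_forty_sixty_split_gives_known_sd(self):
        class Stub:
            def __init__(self, both):
                self._p = {"gfp_only": (100 - both) / 2,
                           "rfp_only": (100 - both) / 2, "both": both}

            def percentages(self):
                return self._p

        out = overlap_percentages([Stub(40.0), Stub(60.0)])
        assert out["both"]["mean"] == pytest.approx(50.0)
        assert out["both"]["sd"] == pytest.approx(14.142, abs=1e-3)


class TestProjectionExtent:
    def test_point_like_trace_has_zero_ranges(self):
        ds = one_trace_dataset([[0.0, -3.0], [1e-9, -3.0]])
        ext = projection_extent(ds, "GFP")
        assert ext.rc_range == pytest.approx(0.0, abs=1e-8)
        assert ext.dv_range == pytest.approx(0.0, abs=1e-8)
        assert ext.ml_range == 0.0

    def test_two_vertices_half_millimeter_apart(self):
        ds = one_trace_dataset([[0.0, -3.0], [0.5, -3.0]])
        assert projection_extent(ds, "GFP").rc_range == pytest.approx(0.5)

    def test_no_varicose_fibers_flags_empty(self):
        ds = one_trace_dataset([[0.0, -3.0], [0.5, -3.0]], varicose=False)
        assert projection_extent(ds, "GFP").empty is True

    def test_matches_bruteforce_clipped_minmax(self, small_mouse):
        for ch in ("GFP", "RFP"):
            ext = projection_extent(small_mouse, ch)
            rc, dv, mls = [], [], set()
            by_index = {s.index: s for s in small_mouse.sections}
            for t in small_mouse.traces_for(ch, varicose_only=True):
                poly = by_index[t.section_index].polygon
                inter = LineString(t.points).intersection(poly)
                if inter.is_empty or inter.length == 0:
                    continue
                import shapely

                coords = shapely.get_coordinates(inter)
                rc.extend(coords[:, 0])
                dv.extend(coords[:, 1])
                mls.add(by_index[t.section_index].ml_center)
            assert ext.rc_range == pytest.approx(max(rc) - min(rc), abs=1e-12)
            assert ext.dv_range == pytest.approx(max(dv) - min(dv), abs=1e-12)
            assert ext.ml_range == pytest.approx(max(mls) - min(mls), abs=1e-12)


class TestContingencyPercentage:
    @pytest.mark.parametrize(
        "positive,total,expected",
        [
            (255, 258, 98.8),
            (255, 267, 95.5),
            (99, 104, 95.2),
            (100, 103, 97.1),
            (10, 277, 3.6),
            (0, 10, 0.0),
            (1, 16, 6.3),  # 6.25 rounds half-up, not to even
        ],
    )
    def test_reported_worked_examples(self, positive, total, expected):
        assert contingency_percentage(positive, total) == expected

    def test_zero_total_rejected(self):
        with pytest.raises(ValidationError):
            contingency_percentage(1, 0)
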