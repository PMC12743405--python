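import itertools
import math

import numpy as np
import pandas as pd
import pytest

from spermtopo import presets
from spermtopo.topology import (
    call_repositioning,
    chromocenter_cluster,
    chromocenter_hull_area,
    distance_summary,
    linkage_to_newick,
    summarize_topology,
)

# ---------------------------------------------------------------------------
# independent oracles


def greedy_ward_partition(points: dict[str, tuple[float, float]], k: int):
    """Exhaustive greedy Ward agglomeration oracle (Lance–Williams-free).

    Merges the pair of clusters with the smallest increase in total
    within-cluster sum of squares until k clusters remain.
    """
    clusters = {name: [np.asarray(p, float)] for name, p in points.items()}

    def merge_cost(a, b):
        na, nb = len(clusters[a]), len(clusters[b])
        ca = np.mean(clusters[a], axis=0)
        cb = np.mean(clusters[b], axis=0)
        return na * nb / (na + nb) * float(np.sum((ca - cb) ** 2))

    names = {name: {name} for name in clusters}
    while len(clusters) > k:
        a, b = min(itertools.combinations(clusters, 2), key=lambda ab: merge_cost(*ab))
        clusters[a] = clusters[a] + clusters[b]
        names[a] |= names.pop(b)
        del clusters[b]
    return {frozenset(members) for members in names.values()}


def shoelace_hull_area(points: np.ndarray) -> float:
    """Convex-hull area via monotone chain + shoelace (independent route)."""
    pts = sorted(map(tuple, points))

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    def half(seq):
        out = []
        for p in seq:
            while len(out) >= 2 and cross(out[-2], out[-1], p) <= 0:
                out.pop()
            out.append(p)
        return out

    hull = half(pts)[:-1] + half(reversed(pts))[:-1]
    area = 0.0
    for (x1, y1), (x2, y2) in zip(hull, hull[1:] + hull[:1]):
        area += x1 * y2 - x2 * y1
    return abs(area) / 2.0


# ---------------------------------------------------------------------------


class TestSummarizeTopology:
    @staticmethod
    def _frame(ts, ds, hs, case="K1"):
        return pd.DataFrame(
            {
                "chromosome": "X", "fraction": "raw", "case": case,
                "axial_fraction": ts, "d_over_l": ds, "h_over_l": hs,
            }
        )

    def test_identical_positions_zero_se(self):
        df = self._frame([0.5] * 10, [0.5] * 10, [0.1] * 10)
        with pytest.warns(UserWarning):
            (s,) = summarize_topology(df, ["chromosome", "fraction"])
        assert s.se_d_over_l == 0.0 and s.se_h_over_l == 0.0

    def test_two_signal_se(self):
        # D/L 0.4 and 0.6: mean 0.5, sample SD 0.1414..., SE = SD/sqrt(2) = 0.1
        df = self._frame([0.4, 0.6], [0.4, 0.6], [0.1, 0.1])
        with pytest.warns(UserWarning):
            (s,) = summarize_topology(df, ["chromosome", "fraction"])
        assert s.mean_d_over_l == pytest.approx(0.5)
        assert s.se_d_over_l == pytest.approx(0.1)

    def test_zone_frequencies_match_histogram_oracle(self, rng):
        ts = rng.uniform(0, 1, 900)
        df = self._frame(ts, ts, np.full(900, 0.1))
        (s,) = summarize_topology(df, ["chromosome", "fraction"])
        hist, _ = np.histogram(ts, bins=[0, 1 / 3, 2 / 3, 1.0000001])
        expected = 100.0 * hist / hist.sum()
        assert s.zone_freq_mean == pytest.approx((expected[2], expected[1], expected[0]))

    def test_per_case_zone_mean(self, rng):
        frames = [self._frame(rng.uniform(0, 1, 200), np.full(200, 0.5),
                              np.full(200, 0.1), case=c) for c in ("K1", "K2", "K3")]
        df = pd.concat(frames, ignore_index=True)
        (s,) = summarize_topology(df, ["chromosome", "fraction"])
        per_case = s.per_case_zone_freq
        assert per_case.shape == (3, 3)
        assert s.zone_freq_mean == pytest.approx(tuple(per_case.mean(axis=0)))
        assert sum(s.zone_freq_mean) == pytest.approx(100.0, abs=1e-9)


class TestCallRepositioning:
    @staticmethod
    def _group(rng, n, d_mu=0.5, h_mu=0.15, d_shift=0.0, h_scale=1.0):
        return pd.DataFrame(
            {
                "d_over_l": rng.normal(d_mu, 0.1, n) + d_shift,
                "h_over_l": np.abs(rng.normal(h_mu, 0.04, n)) * h_scale,
            }
        )

    def test_identical_distributions_none(self, rng):
        a = self._group(rng, 200)
        b = a.copy()
        call = call_repositioning({"raw": a, "SU": b}, ("raw", "SU"))
        assert call.direction == "none"

    def test_d_shift_called_apical(self, rng):
        a = self._group(rng, 200)
        b = a.copy()
        b["d_over_l"] += 0.2
        call = call_repositioning({"raw": a, "SU": b}, ("raw", "SU"))
        assert call.direction == "basal-apical"
        assert call.p_d < 0.05

    def test_h_scale_called_periphery(self, rng):
        a = self._group(rng, 200)
        b = a.copy()
        b["h_over_l"] *= 1.5
        call = call_repositioning({"raw": a, "SU": b}, ("raw", "SU"))
        assert call.direction == "center-periphery"
        assert call.p_h < 0.05

    def test_both_axes(self, rng):
        a = self._group(rng, 300)
        b = a.copy()
        b["d_over_l"] += 0.2
        b["h_over_l"] *= 1.6
        call = call_repositioning({"raw": a, "SU": b}, ("raw", "SU"))
        assert call.direction == "both"

    def test_three_group_dunn_path(self, rng):
        groups = {
            "raw": self._group(rng, 150),
            "SU": self._group(rng, 150, d_shift=0.15),
            "DGC": self._group(rng, 150),
        }
        call = call_repositioning(groups, ("raw", "SU"))
        assert call.direction == "basal-apical"
        null_call = call_repositioning(groups, ("raw", "DGC"))
        assert null_call.direction == "none"

    def test_degenerate_tied(self):
        a = pd.DataFrame({"d_over_l": [0.5] * 5, "h_over_l": [0.1] * 5})
        with pytest.warns(UserWarning, match="tied"):
            call = call_repositioning({"raw": a, "SU": a.copy()}, ("raw", "SU"))
        assert call.direction == "none"

    def test_type_i_error_calibration(self):
        # A, B from the same distribution: non-"none" rate ~ alpha
        rng = np.random.default_rng(99)
        alpha, reps = 0.05, 500
        false_calls = 0
        for _ in range(reps):
            a = self._group(rng, 100)
            b = self._group(rng, 100)
            if call_repositioning({"A": a, "B": b}, ("A", "B")).direction != "none":
                false_calls += 1
        rate = false_calls / reps
        # two independent axis tests at alpha each -> family rate <= 2*alpha
        upper = 2 * alpha + 3 * math.sqrt(2 * alpha * (1 - 2 * alpha) / reps)
        assert rate <= upper
        assert rate >= alpha / 4  # not trivially silent either


class TestChromocenterCluster:
    @pytest.mark.parametrize("fraction", ["raw", "SU", "DGC"])
    def test_published_partitions(self, fraction):
        k, expected = presets.CHROMOCENTER_PARTITION[fraction]
        part = chromocenter_cluster(presets.radial_points(fraction), k)
        assert set(part.clusters) == set(expected)

    @pytest.mark.parametrize("fraction", ["raw", "SU", "DGC"])
    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_matches_greedy_ward_oracle(self, fraction, k):
        points = presets.radial_points(fraction)
        part = chromocenter_cluster(points, k)
        assert set(part.clusters) == greedy_ward_partition(points, k)

    def test_k1_and_kn_limits(self):
        points = presets.radial_points("raw")
        assert chromocenter_cluster(points, 1).clusters == (frozenset(points),)
        singles = chromocenter_cluster(points, len(points)).clusters
        assert set(singles) == {frozenset({c}) for c in points}

    def test_merge_heights_nondecreasing(self):
        part = chromocenter_cluster(presets.radial_points("SU"), 3)
        heights = part.merge_heights
        assert (np.diff(heights) >= -1e-12).all()

    def test_coincident_points_merge_at_zero(self):
        part = chromocenter_cluster({"a": (0.5, 0.1), "b": (0.5, 0.1), "c": (0.9, 0.3)}, 2)
        assert part.merge_heights[0] == pytest.approx(0.0, abs=1e-12)
        assert frozenset({"a", "b"}) in part.clusters

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            chromocenter_cluster({"a": (0, 0), "b": (1, 1)}, 3)

    def test_newick_well_formed(self):
        part = chromocenter_cluster(presets.radial_points("raw"), 3)
        nwk = part.newick
        assert nwk.endswith(";")
        assert nwk.count("(") == nwk.count(")") == len(part.labels) - 1
        for label in part.labels:
            assert label in nwk

    def test_newick_parseable_and_heights_consistent(self):
        # leaf depth from the root equals the root merge height
        from io import StringIO

        from skbio import TreeNode

        part = chromocenter_cluster(presets.radial_points("raw"), 3)
        tree = TreeNode.read(StringIO(part.newick))
        root_height = part.merge_heights[-1]
        for tip in tree.tips():
            assert tip.distance(tree) == pytest.approx(root_height, rel=1e-4)


class TestHullArea:
    def test_unit_right_triangle(self):
        area = chromocenter_hull_area({"a": (0, 0), "b": (1, 0), "c": (0, 1)})
        assert area == pytest.approx(0.5)

    def test_translation_invariance(self, rng):
        pts = {str(i): tuple(p) for i, p in enumerate(rng.uniform(0, 1, (7, 2)))}
        shifted = {k: (x + 5.0, y - 3.0) for k, (x, y) in pts.items()}
        assert chromocenter_hull_area(pts) == pytest.approx(chromocenter_hull_area(shifted))

    @pytest.mark.parametrize("fraction", ["raw", "SU", "DGC"])
    @pytest.mark.parametrize("mirror", [False, True])
    def test_matches_shoelace_oracle(self, fraction, mirror):
        points = presets.radial_points(fraction)
        pts = np.array(list(points.values()))
        if mirror:
            pts = np.vstack([pts, pts * [1, -1]])
        assert chromocenter_hull_area(points, include_mirror=mirror) == pytest.approx(
            shoelace_hull_area(pts), abs=1e-9
        )

    def test_collinear_warns_zero(self):
        with pytest.warns(UserWarning, match="collinear"):
            area = chromocenter_hull_area({"a": (0, 0), "b": (1, 1), "c": (2, 2)})
        assert area == 0.0

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            chromocenter_hull_area({"a": (0, 0), "b": (1, 1)})


class TestDistanceSummary:
    @staticmethod
    def _table(means: dict[str, float], n=150, sd=0.3, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for fraction, mu in means.items():
            rows.append(
                pd.DataFrame(
                    {
                        "pair": "4-8", "fraction": fraction,
                        "distance_um": rng.normal(mu, sd, n),
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def test_printed_fold_changes_from_exact_means(self):
        # exact constructed samples with the printed means
        df = pd.concat(
            [
                pd.DataFrame({"pair": "4-8", "fraction": f, "distance_um": [m] * 100})
                for f, m in (("raw", 1.888), ("DGC", 2.184))
            ],
            ignore_index=True,
        )
        out = distance_summary(df)
        dgc = out[out["fraction"] == "DGC"].iloc[0]
        assert dgc["fold_vs_raw_2dp"] == 1.16

    def test_identical_groups_fold_one(self):
        df = self._table({"raw": 2.0, "SU": 2.0})
        out = distance_summary(df)
        su = out[out["fraction"] == "SU"].iloc[0]
        assert su["fold_vs_raw_2dp"] == pytest.approx(1.0, abs=0.05)

    def test_mean_and_se(self, rng):
        vals = rng.normal(1.9, 0.3, 200)
        df = pd.DataFrame({"pair": "7-9", "fraction": "raw", "distance_um": vals})
        out = distance_summary(df)
        row = out.iloc[0]
        assert row["mean_um"] == pytest.approx(vals.mean())
        assert row["se_um"] == pytest.approx(vals.std(ddof=1) / math.sqrt(200))

    def test_low_n_warning(self):
        df = self._table({"raw": 2.0}, n=10)
        with pytest.warns(UserWarning, match="only 10"):
            distance_summary(df)
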