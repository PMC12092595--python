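"""Nearest-focal distances, medians, ranking and condition statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from isgt import (
    TissueSimSpec,
    compare_conditions,
    median_distance_by_type,
    nearest_focal_distances,
    pearson_correlation,
    rank_neighbors,
    simulate_cohort,
    simulate_tissue,
)


def _frame(points, types, sample="s1", condition="d"):
    """points: list of (x, y); types: parallel list of type names."""
    n = len(points)
    ids = [f"{sample}_c{i}" for i in range(n)]
    smap = pd.DataFrame(
        {
            "cell_id": ids,
            "x_um": [p[0] for p in points],
            "y_um": [p[1] for p in points],
            "sample_id": sample,
        }
    )
    cells = pd.DataFrame(
        {
            "cell_id": ids,
            "sample_id": sample,
            "condition": condition,
            "cell_type": types,
            "lineage": ["lymphocyte" if t in ("ISG-T", "Tn") else "non_lymphocyte" for t in types],
            "is_T": [t in ("ISG-T", "Tn") for t in types],
        }
    )
    return smap, cells


class TestNearestFocalDistances:
    def test_three_four_five_triangle(self):
        smap, cells = _frame([(0, 0), (3, 4), (10, 0)], ["Tn", "ISG-T", "ISG-T"])
        rec, skipped = nearest_focal_distances(smap, cells, "ISG-T")
        assert skipped == []
        assert rec["d_min_um"].iloc[0] == pytest.approx(5.0)

    def test_colocated_cell_has_zero_distance(self):
        smap, cells = _frame([(2, 2), (2, 2)], ["pDC", "ISG-T"])
        rec, _ = nearest_focal_distances(smap, cells, "ISG-T")
        assert rec["d_min_um"].iloc[0] == 0.0

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(0)
        n, m = 1000, 50
        pts = rng.uniform(0, 500, size=(n, 2))
        types = np.array(["other"] * n, dtype=object)
        types[rng.choice(n, m, replace=False)] = "ISG-T"
        smap, cells = _frame([tuple(p) for p in pts], list(types))
        rec, _ = nearest_focal_distances(smap, cells, "ISG-T")

        focal = pts[types == "ISG-T"]
        expect = {}
        for cid, p, t in zip(smap["cell_id"], pts, types):
            if t == "ISG-T":
                continue
            best = np.inf
            for q in focal:
                best = min(best, np.hypot(p[0] - q[0], p[1] - q[1]))
            expect[cid] = best
        got = rec.set_index("cell_id")["d_min_um"]
        for cid, d in expect.items():
            assert got[cid] == pytest.approx(d, rel=1e-9)

    def test_samples_without_focal_cells_skipped(self):
        s1, c1 = _frame([(0, 0), (1, 1)], ["pDC", "ISG-T"], sample="s1")
        s2, c2 = _frame([(5, 5), (6, 6)], ["pDC", "Tn"], sample="s2")
        smap = pd.concat([s1, s2], ignore_index=True)
        cells = pd.concat([c1, c2], ignore_index=True)
        rec, skipped = nearest_focal_distances(smap, cells, "ISG-T")
        assert skipped == ["s2"]
        assert set(rec["sample_id"]) == {"s1"}

    def test_absent_focal_type_rejected(self):
        smap, cells = _frame([(0, 0)], ["pDC"])
        with pytest.raises(ValueError, match="absent"):
            nearest_focal_distances(smap, cells, "ISG-T")

    def test_sample_isolation(self):
        """Adding a new sample never changes another sample's records."""
        s1, c1 = _frame([(0, 0), (3, 4), (50, 50)], ["pDC", "ISG-T", "Tn"], sample="s1")
        rec_before, _ = nearest_focal_distances(s1, c1, "ISG-T")
        s2, c2 = _frame([(0.1, 0.1), (1, 1)], ["pDC", "ISG-T"], sample="s2")
        rec_after, _ = nearest_focal_distances(
            pd.concat([s1, s2], ignore_index=True),
            pd.concat([c1, c2], ignore_index=True),
            "ISG-T",
        )
        a = rec_before.set_index("cell_id")["d_min_um"]
        b = rec_after[rec_after["sample_id"] == "s1"].set_index("cell_id")["d_min_um"]
        pd.testing.assert_series_equal(a.sort_index(), b.sort_index())

    def test_scale_equivariance_and_rigid_invariance(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(0, 100, size=(60, 2))
        types = ["ISG-T" if i % 5 == 0 else "pDC" for i in range(60)]
        smap, cells = _frame([tuple(p) for p in pts], types)
        base, _ = nearest_focal_distances(smap, cells, "ISG-T")
        base = base.set_index("cell_id")["d_min_um"]

        c = 3.7
        scaled = smap.assign(x_um=smap["x_um"] * c, y_um=smap["y_um"] * c)
        rec_s, _ = nearest_focal_distances(scaled, cells, "ISG-T")
        np.testing.assert_allclose(
            rec_s.set_index("cell_id")["d_min_um"].loc[base.index], base * c, atol=1e-9
        )

        theta = 0.83
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        xy = smap[["x_um", "y_um"]].to_numpy() @ rot.T + np.array([12.0, -44.0])
        moved = smap.assign(x_um=xy[:, 0], y_um=xy[:, 1])
        rec_r, _ = nearest_focal_distances(moved, cells, "ISG-T")
        np.testing.assert_allclose(
            rec_r.set_index("cell_id")["d_min_um"].loc[base.index], base, atol=1e-9
        )


class TestMedians:
    def _records(self, rows):
        return pd.DataFrame(
            rows, columns=["cell_id", "sample_id", "condition", "cell_type", "lineage", "d_min_um"]
        )

    def test_simple_median(self):
        rec = self._records(
            [[f"c{i}", "s1", "d", "pDC", "non_lymphocyte", v] for i, v in enumerate([1.0, 2.0, 3.0])]
        )
        med = median_distance_by_type(rec, "pooled_cells")
        assert med.loc[med["cell_type"] == "pDC", "median_d_um"].iloc[0] == 2.0

    def test_median_of_sample_medians(self):
        rows = [["a", "s1", "d", "pDC", "non_lymphocyte", 1.0],
                ["b", "s1", "d", "pDC", "non_lymphocyte", 1.0],
                ["c", "s1", "d", "pDC", "non_lymphocyte", 9.0],
                ["d", "s2", "d", "pDC", "non_lymphocyte", 3.0]]
        med = median_distance_by_type(self._records(rows), "median_of_sample_medians")
        # sample medians {1, 3} -> 2
        assert med["median_d_um"].iloc[0] == 2.0
        assert med["n"].iloc[0] == 2  # n counts samples under this pooling

    def test_both_poolings_match_brute_force(self):
        rng = np.random.default_rng(8)
        rows = []
        for i in range(300):
            rows.append([f"c{i}", f"s{rng.integers(3)}", "d",
                         rng.choice(["pDC", "Tn", "EC"]), "non_lymphocyte",
                         float(rng.exponential(50))])
        rec = self._records(rows)
        pooled = median_distance_by_type(rec, "pooled_cells").set_index("cell_type")
        sm = median_distance_by_type(rec, "median_of_sample_medians").set_index("cell_type")
        for t, g in rec.groupby("cell_type"):
            assert pooled.loc[t, "median_d_um"] == float(np.median(g["d_min_um"]))
            expected = float(np.median([np.median(x["d_min_um"]) for _, x in g.groupby("sample_id")]))
            assert sm.loc[t, "median_d_um"] == expected


class TestRankNeighbors:
    def test_closest_type_is_rank_one(self):
        med = pd.DataFrame(
            {
                "cell_type": ["EC", "pDC"],
                "lineage": ["non_lymphocyte", "non_lymphocyte"],
                "median_d_um": [40.0, 10.0],
                "n": [5, 5],
            }
        )
        net = rank_neighbors(med, "ISG-T")
        assert net.closest("non_lymphocyte") == "pDC"
        assert net.graph.has_edge("ISG-T", "pDC")
        assert net.graph["ISG-T"]["pDC"]["rank"] == 1

    def test_tie_broken_by_name_and_flagged(self):
        med = pd.DataFrame(
            {
                "cell_type": ["FIB", "EC"],
                "lineage": ["non_lymphocyte"] * 2,
                "median_d_um": [10.0, 10.0],
                "n": [5, 5],
            }
        )
        net = rank_neighbors(med, "ISG-T")
        assert net.closest("non_lymphocyte") == "EC"  # name order
        assert net.table["tied"].all()

    def test_attraction_recovered_per_sample(self):
        """pDC parents at sigma=30: pDC is the rank-1 non-lymphocyte
        neighbor of ISG-T in >= 9 of 10 simulated disease samples."""
        smap, cells = simulate_cohort(
            {"disease": TissueSimSpec(attraction_sigma_um=30.0)}, 10, base_seed=17
        )
        wins = 0
        for sid in cells["sample_id"].unique():
            rec, _ = nearest_focal_distances(
                smap[smap["sample_id"] == sid], cells[cells["sample_id"] == sid], "ISG-T"
            )
            med = median_distance_by_type(rec, "pooled_cells")
            net = rank_neighbors(med, "ISG-T")
            wins += net.closest("non_lymphocyte") == "pDC"
        assert wins >= 9

    def test_median_distance_monotone_in_sigma(self):
        """Pooled median pDC distance strictly increases over
        sigma in {10, 30, 100, 300} um (perfect Spearman ordering)."""
        meds = []
        for sigma in (10.0, 30.0, 100.0, 300.0):
            smap, cells = simulate_cohort(
                {"d": TissueSimSpec(attraction_sigma_um=sigma)}, 5, base_seed=23
            )
            rec, _ = nearest_focal_distances(smap, cells, "ISG-T")
            med = median_distance_by_type(rec, "pooled_cells").set_index("cell_type")
            meds.append(med.loc["pDC", "median_d_um"])
        assert np.all(np.diff(meds) > 0)


class TestCompareConditions:
    def test_identical_groups_anova_f_zero(self):
        res = compare_conditions({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]}, "anova_tukey")
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)
        assert np.allclose(res.pairwise["p-adj"].astype(float), 1.0, atol=1e-3)

    def test_anova_matches_closed_form(self):
        """{1,2,3},{4,5,6},{7,8,9}: SSB=54, SSW=6 -> F=27; for F(2,6),
        p = (1 + 2F/6)^-3 = 0.001 exactly."""
        res = compare_conditions(
            {"a": [1, 2, 3], "b": [4, 5, 6], "c": [7, 8, 9]}, "anova_tukey"
        )
        assert res.statistic == pytest.approx(27.0, abs=1e-8)
        assert res.p_value == pytest.approx(0.001, abs=1e-8)

    def test_tukey_matches_studentized_range(self):
        """Tukey adjusted p for each pair equals the studentized-range
        tail probability at q = |diff| / sqrt(MSW/n)."""
        groups = {"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0], "c": [7.0, 8.0, 9.0]}
        res = compare_conditions(groups, "anova_tukey")
        msw = 1.0  # SSW=6 over df=6
        for _, row in res.pairwise.iterrows():
            q = abs(float(row["meandiff"])) / np.sqrt(msw / 3.0)
            expected = stats.studentized_range.sf(q, k=3, df=6)
            assert float(row["p-adj"]) == pytest.approx(expected, abs=1e-3)

    def test_mann_whitney_exact_small_sample(self):
        """Fully separated {1,2,3} vs {4,5,6}: U=0, exact two-sided
        p = 2/C(6,3) = 0.1."""
        res = compare_conditions({"a": [1, 2, 3], "b": [4, 5, 6]}, "mann_whitney")
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(0.1, abs=1e-8)

    def test_welch_t_matches_hand_computation(self):
        """{1,2,3,4} vs {2,4,6,8}: t = -1.5/sqrt(25/48)... computed from
        first principles with the Welch-Satterthwaite df and the
        incomplete-beta t tail."""
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([2.0, 4.0, 6.0, 8.0])
        v1, v2 = a.var(ddof=1) / 4, b.var(ddof=1) / 4
        t_hand = (a.mean() - b.mean()) / np.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1 ** 2 / 3 + v2 ** 2 / 3)
        p_hand = special.betainc(df / 2, 0.5, df / (df + t_hand ** 2))
        res = compare_conditions({"a": a, "b": b}, "welch_t")
        assert res.statistic == pytest.approx(t_hand, abs=1e-8)
        assert res.p_value == pytest.approx(p_hand, abs=1e-8)

    def test_wilcoxon_rank_sum_matches_normal_approximation(self):
        """{1,2,3} vs {4,5,6}: rank sum 6, E=10.5, Var=5.25 ->
        z = -4.5/sqrt(5.25); p = erfc(|z|/sqrt(2))."""
        z = -4.5 / np.sqrt(5.25)
        p_hand = special.erfc(abs(z) / np.sqrt(2))
        res = compare_conditions({"a": [1, 2, 3], "b": [4, 5, 6]}, "wilcoxon")
        assert res.statistic == pytest.approx(z, abs=1e-8)
        assert res.p_value == pytest.approx(p_hand, abs=1e-8)

    def test_pearson_on_exact_line(self):
        x = np.arange(1.0, 6.0)
        r, p = pearson_correlation(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p < 1e-8

    def test_degenerate_groups_reported_missing(self):
        res = compare_conditions({"a": [2.0, 2.0], "b": [2.0, 2.0]}, "welch_t")
        assert np.isnan(res.p_value)
        assert "degenerate" in res.note

    def test_two_group_test_rejects_three_groups(self):
        with pytest.raises(ValueError, match="two groups"):
            compare_conditions({"a": [1, 2], "b": [3, 4], "c": [5, 6]}, "welch_t")

    def test_condition_separation_direction(self):
        """Uniform control cohorts sit >= 2x farther from pDC than
        attracted (sigma=30) disease cohorts."""
        smap, cells = simulate_cohort(
            {
                "disease": TissueSimSpec(attraction_sigma_um=30.0),
                "control": TissueSimSpec(attraction_sigma_um=np.inf),
            },
            5,
            base_seed=31,
        )
        rec, _ = nearest_focal_distances(smap, cells, "ISG-T")
        med = median_distance_by_type(rec, "pooled_cells", by_condition=True)
        pdc = med[med["cell_type"] == "pDC"].set_index("condition")["median_d_um"]
        assert pdc["control"] >= 2 * pdc["disease"]
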