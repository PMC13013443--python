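"""Grade shares, upgrade rates, bypass premiums, bootstrap differentials
and the passive/active premium decomposition."""

import numpy as np
import pandas as pd
import pytest

from flowscope.grade_bypass import (
    bootstrap_differentials,
    bypass_premium,
    channel_differentials,
    grade_bypass_edge_table,
    grade_share,
    min_same_grade_distance,
    premium_decomposition,
    upgrade_rate,
    weighted_bootstrap_ci,
)
from flowscope.network_builder import FlowNetwork, ImpedanceMatrix


def edges_frame(rows):
    return pd.DataFrame(
        rows, columns=["channel", "weight", "g_origin", "g_dest", "excess_km"]
    )


class TestGradeShare:
    def test_all_tertiary(self):
        e = edges_frame([("intra", 10, 1, 3, 0.0), ("intra", 5, 2, 3, 1.0)])
        assert grade_share(e, "intra") == {1: 0.0, 2: 0.0, 3: 1.0}

    def test_hand_mix_sums_to_one(self):
        e = edges_frame(
            [("intra", 47, 1, 1, 0), ("intra", 26, 1, 2, 0), ("intra", 27, 1, 3, 0)]
        )
        s = grade_share(e, "intra")
        assert s == pytest.approx({1: 0.47, 2: 0.26, 3: 0.27})
        assert sum(s.values()) == pytest.approx(1.0)


class TestUpgradeRate:
    def test_extremes(self):
        up = edges_frame([("inter", 7, 1, 3, 0)])
        same = edges_frame([("inter", 7, 2, 2, 0)])
        assert upgrade_rate(up, "inter") == 1.0
        assert upgrade_rate(same, "inter") == 0.0

    def test_hand_count(self):
        e = edges_frame(
            [
                ("intra", 1, 1, 2, 0),
                ("intra", 1, 1, 3, 0),
                ("intra", 1, 2, 3, 0),
                ("intra", 1, 2, 2, 0),
                ("intra", 1, 3, 1, 0),
            ]
        )
        assert upgrade_rate(e, "intra") == pytest.approx(0.6)


class TestMinSameGradeDistance:
    def make_R(self):
        r = np.array([[5.0, 8.0, 2.0, 4.0]])
        return ImpedanceMatrix(
            r=r, d=r, tau=np.ones_like(r), unit_ids=np.array([0]),
            hospital_ids=np.array([0, 1, 2, 3]),
        )

    def test_minimum_per_grade(self):
        R = self.make_R()
        grades = {0: 3, 1: 3, 2: 1, 3: 2}
        r_star = min_same_grade_distance(R, grades)
        assert r_star[0].tolist() == [2.0, 4.0, 5.0]

    def test_missing_grade_flagged_nan(self):
        R = self.make_R()
        r_star = min_same_grade_distance(R, {0: 3, 1: 3, 2: 3, 3: 3})
        assert np.isnan(r_star[0, 0]) and np.isnan(r_star[0, 1])
        assert r_star[0, 2] == 2.0

    def test_adding_hospital_never_increases(self):
        R = self.make_R()
        grades = {0: 3, 1: 3, 2: 1, 3: 2}
        base = min_same_grade_distance(R, grades)
        r2 = np.array([[5.0, 8.0, 2.0, 4.0, 1.0]])
        R2 = ImpedanceMatrix(
            r=r2, d=r2, tau=np.ones_like(r2), unit_ids=np.array([0]),
            hospital_ids=np.array([0, 1, 2, 3, 4]),
        )
        bigger = min_same_grade_distance(R2, {**grades, 4: 3})
        assert np.all(bigger[0] <= base[0] + 1e-12)


class TestBypassPremium:
    def test_single_edge_arithmetic(self):
        e = edges_frame([("inter", 1, 1, 3, 6.0)])
        assert bypass_premium(e, "inter", 3) == 6.0

    def test_weighted_mean(self):
        e = edges_frame([("inter", 3, 1, 3, 2.0), ("inter", 1, 1, 3, 6.0)])
        assert bypass_premium(e, "inter", 3) == pytest.approx(3.0)

    def test_nearest_choice_gives_zero(self):
        e = edges_frame([("intra", 5, 1, 2, 0.0), ("intra", 2, 1, 2, 0.0)])
        assert bypass_premium(e, "intra", 2) == 0.0


class TestChannelDifferentials:
    def test_identical_channels_zero(self):
        rows = [("inter", 5, 1, 3, 2.0), ("inter", 3, 2, 2, 1.0),
                ("intra", 5, 1, 3, 2.0), ("intra", 3, 2, 2, 1.0)]
        d = channel_differentials(edges_frame(rows))
        for name, v in d.items():
            if name == "d_bp_1":  # no grade-1 flow in either channel
                assert np.isnan(v)
            else:
                assert v == pytest.approx(0.0)

    def test_printed_table_arithmetic(self):
        # intra: UR 0.447, tertiary share 0.268; inter: UR 0.654, share 0.534
        intra = [
            ("intra", 470, 1, 1, 0.0),
            ("intra", 179, 1, 2, 0.0),
            ("intra", 83, 2, 2, 0.0),
            ("intra", 268, 1, 3, 0.0),
        ]
        inter = [
            ("inter", 211, 1, 1, 0.0),
            ("inter", 120, 1, 2, 0.0),
            ("inter", 135, 2, 2, 0.0),
            ("inter", 534, 1, 3, 0.0),
        ]
        e = edges_frame(intra + inter)
        assert upgrade_rate(e, "intra") == pytest.approx(0.447)
        assert upgrade_rate(e, "inter") == pytest.approx(0.654)
        d = channel_differentials(e)
        assert d["d_ur"] == pytest.approx(0.207)
        assert d["d_pi_3"] == pytest.approx(0.534 - 0.268)


class TestWeightedBootstrap:
    def test_single_edge_degenerate_ci(self):
        e = edges_frame([("inter", 4, 1, 3, 5.0), ("intra", 2, 1, 3, 1.0)])
        est, lo, hi, sig = weighted_bootstrap_ci(
            e, lambda s: bypass_premium(s, "inter", 3), "inter", B=50, seed=0
        )
        assert est == lo == hi == 5.0
        assert sig

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(4)
        e = edges_frame(
            [("inter", int(w), 1, 3, float(x)) for w, x in
             zip(rng.integers(1, 10, 30), rng.uniform(0, 8, 30))]
        )
        fn = lambda s: bypass_premium(s, "inter", 3)
        a = weighted_bootstrap_ci(e, fn, "inter", B=200, seed=7)
        b = weighted_bootstrap_ci(e, fn, "inter", B=200, seed=7)
        assert a == b

    def test_differentials_reproducible_and_complete(self):
        rng = np.random.default_rng(5)
        rows = [
            (c, int(w), int(go), int(gd), float(x))
            for c in ("intra", "inter")
            for w, go, gd, x in zip(
                rng.integers(1, 10, 40), rng.integers(1, 3, 40),
                rng.integers(1, 4, 40), rng.uniform(0, 8, 40),
            )
        ]
        e = edges_frame(rows)
        a = bootstrap_differentials(e, B=100, seed=1)
        b = bootstrap_differentials(e, B=100, seed=1)
        pd.testing.assert_frame_equal(a, b)
        assert set(a["metric"]) == {
            "d_pi_1", "d_pi_2", "d_pi_3", "d_ur", "d_bp_1", "d_bp_2", "d_bp_3"
        }


class TestPremiumDecomposition:
    def test_printed_headline_split(self):
        d = premium_decomposition(10.24, 7.53)
        assert d["baseline_pct"] == pytest.approx(73.54, abs=0.01)
        assert d["active_pct"] == pytest.approx(26.46, abs=0.01)
        assert d["active_km"] == pytest.approx(2.71, abs=0.005)

    def test_equal_premiums_all_baseline(self):
        d = premium_decomposition(6.0, 6.0)
        assert d["active_km"] == 0.0
        assert d["baseline_pct"] == 100.0

    def test_even_split(self):
        d = premium_decomposition(8.0, 4.0)
        assert d == pytest.approx(
            {
                "baseline_km": 4.0, "active_km": 4.0, "baseline_pct": 50.0,
                "active_pct": 50.0, "bp_inter_tertiary_km": 8.0,
                "bp_inter_secondary_km": 4.0,
            }
        )

    def test_negative_surplus_floored(self):
        d = premium_decomposition(5.0, 7.0)
        assert d["active_km"] == 0.0
        assert "warning" in d
        assert d["bp_inter_tertiary_km"] == 5.0


class TestEndToEndEdgeTable:
    def test_excess_nonnegative_on_generated_network(self, small_city, small_units, small_R):
        from flowscope.synthetic_city import FlowGenConfig, generate_od_flows

        net, _ = generate_od_flows(
            small_city, small_units, small_R, FlowGenConfig(seed=41, total_trips=30_000)
        )
        d_unit = {u.id: u.district for u in small_units}
        edges = grade_bypass_edge_table(
            net, small_R, small_city.grade_of, d_unit, small_city.district_of
        )
        assert (edges["excess_km"] >= -1e-9).all()
        assert set(edges["channel"]) <= {"intra", "inter"}
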