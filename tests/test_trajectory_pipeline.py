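"""Cleaning, resident filtering, anchor identification, visit detection and
origin assignment on hand-built logs with known expected outcomes."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from flowscope.network_builder import DemandUnit, Hospital
from flowscope.trajectory_pipeline import (
    assign_origin,
    build_staypoints,
    clean_records,
    detect_visits,
    exclude_onsite,
    filter_residents,
    identify_anchor,
)


def make_log(rows):
    return pd.DataFrame(rows, columns=["user_id", "ts", "x_km", "y_km"])


T0 = pd.Timestamp("2019-03-04 09:00:00")  # a Monday


class TestCleanRecords:
    def test_pingpong_triple_collapses(self):
        log = make_log(
            [
                ("u", T0, 0.0, 0.0),
                ("u", T0 + pd.Timedelta(minutes=5), 0.4, 0.0),
                ("u", T0 + pd.Timedelta(minutes=10), 0.0, 0.0),
            ]
        )
        clean, counters = clean_records(log)
        assert counters["pingpong_merged"] == 1
        assert len(clean) == 2
        stays = build_staypoints(clean)
        assert len(stays) == 1
        assert stays.loc[0, "start"] == T0
        assert stays.loc[0, "end"] == T0 + pd.Timedelta(minutes=10)
        assert stays.loc[0, "x_km"] == pytest.approx(0.0)

    def test_speed_infeasible_point_dropped(self):
        log = make_log([("u", T0, 0.0, 0.0), ("u", T0 + pd.Timedelta(hours=1), 100.0, 0.0)])
        clean, counters = clean_records(log, max_speed_kmh=80)
        assert counters["speed_dropped"] == 1
        assert len(clean) == 1
        assert clean.loc[0, "x_km"] == 0.0

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        rows = [
            ("u", T0 + pd.Timedelta(minutes=int(m)), float(x), float(y))
            for m, x, y in zip(range(0, 600, 7), rng.normal(0, 3, 86), rng.normal(0, 3, 86))
        ]
        once, _ = clean_records(make_log(rows))
        twice, counters = clean_records(once)
        assert twice.equals(once)
        assert counters["speed_dropped"] == 0 and counters["pingpong_merged"] == 0

    def test_unparseable_timestamp_rejected(self):
        log = make_log([("u", "not-a-time", 0.0, 0.0), ("u", T0, 1.0, 1.0)])
        clean, counters = clean_records(log)
        assert counters["unparseable_ts"] == 1
        assert len(clean) == 1

    def test_order_insensitive(self):
        rng = np.random.default_rng(1)
        rows = [
            ("u", T0 + pd.Timedelta(minutes=int(m)), float(x), 0.0)
            for m, x in zip(range(0, 300, 5), rng.normal(0, 0.01, 60))
        ]
        log = make_log(rows)
        shuffled = log.sample(frac=1.0, random_state=2).reset_index(drop=True)
        a, _ = clean_records(log)
        b, _ = clean_records(shuffled)
        assert a.equals(b)


class TestFilterResidents:
    @pytest.mark.parametrize("n_days,kept", [(16, True), (15, False), (20, True)])
    def test_strict_active_day_threshold(self, n_days, kept):
        rows = [
            ("u", pd.Timestamp("2019-03-01") + pd.Timedelta(days=d, hours=10), 0.0, 0.0)
            for d in range(n_days)
        ]
        log, _ = clean_records(make_log(rows))
        assert (("u" in filter_residents(log)) is kept)

    def test_empty_log(self):
        assert filter_residents(make_log([])[0:0].assign(ts=pd.Series(dtype="datetime64[ns]"))) == set()


def nightly_log(n_nights_at_home, n_other_nights, home=(5.0, 5.0), other=(15.0, 15.0)):
    """Hourly pings 22:00-02:00 for each night, at home or elsewhere."""
    rows = []
    day = 0
    for _ in range(n_nights_at_home):
        for h in (22, 23, 0, 1):
            ts = pd.Timestamp("2019-03-01 00:00") + pd.Timedelta(days=day, hours=h)
            if h < 6:
                ts += pd.Timedelta(days=1)
            rows.append(("u", ts, home[0], home[1]))
        day += 1
    for _ in range(n_other_nights):
        for h in (22, 23, 0, 1):
            ts = pd.Timestamp("2019-03-01 00:00") + pd.Timedelta(days=day, hours=h)
            if h < 6:
                ts += pd.Timedelta(days=1)
            rows.append(("u", ts, other[0], other[1]))
        day += 1
    return make_log(rows)


class TestIdentifyAnchor:
    def test_majority_cluster_accepted(self):
        log, _ = clean_records(nightly_log(5, 3))
        a = identify_anchor(log, "home", min_pts=4)
        assert a is not None
        assert a.n_supporting_days == 5
        assert a.reliability == pytest.approx(5 / 8)
        assert (a.x, a.y) == pytest.approx((5.0, 5.0))

    def test_minority_cluster_rejected(self):
        log, _ = clean_records(nightly_log(5, 7))  # 5 of 12 nights = 41.7%
        # the larger cluster covers 7 of 12 = 58.3% and wins instead
        a = identify_anchor(log, "home", min_pts=4)
        assert a is not None and (a.x, a.y) == pytest.approx((15.0, 15.0))

    def test_no_qualifying_cluster(self):
        log, _ = clean_records(nightly_log(4, 4))  # both clusters at 50%, not > 50%
        assert identify_anchor(log, "home", min_pts=4) is None

    def test_work_window_excludes_weekends(self):
        rows = [
            ("u", pd.Timestamp("2019-03-02 10:00") + pd.Timedelta(days=7 * k), 3.0, 3.0)
            for k in range(8)  # Saturdays
        ]
        log, _ = clean_records(make_log(rows))
        assert identify_anchor(log, "work", min_pts=2, min_days=2) is None


class TestExcludeOnsite:
    def make_hospital(self):
        return Hospital(id=0, x=0.0, y=0.0, grade=3, footprint=box(-0.1, -0.1, 0.1, 0.1))

    def anchors_at(self, x):
        return pd.DataFrame(
            [("u", "home", x, 0.0, 10, 0.9)],
            columns=["user_id", "kind", "x_km", "y_km", "n_supporting_days", "reliability"],
        )

    def test_anchor_inside_buffer_excluded(self):
        kept = exclude_onsite({"u"}, self.anchors_at(0.15), [self.make_hospital()], buffer_m=100)
        assert kept == set()

    def test_anchor_outside_buffer_retained(self):
        kept = exclude_onsite({"u"}, self.anchors_at(0.25), [self.make_hospital()], buffer_m=100)
        assert kept == {"u"}

    def test_no_hospitals_identity(self):
        assert exclude_onsite({"u"}, self.anchors_at(0.0), [], buffer_m=100) == {"u"}


HOSPITALS = [
    Hospital(id=1, x=10.0, y=10.0, grade=3, footprint=box(9.9, 9.9, 10.1, 10.1)),
    Hospital(id=2, x=20.0, y=20.0, grade=1, footprint=box(19.9, 19.9, 20.1, 20.1)),
]


def hospital_stay(uid, day_ts, hosp, hours):
    return [
        (uid, day_ts + pd.Timedelta(hours=h), hosp.x, hosp.y) for h in hours
    ]


class TestDetectVisits:
    def test_90_minute_stay_detected(self):
        day = pd.Timestamp("2019-03-05")
        rows = hospital_stay("u", day, HOSPITALS[0], [9, 10])  # span 09:00-10:00
        visits, _ = detect_visits(make_log(rows).assign(ts=lambda d: pd.to_datetime(d.ts)), HOSPITALS)
        assert len(visits) == 1
        assert visits.loc[0, "hospital_id"] == 1
        assert visits.loc[0, "dwell_min"] >= 60

    def test_short_stay_ignored(self):
        day = pd.Timestamp("2019-03-05")
        rows = [
            ("u", day + pd.Timedelta(hours=9), 10.0, 10.0),
            ("u", day + pd.Timedelta(hours=9, minutes=45), 10.0, 10.0),
            ("u", day + pd.Timedelta(hours=11), 0.0, 0.0),
        ]
        visits, counters = detect_visits(
            make_log(rows).assign(ts=lambda d: pd.to_datetime(d.ts)), HOSPITALS
        )
        assert len(visits) == 0
        assert counters["below_dwell"] == 1

    def test_first_daily_visit_kept(self):
        day = pd.Timestamp("2019-03-05")
        rows = hospital_stay("u", day, HOSPITALS[0], [9, 10]) + hospital_stay(
            "u", day, HOSPITALS[1], [14, 15]
        )
        visits, _ = detect_visits(make_log(rows).assign(ts=lambda d: pd.to_datetime(d.ts)), HOSPITALS)
        assert len(visits) == 1
        assert visits.loc[0, "hospital_id"] == 1

    def test_outside_windows_ignored(self):
        day = pd.Timestamp("2019-03-05")
        rows = hospital_stay("u", day, HOSPITALS[0], [19, 20, 21])  # evening
        visits, _ = detect_visits(make_log(rows).assign(ts=lambda d: pd.to_datetime(d.ts)), HOSPITALS)
        assert len(visits) == 0


UNITS = [
    DemandUnit(id=1, polygon=box(0, 0, 15, 30), district="A"),
    DemandUnit(id=2, polygon=box(15, 0, 30, 30), district="B"),
]


def anchors_frame(rows):
    return pd.DataFrame(
        rows, columns=["user_id", "kind", "x_km", "y_km", "n_supporting_days", "reliability"]
    )


class TestAssignOrigin:
    def visit_frame(self, start_hour=9.5):
        day = pd.Timestamp("2019-03-05")
        return pd.DataFrame(
            {
                "user_id": ["u"],
                "day": [day],
                "hospital_id": [1],
                "dwell_min": [90.0],
                "start": [day + pd.Timedelta(hours=start_hour)],
                "end": [day + pd.Timedelta(hours=start_hour + 1.5)],
                "x_km": [10.0],
                "y_km": [10.0],
            }
        )

    def test_most_recent_anchor_wins(self):
        day = pd.Timestamp("2019-03-05")
        anchors = anchors_frame(
            [("u", "home", 5.0, 5.0, 10, 0.9), ("u", "work", 25.0, 5.0, 10, 0.9)]
        )
        log = make_log(
            [("u", day + pd.Timedelta(hours=7), 5.0, 5.0), ("u", day + pd.Timedelta(hours=8), 25.0, 5.0)]
        ).assign(ts=lambda d: pd.to_datetime(d.ts))
        out, _ = assign_origin(self.visit_frame(), anchors, log, UNITS)
        assert out.loc[0, "origin_kind"] == "work"
        assert out.loc[0, "origin_unit_id"] == 2

    def test_fallback_to_home(self):
        anchors = anchors_frame([("u", "home", 5.0, 5.0, 10, 0.9)])
        log = make_log([]).assign(ts=pd.Series(dtype="datetime64[ns]"))
        out, counters = assign_origin(self.visit_frame(), anchors, log, UNITS)
        assert counters["fallback_home"] == 1
        assert out.loc[0, "origin_kind"] == "home"
        assert out.loc[0, "origin_unit_id"] == 1

    def test_no_anchor_drops_visit(self):
        log = make_log([]).assign(ts=pd.Series(dtype="datetime64[ns]"))
        out, counters = assign_origin(self.visit_frame(), anchors_frame([]), log, UNITS)
        assert len(out) == 0
        assert counters["no_anchor_dropped"] == 1
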