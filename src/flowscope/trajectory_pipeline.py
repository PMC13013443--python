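"""From raw signaling pings to valid hospital-seeking visits with origins.

Stages, in the order they run: record cleaning (ping-pong merge, speed
filter), permanent-resident filter (> 15 active days), home/work anchor
identification (time-windowed DBSCAN with frequency and reliability
constraints), on-site exclusion (anchors inside a hospital buffer), visit
detection (in-perimeter stays >= 60 min inside daytime windows, first visit
per user-day) and origin assignment (most recent pre-visit anchor, falling
back to home, resolved to a Thiessen demand unit by point-in-polygon).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely import STRtree, contains_xy
from shapely.geometry import Point
from sklearn.cluster import DBSCAN

from .network_builder import DemandUnit, Hospital

__all__ = [
    "AnchorLocation",
    "clean_records",
    "filter_residents",
    "build_staypoints",
    "identify_anchor",
    "identify_anchors",
    "exclude_onsite",
    "detect_visits",
    "assign_origin",
    "run_trajectory_pipeline",
]

HOME_HOURS = frozenset(list(range(22, 24)) + list(range(0, 6)))
WORK_HOURS = frozenset([9, 10, 13, 14, 15, 16])  # 09:00-11:00 and 13:00-17:00
VISIT_WINDOWS = ((8, 11), (13, 16))  # daytime outpatient windows (hours)


@dataclass
class AnchorLocation:
    user_id: str
    kind: str  # "home" | "work"
    x: float
    y: float
    n_supporting_days: int
    reliability: float


# ---------------------------------------------------------------------------
# Cleaning
# ---------------------------------------------------------------------------

def clean_records(
    log: pd.DataFrame,
    max_speed_kmh: float = 120.0,
    merge_window_min: float = 15.0,
    pingpong_eps_km: float = 0.5,
) -> tuple[pd.DataFrame, dict]:
    """Sort, deduplicate, drop speed-infeasible points, merge ping-pong triples.

    A triple A-B-A' with A' within 50 m of A, B within ``pingpong_eps_km`` of
    A and the whole excursion inside ``merge_window_min`` is a base-station
    handover artifact: B is removed so the stay at A survives intact.  A
    record whose implied speed from the previously kept record exceeds
    ``max_speed_kmh`` is a drift outlier and is dropped.  Unparseable
    timestamps are rejected per record.  Idempotent.
    """
    counters = {"unparseable_ts": 0, "duplicates": 0, "speed_dropped": 0, "pingpong_merged": 0}
    df = log.copy()
    ts = pd.to_datetime(df["ts"], errors="coerce")
    bad = ts.isna()
    counters["unparseable_ts"] = int(bad.sum())
    df = df.loc[~bad].assign(ts=ts[~bad])
    n0 = len(df)
    df = df.drop_duplicates(subset=["user_id", "ts"], keep="first")
    counters["duplicates"] = n0 - len(df)
    df = df.sort_values(["user_id", "ts"], ignore_index=True)

    keep_mask = np.ones(len(df), dtype=bool)
    x = df["x_km"].to_numpy(float)
    y = df["y_km"].to_numpy(float)
    t = df["ts"].to_numpy("datetime64[s]").astype("int64")
    uid = df["user_id"].to_numpy()

    # speed filter: greedy forward pass against the last kept record
    start = 0
    while start < len(df):
        end = start
        while end < len(df) and uid[end] == uid[start]:
            end += 1
        last = start
        for k in range(start + 1, end):
            dt_h = (t[k] - t[last]) / 3600.0
            dist = float(np.hypot(x[k] - x[last], y[k] - y[last]))
            if dt_h <= 0:
                if dist > 1e-9:
                    keep_mask[k] = False
                    counters["speed_dropped"] += 1
                continue
            if dist / dt_h > max_speed_kmh:
                keep_mask[k] = False
                counters["speed_dropped"] += 1
            else:
                last = k
        start = end

    df = df.loc[keep_mask].reset_index(drop=True)
    x = df["x_km"].to_numpy(float)
    y = df["y_km"].to_numpy(float)
    t = df["ts"].to_numpy("datetime64[s]").astype("int64")
    uid = df["user_id"].to_numpy()
    keep_mask = np.ones(len(df), dtype=bool)
    win_s = merge_window_min * 60.0
    for k in range(1, len(df) - 1):
        if uid[k - 1] != uid[k] or uid[k] != uid[k + 1]:
            continue
        if t[k + 1] - t[k - 1] > win_s:
            continue
        d_aa = np.hypot(x[k + 1] - x[k - 1], y[k + 1] - y[k - 1])
        d_ab = np.hypot(x[k] - x[k - 1], y[k] - y[k - 1])
        if d_aa <= 0.05 and 0 < d_ab <= pingpong_eps_km:
            keep_mask[k] = False
            counters["pingpong_merged"] += 1
    df = df.loc[keep_mask].reset_index(drop=True)
    return df, counters


def filter_residents(log: pd.DataFrame, min_active_days: int = 15) -> set[str]:
    """Users with strictly more than ``min_active_days`` days having >= 1 record."""
    if log.empty:
        return set()
    active = log.groupby("user_id")["ts"].apply(lambda s: s.dt.normalize().nunique())
    return set(active.index[active > min_active_days])


# ---------------------------------------------------------------------------
# Stay points
# ---------------------------------------------------------------------------

def build_staypoints(
    log: pd.DataFrame, eps_km: float = 0.2, max_gap_min: float = 120.0
) -> pd.DataFrame:
    """Merge consecutive same-place records into dwell (stay) points.

    A record extends the current stay when it lies within ``eps_km`` of the
    stay's running centroid and follows within ``max_gap_min``; otherwise a
    new stay begins.  Returns one row per stay with its span and centroid.
    """
    rows = []
    df = log.sort_values(["user_id", "ts"])
    x = df["x_km"].to_numpy(float)
    y = df["y_km"].to_numpy(float)
    t = df["ts"].to_numpy("datetime64[s]")
    uid = df["user_id"].to_numpy()
    gap = np.timedelta64(int(max_gap_min * 60), "s")

    i = 0
    n = len(df)
    while i < n:
        cx, cy = x[i], y[i]
        cnt = 1
        j = i + 1
        while (
            j < n
            and uid[j] == uid[i]
            and (t[j] - t[j - 1]) <= gap
            and np.hypot(x[j] - cx, y[j] - cy) <= eps_km
        ):
            cnt += 1
            cx += (x[j] - cx) / cnt
            cy += (y[j] - cy) / cnt
            j += 1
        rows.append((uid[i], pd.Timestamp(t[i]), pd.Timestamp(t[j - 1]), cx, cy, cnt))
        i = j
    return pd.DataFrame(
        rows, columns=["user_id", "start", "end", "x_km", "y_km", "n_records"]
    )


# ---------------------------------------------------------------------------
# Anchors
# ---------------------------------------------------------------------------

def _window_frame(log: pd.DataFrame, kind: str) -> tuple[pd.DataFrame, pd.Series]:
    """In-window records plus the period label (night date / workday date)."""
    hours = log["ts"].dt.hour
    if kind == "home":
        mask = hours.isin(HOME_HOURS)
        period = (log["ts"] - pd.Timedelta(hours=6)).dt.normalize()
    elif kind == "work":
        mask = hours.isin(WORK_HOURS) & (log["ts"].dt.dayofweek < 5)
        period = log["ts"].dt.normalize()
    else:
        raise ValueError(f"unknown anchor kind {kind!r}")
    return log.loc[mask], period.loc[mask]


def identify_anchor(
    user_log: pd.DataFrame,
    kind: str,
    eps_km: float = 0.3,
    min_pts: int = 5,
    min_days: int = 5,
    min_reliability: float = 0.5,
) -> AnchorLocation | None:
    """Time-windowed DBSCAN anchor for one user; None when no cluster qualifies.

    A cluster qualifies if it covers >= ``min_days`` distinct nights/workdays
    AND strictly more than ``min_reliability`` of the user's active
    nights/workdays.  Among qualifying clusters the winner covers the most
    periods (ties: more points, then smaller centroid y).  The anchor is the
    cluster's geometric center.
    """
    sub, period = _window_frame(user_log, kind)
    if len(sub) < min_pts:
        return None
    n_active = period.nunique()
    if n_active == 0:
        return None
    xy = sub[["x_km", "y_km"]].to_numpy(float)
    labels = DBSCAN(eps=eps_km, min_samples=min_pts).fit_predict(xy)
    best = None
    for lab in np.unique(labels):
        if lab == -1:
            continue
        in_cluster = labels == lab
        days_covered = period[in_cluster].nunique()
        rel = days_covered / n_active
        if days_covered < min_days or rel <= min_reliability:
            continue
        center = xy[in_cluster].mean(axis=0)
        key = (days_covered, int(in_cluster.sum()), -center[1])
        if best is None or key > best[0]:
            best = (
                key,
                AnchorLocation(
                    user_id=str(sub["user_id"].iloc[0]),
                    kind=kind,
                    x=float(center[0]),
                    y=float(center[1]),
                    n_supporting_days=int(days_covered),
                    reliability=float(rel),
                ),
            )
    return None if best is None else best[1]


def identify_anchors(
    log: pd.DataFrame, users: set[str] | None = None, eps_km: float = 0.3, min_pts: int = 5
) -> pd.DataFrame:
    """Home and work anchors for every user (table form; absent anchors omitted)."""
    rows = []
    for uid, user_log in log.groupby("user_id", sort=True):
        if users is not None and uid not in users:
            continue
        for kind in ("home", "work"):
            a = identify_anchor(user_log, kind, eps_km=eps_km, min_pts=min_pts)
            if a is not None:
                rows.append((a.user_id, a.kind, a.x, a.y, a.n_supporting_days, a.reliability))
    return pd.DataFrame(
        rows, columns=["user_id", "kind", "x_km", "y_km", "n_supporting_days", "reliability"]
    )


def exclude_onsite(
    users: set[str],
    anchors: pd.DataFrame,
    hospitals: list[Hospital],
    buffer_m: float = 100.0,
) -> set[str]:
    """Drop users whose home or work anchor lies inside any hospital buffer.

    Long-term inpatients and hospital staff would otherwise register as
    high-frequency visitors.  Returns the retained user set.
    """
    if not hospitals or anchors.empty:
        return set(users)
    buf_km = buffer_m / 1000.0
    geoms = [h.perimeter().buffer(buf_km) for h in hospitals]
    tree = STRtree(geoms)
    onsite: set[str] = set()
    for _, row in anchors.iterrows():
        if row["user_id"] not in users:
            continue
        p = Point(row["x_km"], row["y_km"])
        for gi in tree.query(p):
            if geoms[gi].covers(p):
                onsite.add(row["user_id"])
                break
    return set(users) - onsite


# ---------------------------------------------------------------------------
# Visits
# ---------------------------------------------------------------------------

def _in_window_minutes(start: pd.Timestamp, end: pd.Timestamp, windows=VISIT_WINDOWS) -> float:
    """Minutes of [start, end] that fall inside the daytime windows."""
    total = 0.0
    for day in pd.date_range(start.normalize(), end.normalize(), freq="D"):
        for lo, hi in windows:
            w0 = day + pd.Timedelta(hours=lo)
            w1 = day + pd.Timedelta(hours=hi)
            ov = (min(end, w1) - max(start, w0)).total_seconds() / 60.0
            if ov > 0:
                total += ov
    return total


def detect_visits(
    log: pd.DataFrame,
    hospitals: list[Hospital],
    windows=VISIT_WINDOWS,
    min_dwell_min: float = 60.0,
    stay_eps_km: float = 0.2,
) -> tuple[pd.DataFrame, dict]:
    """Valid hospital-seeking visits: in-perimeter stays with in-window dwell
    >= ``min_dwell_min``; only the first qualifying visit per user-day.

    A stay is matched to the hospital whose perimeter contains its centroid;
    if several overlap, the smallest hospital id wins (counted).
    """
    counters = {"below_dwell": 0, "boundary_dwell_60": 0, "polygon_ties": 0}
    stays = build_staypoints(log, eps_km=stay_eps_km)
    geoms = [h.perimeter() for h in hospitals]
    hosp_ids = [h.id for h in hospitals]
    tree = STRtree(geoms)

    cand = []
    cx = stays["x_km"].to_numpy()
    cy = stays["y_km"].to_numpy()
    for k in range(len(stays)):
        p = Point(cx[k], cy[k])
        hits = sorted(hosp_ids[gi] for gi in tree.query(p) if geoms[gi].covers(p))
        if not hits:
            continue
        if len(hits) > 1:
            counters["polygon_ties"] += 1
        row = stays.iloc[k]
        dwell = _in_window_minutes(row["start"], row["end"], windows)
        overlaps = dwell > 0
        if not overlaps or dwell < min_dwell_min:
            if overlaps:
                counters["below_dwell"] += 1
            continue
        if dwell == min_dwell_min:
            counters["boundary_dwell_60"] += 1
        cand.append(
            (
                row["user_id"],
                row["start"].normalize(),
                hits[0],
                dwell,
                row["start"],
                row["end"],
                row["x_km"],
                row["y_km"],
            )
        )
    visits = pd.DataFrame(
        cand,
        columns=["user_id", "day", "hospital_id", "dwell_min", "start", "end", "x_km", "y_km"],
    )
    if len(visits):
        visits = (
            visits.sort_values(["user_id", "day", "start"])
            .groupby(["user_id", "day"], as_index=False)
            .first()
        )
    return visits, counters


def assign_origin(
    visits: pd.DataFrame,
    anchors: pd.DataFrame,
    log: pd.DataFrame,
    units: list[DemandUnit],
    match_eps_km: float = 0.3,
) -> tuple[pd.DataFrame, dict]:
    """Attach origin coordinates and demand-unit ids to detected visits.

    The origin is the anchor (home or work) at which the user was last
    observed before the visit started on the same day; with no same-day
    pre-visit anchor observation it falls back to home.  Users without any
    anchor lose the visit (counted).  The origin unit is found by
    point-in-polygon over the Thiessen cells.
    """
    counters = {"no_anchor_dropped": 0, "fallback_home": 0}
    anchor_map: dict[str, dict[str, tuple[float, float]]] = {}
    for _, a in anchors.iterrows():
        anchor_map.setdefault(a["user_id"], {})[a["kind"]] = (a["x_km"], a["y_km"])

    polys = [u.polygon for u in units]
    unit_ids = [u.id for u in units]
    tree = STRtree(polys)

    def unit_of(px: float, py: float) -> int:
        p = Point(px, py)
        hits = [gi for gi in tree.query(p) if polys[gi].covers(p)]
        if hits:
            return unit_ids[min(hits)]
        gi = min(range(len(polys)), key=lambda g: polys[g].distance(p))
        return unit_ids[gi]

    log = log.sort_values(["user_id", "ts"])
    out = []
    for _, v in visits.iterrows():
        uid = v["user_id"]
        amap = anchor_map.get(uid)
        if not amap:
            counters["no_anchor_dropped"] += 1
            continue
        sub = log[
            (log["user_id"] == uid)
            & (log["ts"] < v["start"])
            & (log["ts"].dt.normalize() == v["day"])
        ]
        origin_kind = None
        for _, rec in sub.iloc[::-1].iterrows():
            for kind, (ax, ay) in amap.items():
                if np.hypot(rec["x_km"] - ax, rec["y_km"] - ay) <= match_eps_km:
                    origin_kind = kind
                    break
            if origin_kind:
                break
        if origin_kind is None:
            origin_kind = "home" if "home" in amap else next(iter(amap))
            counters["fallback_home"] += 1
        ox, oy = amap[origin_kind]
        out.append(
            (
                uid,
                v["day"],
                int(v["hospital_id"]),
                float(v["dwell_min"]),
                origin_kind,
                ox,
                oy,
                unit_of(ox, oy),
            )
        )
    result = pd.DataFrame(
        out,
        columns=[
            "user_id",
            "day",
            "hospital_id",
            "dwell_min",
            "origin_kind",
            "origin_x",
            "origin_y",
            "origin_unit_id",
        ],
    )
    return result, counters


def run_trajectory_pipeline(
    log: pd.DataFrame,
    hospitals: list[Hospital],
    units: list[DemandUnit],
    max_speed_kmh: float = 120.0,
    min_active_days: int = 15,
    eps_km: float = 0.3,
    min_pts: int = 5,
    buffer_m: float = 100.0,
    min_dwell_min: float = 60.0,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Full trajectory stage: clean -> residents -> anchors -> on-site
    exclusion -> visit detection -> origin assignment.

    Returns (visits, anchors, funnel counters).
    """
    funnel: dict = {}
    clean, c1 = clean_records(log, max_speed_kmh=max_speed_kmh)
    funnel.update(c1)
    residents = filter_residents(clean, min_active_days=min_active_days)
    funnel["n_residents"] = len(residents)
    clean = clean[clean["user_id"].isin(residents)]
    anchors = identify_anchors(clean, residents, eps_km=eps_km, min_pts=min_pts)
    retained = exclude_onsite(residents, anchors, hospitals, buffer_m=buffer_m)
    funnel["onsite_excluded"] = len(residents) - len(retained)
    clean = clean[clean["user_id"].isin(retained)]
    anchors = anchors[anchors["user_id"].isin(retained)].reset_index(drop=True)
    visits, c2 = detect_visits(clean, hospitals, min_dwell_min=min_dwell_min)
    funnel.update(c2)
    visits, c3 = assign_origin(visits, anchors, clean, units)
    funnel.update(c3)
    funnel["n_visits"] = len(visits)
    return visits, anchors, funnel
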