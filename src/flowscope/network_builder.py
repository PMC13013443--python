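"""Demand units, spatial impedance, and the weighted directed patient-flow network.

The supply side is a set of graded hospitals; the demand side is the Thiessen
(Voronoi) partition they generate, one demand unit per hospital.  Flows are
monthly visit counts aggregated into a dense origin x destination integer
matrix, and spatial impedance is a detour-corrected mean Euclidean distance
``r_ij = d_ij * tau_ij`` estimated by Monte Carlo sampling inside each unit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon, box
from shapely.ops import voronoi_diagram
from shapely import MultiPoint

__all__ = [
    "Hospital",
    "DemandUnit",
    "ImpedanceMatrix",
    "FlowNetwork",
    "build_thiessen",
    "build_impedance",
    "aggregate_flows",
    "network_summary",
    "weighted_quantile",
    "weighted_sde",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Hospital:
    """A supply node: graded public general hospital with planar km coordinates."""

    id: int
    x: float
    y: float
    grade: int  # 1 = primary, 2 = secondary, 3 = tertiary
    district: str = ""
    footprint: Polygon | None = None

    def __post_init__(self) -> None:
        if self.grade not in (1, 2, 3):
            raise ValueError(f"hospital grade must be 1, 2 or 3, got {self.grade}")

    @property
    def xy(self) -> tuple[float, float]:
        return (self.x, self.y)

    @property
    def point(self) -> Point:
        return Point(self.x, self.y)

    def perimeter(self, default_radius_km: float = 0.06) -> Polygon:
        """Hospital area polygon: the footprint if present, else a point buffer."""
        if self.footprint is not None:
            return self.footprint
        return self.point.buffer(default_radius_km)


@dataclass
class DemandUnit:
    """A Thiessen demand unit; its id equals its generator hospital's id."""

    id: int
    polygon: Polygon
    district: str = ""


@dataclass
class ImpedanceMatrix:
    """Pairwise impedance r = d * tau between demand units (rows) and hospitals (cols)."""

    r: np.ndarray
    d: np.ndarray
    tau: np.ndarray
    unit_ids: np.ndarray
    hospital_ids: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.d = np.asarray(self.d, dtype=float)
        self.tau = np.asarray(self.tau, dtype=float)
        self.unit_ids = np.asarray(self.unit_ids)
        self.hospital_ids = np.asarray(self.hospital_ids)
        if not np.all(self.r > 0):
            raise ValueError("impedance matrix must be strictly positive (including the diagonal)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.r.shape


@dataclass
class FlowNetwork:
    """Weighted directed bipartite network G = (O, D, E, W).

    ``w[i, j]`` is the monthly visit count from demand unit ``unit_ids[i]``
    to hospital ``hospital_ids[j]``; edges are the strictly positive cells.
    """

    w: np.ndarray
    unit_ids: np.ndarray
    hospital_ids: np.ndarray
    month: str = ""

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w)
        if np.any(self.w < 0):
            raise ValueError("flow weights must be non-negative")
        self.unit_ids = np.asarray(self.unit_ids)
        self.hospital_ids = np.asarray(self.hospital_ids)

    @property
    def n_origins(self) -> int:
        return self.w.shape[0]

    @property
    def n_destinations(self) -> int:
        return self.w.shape[1]

    @property
    def total_flow(self) -> int:
        return int(self.w.sum())

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(self.w))

    def in_strength(self) -> np.ndarray:
        """S_j^in = sum_i w_ij, one entry per hospital."""
        return self.w.sum(axis=0)

    def out_strength(self) -> np.ndarray:
        """S_i^out = sum_j w_ij, one entry per demand unit."""
        return self.w.sum(axis=1)

    def edges(self) -> list[tuple[int, int, int]]:
        """Realized edges as (origin unit id, hospital id, weight), weight > 0."""
        ii, jj = np.nonzero(self.w)
        return [
            (int(self.unit_ids[i]), int(self.hospital_ids[j]), int(self.w[i, j]))
            for i, j in zip(ii, jj)
        ]

    def to_edge_frame(self) -> pd.DataFrame:
        ii, jj = np.nonzero(self.w)
        return pd.DataFrame(
            {
                "origin_unit_id": self.unit_ids[ii],
                "hospital_id": self.hospital_ids[jj],
                "weight": self.w[ii, jj],
            }
        ).sort_values(["origin_unit_id", "hospital_id"], ignore_index=True)


# ---------------------------------------------------------------------------
# Thiessen partition
# ---------------------------------------------------------------------------

def build_thiessen(hospitals: list[Hospital], study_area: Polygon) -> list[DemandUnit]:
    """Partition the study area into Voronoi cells seeded at hospital locations.

    Each cell is clipped to the study area and carries the id and district of
    its generator hospital ("one-hospital-one-domain").
    """
    if len(hospitals) < 3:
        raise ValueError("need at least 3 hospitals to build a Thiessen partition")
    coords = {(h.x, h.y) for h in hospitals}
    if len(coords) != len(hospitals):
        raise ValueError("duplicate hospital coordinates: Voronoi cells undefined")

    seeds = MultiPoint([h.point for h in hospitals])
    cells = voronoi_diagram(seeds, envelope=study_area.buffer(1.0))
    units: list[DemandUnit] = []
    remaining = list(cells.geoms)
    for h in hospitals:
        cell = next((c for c in remaining if c.covers(h.point)), None)
        if cell is None:  # numeric edge case: fall back to nearest cell
            cell = min(remaining, key=lambda c: c.distance(h.point))
        clipped = cell.intersection(study_area)
        units.append(DemandUnit(id=h.id, polygon=clipped, district=h.district))
    return units


# ---------------------------------------------------------------------------
# Impedance
# ---------------------------------------------------------------------------

def _sample_in_polygon(poly: Polygon, n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform points inside a polygon by rejection from the bounding box."""
    minx, miny, maxx, maxy = poly.bounds
    out = np.empty((0, 2))
    from shapely import contains_xy

    while out.shape[0] < n:
        m = max(2 * (n - out.shape[0]), 64)
        xs = rng.uniform(minx, maxx, m)
        ys = rng.uniform(miny, maxy, m)
        keep = contains_xy(poly, xs, ys)
        out = np.vstack([out, np.column_stack([xs[keep], ys[keep]])])
    return out[:n]


def build_impedance(
    units: list[DemandUnit],
    hospitals: list[Hospital],
    n_samples: int = 2000,
    tau_land: float = 1.3,
    tau_river: float = 1.8,
    river_x: float | None = None,
    seed: int | None = 0,
) -> ImpedanceMatrix:
    """Monte-Carlo impedance matrix r_ij = d_ij * tau_ij.

    d_ij is the mean Euclidean distance from ``n_samples`` uniform points in
    unit i to hospital j; tau_ij is ``tau_river`` when the centroid-to-hospital
    segment crosses the vertical river line ``x = river_x`` and ``tau_land``
    otherwise.  One point set is drawn per unit and re-used across hospitals.
    """
    rng = np.random.default_rng(seed)
    hx = np.array([h.x for h in hospitals])
    hy = np.array([h.y for h in hospitals])
    n_u, n_h = len(units), len(hospitals)
    d = np.empty((n_u, n_h))
    tau = np.full((n_u, n_h), tau_land)

    for i, u in enumerate(units):
        if u.polygon.is_empty or u.polygon.area <= 0:
            warnings.warn(f"demand unit {u.id} has zero area; using its representative point")
            pts = np.array([[u.polygon.centroid.x, u.polygon.centroid.y]]) \
                if not u.polygon.is_empty else np.zeros((1, 2))
        else:
            pts = _sample_in_polygon(u.polygon, n_samples, rng)
        d[i] = np.sqrt((pts[:, 0, None] - hx) ** 2 + (pts[:, 1, None] - hy) ** 2).mean(axis=0)
        if river_x is not None:
            cx = u.polygon.centroid.x
            tau[i] = np.where((cx - river_x) * (hx - river_x) < 0, tau_river, tau_land)

    r = d * tau
    # a unit's own hospital can make d_ii ~ 0 only for degenerate cells; guard
    r = np.maximum(r, 1e-9)
    return ImpedanceMatrix(
        r=r,
        d=d,
        tau=tau,
        unit_ids=np.array([u.id for u in units]),
        hospital_ids=np.array([h.id for h in hospitals]),
    )


# ---------------------------------------------------------------------------
# Flow aggregation and summaries
# ---------------------------------------------------------------------------

def aggregate_flows(
    visits: pd.DataFrame,
    unit_ids: np.ndarray,
    hospital_ids: np.ndarray,
    month: str = "",
) -> FlowNetwork:
    """Count visits into the OD weight matrix w_ij.

    ``visits`` needs ``origin_unit_id`` and ``hospital_id`` columns; each row
    is one valid hospital-seeking visit.
    """
    unit_ids = np.asarray(unit_ids)
    hospital_ids = np.asarray(hospital_ids)
    w = np.zeros((len(unit_ids), len(hospital_ids)), dtype=np.int64)
    if len(visits):
        u_idx = pd.Index(unit_ids)
        h_idx = pd.Index(hospital_ids)
        oi = u_idx.get_indexer(visits["origin_unit_id"])
        dj = h_idx.get_indexer(visits["hospital_id"])
        if (oi < 0).any() or (dj < 0).any():
            raise ValueError("visit refers to an unknown demand unit or hospital")
        np.add.at(w, (oi, dj), 1)
    return FlowNetwork(w=w, unit_ids=unit_ids, hospital_ids=hospital_ids, month=month)


def weighted_quantile(values: np.ndarray, weights: np.ndarray, q) -> np.ndarray:
    """Quantiles of a weighted distribution by cumulative-weight interpolation."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cw = np.cumsum(w) - 0.5 * w
    cw /= w.sum()
    return np.interp(np.atleast_1d(q), cw, v)


def network_summary(
    net: FlowNetwork,
    R: ImpedanceMatrix | None = None,
    grades: dict[int, int] | None = None,
    top_k: int = 10,
) -> dict:
    """Global structural indicators of the flow network.

    Density uses ordered origin-destination pairs including self-pairs,
    |E| / (|O|*|D|).  Distance statistics are flow-weighted over realized
    edges; grade shares are inflow shares by destination grade.
    """
    out: dict = {
        "n_origins": net.n_origins,
        "n_destinations": net.n_destinations,
        "n_edges": net.n_edges,
        "density": net.n_edges / (net.n_origins * net.n_destinations),
        "total_flow": net.total_flow,
    }
    ii, jj = np.nonzero(net.w)
    ww = net.w[ii, jj].astype(float)
    if R is not None and ww.size:
        rr = R.r[ii, jj]
        out["weighted_mean_distance_km"] = float(np.average(rr, weights=ww))
        p50, p90 = weighted_quantile(rr, ww, [0.5, 0.9])
        out["weighted_p50_km"] = float(p50)
        out["weighted_p90_km"] = float(p90)
    s_in = net.in_strength().astype(float)
    total = s_in.sum()
    if total > 0:
        k = min(top_k, len(s_in))
        out[f"top_{top_k}_inflow_share"] = float(np.sort(s_in)[::-1][:k].sum() / total)
        if grades is not None:
            g = np.array([grades[int(h)] for h in net.hospital_ids])
            out["grade_inflow_shares"] = {
                int(gr): float(s_in[g == gr].sum() / total) for gr in (1, 2, 3)
            }
    return out


def weighted_sde(points: np.ndarray, weights: np.ndarray) -> dict:
    """Weighted standard deviational ellipse of a point pattern.

    Center is the weighted mean; the axes are weighted standard deviations
    along the eigenvectors of the weighted covariance; orientation is the
    major-axis azimuth in degrees clockwise from north, in [0, 180).
    """
    pts = np.asarray(points, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.all(w == 0):
        raise ValueError("all weights are zero: ellipse undefined")
    wn = w / w.sum()
    center = wn @ pts
    c = pts - center
    cov = (c * wn[:, None]).T @ c
    evals, evecs = np.linalg.eigh(cov)  # ascending
    major_v = evecs[:, 1]
    angle = math.degrees(math.atan2(major_v[0], major_v[1])) % 180.0
    return {
        "center": (float(center[0]), float(center[1])),
        "major_axis_len": float(np.sqrt(max(evals[1], 0.0))),
        "minor_axis_len": float(np.sqrt(max(evals[0], 0.0))),
        "orientation_deg": angle,
    }
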