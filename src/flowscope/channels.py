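"""Channel decomposition of the flow network and intra-channel inequality.

Every edge is classified by the administrative relation of its endpoints:
local (origin unit is the destination's own unit, i = j), intra-district
(different unit, same district) or inter-district.  Per channel we report
edge counts, volumes, shares and mean weights, plus Theil-index inequality
with its effective-edge transform rho_c = N_c exp(-T_c) and Lorenz curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network_builder import FlowNetwork

__all__ = [
    "classify_edge",
    "edge_table",
    "channel_decomposition",
    "theil_effective",
    "effective_size",
    "lorenz_curve",
    "lorenz_gini",
    "CHANNELS",
]

CHANNELS = ("local", "intra", "inter")


def classify_edge(i: int, j: int, district_of_unit, district_of_hospital) -> str:
    """Channel of edge (unit i -> hospital j): local iff i = j, else intra
    when the origin's district equals the destination's, else inter."""
    if i == j:
        return "local"
    return "intra" if district_of_unit[i] == district_of_hospital[j] else "inter"


def edge_table(
    net: FlowNetwork, district_of_unit: dict, district_of_hospital: dict
) -> pd.DataFrame:
    """Realized edges with their channel labels."""
    ii, jj = np.nonzero(net.w)
    ui = net.unit_ids[ii]
    hj = net.hospital_ids[jj]
    ud = np.array([district_of_unit[int(u)] for u in ui])
    hd = np.array([district_of_hospital[int(h)] for h in hj])
    channel = np.where(ui == hj, "local", np.where(ud == hd, "intra", "inter"))
    return pd.DataFrame(
        {
            "origin_unit_id": ui,
            "hospital_id": hj,
            "weight": net.w[ii, jj],
            "channel": channel,
        }
    )


def theil_effective(weights: np.ndarray) -> tuple[float, float]:
    """Theil index T_c = sum q ln(N_c q) over edge shares q = w / W_c, and the
    effective edge count rho_c = N_c exp(-T_c).

    T_c = 0 (rho_c = N_c) for perfectly even weights; T_c = ln N_c
    (rho_c = 1) when one edge carries everything.
    """
    w = np.asarray(weights, dtype=float)
    if w.size == 0 or np.any(w <= 0):
        raise ValueError("theil needs strictly positive realized edge weights")
    q = w / w.sum()
    t = float((q * np.log(w.size * q)).sum())
    t = max(t, 0.0)  # clip tiny negative rounding
    return t, effective_size(w.size, t)


def effective_size(n_edges: int, theil: float) -> float:
    """Effective number of edges rho_c = N_c * exp(-T_c)."""
    if n_edges <= 0:
        raise ValueError("n_edges must be positive")
    if theil < 0:
        raise ValueError("Theil index must be >= 0")
    return float(n_edges * np.exp(-theil))


def channel_decomposition(
    net: FlowNetwork, district_of_unit: dict, district_of_hospital: dict
) -> pd.DataFrame:
    """Per-channel structure table (plus a global row).

    Columns: n_edges, edge_share, flow, flow_share, mean_flow, theil,
    effective_edges, effective_ratio.  Empty channels get explicit null rows.
    The channel partition is exhaustive and exclusive, so edge counts and
    flows sum exactly to the global row.
    """
    edges = edge_table(net, district_of_unit, district_of_hospital)
    n_total = len(edges)
    w_total = int(edges["weight"].sum()) if n_total else 0
    rows = []
    for c in CHANNELS:
        sub = edges.loc[edges["channel"] == c, "weight"].to_numpy()
        if sub.size == 0:
            rows.append((c, 0, 0.0, 0, 0.0, np.nan, np.nan, np.nan, np.nan))
            continue
        wc = int(sub.sum())
        t, rho = theil_effective(sub)
        rows.append(
            (
                c,
                sub.size,
                sub.size / n_total if n_total else 0.0,
                wc,
                wc / w_total if w_total else 0.0,
                wc / sub.size,
                t,
                rho,
                rho / sub.size,
            )
        )
    rows.append(
        (
            "global",
            n_total,
            1.0 if n_total else 0.0,
            w_total,
            1.0 if w_total else 0.0,
            w_total / n_total if n_total else np.nan,
            np.nan,
            np.nan,
            np.nan,
        )
    )
    return pd.DataFrame(
        rows,
        columns=[
            "channel",
            "n_edges",
            "edge_share",
            "flow",
            "flow_share",
            "mean_flow",
            "theil",
            "effective_edges",
            "effective_ratio",
        ],
    )


def lorenz_curve(weights: np.ndarray) -> np.ndarray:
    """Lorenz curve of edge weights: (cumulative edge fraction, cumulative
    flow fraction) from (0, 0) to (1, 1) after an ascending sort."""
    w = np.sort(np.asarray(weights, dtype=float))
    if w.size == 0 or np.any(w < 0) or w.sum() <= 0:
        raise ValueError("lorenz curve needs non-negative weights with positive total")
    cum_edges = np.arange(0, w.size + 1) / w.size
    cum_flow = np.concatenate([[0.0], np.cumsum(w)]) / w.sum()
    return np.column_stack([cum_edges, cum_flow])


def lorenz_gini(weights: np.ndarray) -> float:
    """Gini coefficient as twice the area between the diagonal and the Lorenz
    curve (trapezoidal); used as a cross-check against the direct formula."""
    curve = lorenz_curve(weights)
    area = np.trapezoid(curve[:, 1], curve[:, 0])
    return float(1.0 - 2.0 * area)
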