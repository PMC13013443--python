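"""Concentration statistics for node in-strengths and edge weights.

Gini coefficient, Herfindahl-Hirschman index with its effective-number
reciprocal, and cumulative top-k shares, computed either on the full network
or on the non-local scope that drops same-unit (i = j) flows.  Node-level
statistics keep zero-inflow hospitals in N; edge-level statistics run over
realized (w > 0) edges only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network_builder import FlowNetwork

__all__ = [
    "ConcentrationReport",
    "gini",
    "hhi_neff",
    "top_share",
    "node_inflow_concentration",
    "edge_weight_concentration",
]


@dataclass
class ConcentrationReport:
    gini: float
    hhi: float
    n_eff: float
    top_k_share: dict[int, float]
    n: int
    scope: str  # "full" | "nonlocal"
    level: str  # "node" | "edge"
    includes_zero_units: bool = False


def gini(x: np.ndarray) -> float:
    """Gini coefficient of a non-negative vector.

    Sorted ascending, G = sum_m (2m - N - 1) x_(m) / (N sum_m x_(m));
    0 for perfect equality, (N-1)/N when one unit holds everything.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0 or np.any(x < 0):
        raise ValueError("gini needs a non-empty, non-negative vector")
    total = x.sum()
    if total <= 0:
        raise ValueError("gini undefined for an all-zero vector")
    xs = np.sort(x)
    n = xs.size
    m = np.arange(1, n + 1)
    return float(((2 * m - n - 1) * xs).sum() / (n * total))


def hhi_neff(x: np.ndarray) -> tuple[float, float]:
    """Herfindahl index of the share vector and its reciprocal effective number."""
    x = np.asarray(x, dtype=float)
    total = x.sum()
    if total <= 0:
        raise ValueError("hhi undefined for an all-zero vector")
    shares = x / total
    h = float((shares**2).sum())
    return h, 1.0 / h


def top_share(x: np.ndarray, k: int, ids: np.ndarray | None = None) -> float:
    """Share of the total held by the k largest values.

    Ties at the k-th rank are broken deterministically by a secondary
    ascending sort on ``ids`` (position index when ids is None); exactly k
    values are summed.
    """
    x = np.asarray(x, dtype=float)
    if not (0 < k <= x.size):
        raise ValueError(f"k must be in [1, {x.size}]")
    total = x.sum()
    if total <= 0:
        raise ValueError("top_share undefined for an all-zero vector")
    if ids is None:
        ids = np.arange(x.size)
    order = np.lexsort((np.asarray(ids), -x))
    return float(x[order[:k]].sum() / total)


def _scoped_weights(net: FlowNetwork, scope: str) -> np.ndarray:
    w = net.w.astype(float)
    if scope == "nonlocal":
        w = w.copy()
        shared = np.intersect1d(net.unit_ids, net.hospital_ids)
        ui = {int(u): i for i, u in enumerate(net.unit_ids)}
        hj = {int(h): j for j, h in enumerate(net.hospital_ids)}
        for s in shared:
            w[ui[int(s)], hj[int(s)]] = 0.0
    elif scope != "full":
        raise ValueError(f"unknown scope {scope!r}")
    return w


def node_inflow_concentration(
    net: FlowNetwork, scope: str = "full", top_k: tuple[int, ...] = (10,)
) -> ConcentrationReport:
    """Concentration of hospital in-strengths S_j^in (zero-inflow hospitals count)."""
    w = _scoped_weights(net, scope)
    s_in = w.sum(axis=0)
    if s_in.sum() <= 0:
        raise ValueError(f"no flow left at scope={scope!r}")
    h, ne = hhi_neff(s_in)
    return ConcentrationReport(
        gini=gini(s_in),
        hhi=h,
        n_eff=ne,
        top_k_share={k: top_share(s_in, min(k, s_in.size), ids=net.hospital_ids) for k in top_k},
        n=s_in.size,
        scope=scope,
        level="node",
        includes_zero_units=True,
    )


def edge_weight_concentration(
    net: FlowNetwork, scope: str = "full", top_frac: float = 0.01
) -> ConcentrationReport:
    """Concentration of realized edge weights; top share uses the top 1% of edges."""
    w = _scoped_weights(net, scope)
    ww = w[w > 0]
    if ww.size == 0:
        raise ValueError(f"no realized edges at scope={scope!r}")
    h, ne = hhi_neff(ww)
    k = max(1, int(np.ceil(top_frac * ww.size)))
    return ConcentrationReport(
        gini=gini(ww),
        hhi=h,
        n_eff=ne,
        top_k_share={k: top_share(ww, k)},
        n=int(ww.size),
        scope=scope,
        level="edge",
    )
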