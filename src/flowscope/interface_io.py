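"""Configuration, file adapters, logging and the end-to-end pipeline runner.

Everything on disk is plain text: point/polygon layers as GeoJSON, tables as
CSV with documented headers, reports as JSON/CSV with sorted keys so reruns
diff cleanly.  ``run_pipeline`` chains synth (or load) -> trajectories ->
network -> concentration -> null test -> channels -> bypass, persisting
every intermediate and a manifest of seeds and row counts; with ``resume``
a stage is reloaded from disk unless an upstream stage was recomputed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import mapping, shape

from . import channels as channels_mod
from . import concentration as conc_mod
from .grade_bypass import bypass_report
from .network_builder import (
    DemandUnit,
    FlowNetwork,
    Hospital,
    ImpedanceMatrix,
    aggregate_flows,
    build_impedance,
    build_thiessen,
    network_summary,
    weighted_sde,
)
from .null_model import NullModelConfig, null_test_suite
from .synthetic_city import (
    CityConfig,
    FlowGenConfig,
    PopulationConfig,
    SyntheticCity,
    generate_city,
    generate_od_flows,
    generate_signaling_log,
)
from .trajectory_pipeline import run_trajectory_pipeline

__all__ = [
    "RunConfig",
    "run_pipeline",
    "write_hospitals",
    "read_hospitals",
    "write_polygons",
    "read_polygons",
    "write_units",
    "read_units",
    "write_impedance",
    "read_impedance",
    "write_network",
    "read_network",
    "write_signaling_log",
    "read_signaling_log",
]

logger = logging.getLogger("flowscope")


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Seeds, per-stage parameters and output layout for a full run.

    ``mode`` selects how flows arise: "od" draws them straight from the
    distance-decay generative model; "signaling" synthesizes a ping log and
    runs the full trajectory stage first.
    """

    seed: int = 0
    outdir: str = "flowscope_out"
    mode: str = "od"  # "od" | "signaling"
    city: CityConfig = field(default_factory=CityConfig)
    flows: FlowGenConfig = field(default_factory=FlowGenConfig)
    population: PopulationConfig = field(default_factory=PopulationConfig)
    impedance_n_samples: int = 2000
    tau_land: float = 1.3
    tau_river: float = 1.8
    null_B: int = 1000
    null_scopes: tuple[str, ...] = ("full", "nonlocal")
    bootstrap_B: int = 1000
    resume: bool = False

    def __post_init__(self) -> None:
        # propagate the master seed into stage configs unless set explicitly
        if isinstance(self.city, dict):
            self.city = CityConfig(**self.city)
        if isinstance(self.flows, dict):
            self.flows = FlowGenConfig(**self.flows)
        if isinstance(self.population, dict):
            self.population = PopulationConfig(**self.population)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key in ("bbox", "n_hospitals_by_grade"):
            if key in raw.get("city", {}):
                raw["city"][key] = tuple(raw["city"][key])
        for key in ("grade_attraction",):
            if key in raw.get("flows", {}):
                raw["flows"][key] = tuple(raw["flows"][key])
        if "dwell_minutes" in raw.get("population", {}):
            raw["population"]["dwell_minutes"] = tuple(raw["population"]["dwell_minutes"])
        if "null_scopes" in raw:
            raw["null_scopes"] = tuple(raw["null_scopes"])
        return cls(**raw)


def demo_config(seed: int = 0, outdir: str = "flowscope_out") -> RunConfig:
    """Desk-scale defaults: ~50 hospitals, 5 districts, 2e5 trips."""
    return RunConfig(
        seed=seed,
        outdir=outdir,
        mode="od",
        city=CityConfig(seed=seed, n_hospitals_by_grade=(30, 12, 8), n_districts=5),
        flows=FlowGenConfig(seed=seed, total_trips=200_000),
        impedance_n_samples=500,
        null_B=1000,
        bootstrap_B=1000,
    )


# ---------------------------------------------------------------------------
# Adapters
# ---------------------------------------------------------------------------

def _feature(geom, props: dict) -> dict:
    return {"type": "Feature", "geometry": mapping(geom), "properties": props}


def _write_geojson(path: Path, features: list[dict]) -> None:
    path.write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, sort_keys=True)
    )


def write_hospitals(hospitals: list[Hospital], path: str | Path) -> None:
    feats = [
        _feature(
            h.point,
            {
                "id": h.id,
                "grade": h.grade,
                "district": h.district,
                "footprint": None if h.footprint is None else h.footprint.wkt,
            },
        )
        for h in sorted(hospitals, key=lambda h: h.id)
    ]
    _write_geojson(Path(path), feats)


def read_hospitals(path: str | Path) -> list[Hospital]:
    from shapely import wkt as shapely_wkt

    raw = json.loads(Path(path).read_text())
    out = []
    for feat in raw["features"]:
        props = feat["properties"]
        for col in ("id", "grade"):
            if col not in props:
                raise ValueError(f"hospital layer missing required attribute {col!r}")
        geom = shape(feat["geometry"])
        fp = props.get("footprint")
        out.append(
            Hospital(
                id=int(props["id"]),
                x=geom.x,
                y=geom.y,
                grade=int(props["grade"]),
                district=str(props.get("district", "")),
                footprint=None if fp in (None, "") else shapely_wkt.loads(fp),
            )
        )
    return sorted(out, key=lambda h: h.id)


def write_polygons(polys: dict[str, object], path: str | Path) -> None:
    feats = [_feature(poly, {"name": name}) for name, poly in sorted(polys.items())]
    _write_geojson(Path(path), feats)


def read_polygons(path: str | Path) -> dict[str, object]:
    raw = json.loads(Path(path).read_text())
    return {f["properties"]["name"]: shape(f["geometry"]) for f in raw["features"]}


def write_units(units: list[DemandUnit], path: str | Path) -> None:
    feats = [
        _feature(u.polygon, {"id": u.id, "district": u.district})
        for u in sorted(units, key=lambda u: u.id)
    ]
    _write_geojson(Path(path), feats)


def read_units(path: str | Path) -> list[DemandUnit]:
    raw = json.loads(Path(path).read_text())
    units = [
        DemandUnit(
            id=int(f["properties"]["id"]),
            polygon=shape(f["geometry"]),
            district=str(f["properties"].get("district", "")),
        )
        for f in raw["features"]
    ]
    return sorted(units, key=lambda u: u.id)


def write_impedance(R: ImpedanceMatrix, prefix: str | Path) -> None:
    prefix = Path(prefix)
    for name, mat in (("r", R.r), ("d", R.d), ("tau", R.tau)):
        pd.DataFrame(mat, index=R.unit_ids, columns=R.hospital_ids).to_csv(
            f"{prefix}_{name}.csv", index_label="unit_id"
        )


def read_impedance(prefix: str | Path) -> ImpedanceMatrix:
    frames = {}
    for name in ("r", "d", "tau"):
        frames[name] = pd.read_csv(f"{prefix}_{name}.csv", index_col="unit_id")
    r = frames["r"]
    return ImpedanceMatrix(
        r=r.to_numpy(),
        d=frames["d"].to_numpy(),
        tau=frames["tau"].to_numpy(),
        unit_ids=r.index.to_numpy(int),
        hospital_ids=r.columns.to_numpy(int),
    )


def write_network(net: FlowNetwork, path: str | Path) -> None:
    """Three-column weighted edge list plus a JSON sidecar holding the node
    sets (so zero-flow rows/columns survive a round trip)."""
    path = Path(path)
    net.to_edge_frame().to_csv(path, index=False)
    sidecar = {
        "month": net.month,
        "unit_ids": [int(u) for u in net.unit_ids],
        "hospital_ids": [int(h) for h in net.hospital_ids],
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(sidecar, sort_keys=True)
    )


def read_network(path: str | Path) -> FlowNetwork:
    path = Path(path)
    edges = pd.read_csv(path)
    for col in ("origin_unit_id", "hospital_id", "weight"):
        if col not in edges.columns:
            raise ValueError(f"edge list missing required column {col!r}")
        bad = pd.to_numeric(edges[col], errors="coerce").isna()
        if bad.any():
            # +2: header line plus 1-based indexing
            raise ValueError(f"malformed edge list row at line {int(bad.idxmax()) + 2}")
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        unit_ids = np.array(meta["unit_ids"])
        hospital_ids = np.array(meta["hospital_ids"])
        month = meta.get("month", "")
    else:
        unit_ids = np.unique(edges["origin_unit_id"])
        hospital_ids = np.unique(edges["hospital_id"])
        month = ""
    return aggregate_flows(
        edges.loc[edges.index.repeat(edges["weight"].astype(int))],
        unit_ids,
        hospital_ids,
        month=month,
    )


def write_signaling_log(log: pd.DataFrame, path: str | Path) -> None:
    out = log.rename(columns={"ts": "ts_iso8601"}).copy()
    out["ts_iso8601"] = pd.to_datetime(out["ts_iso8601"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def read_signaling_log(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("user_id", "ts_iso8601", "x_km", "y_km"):
        if col not in df.columns:
            raise ValueError(f"signaling log missing required column {col!r}")
    df = df.rename(columns={"ts_iso8601": "ts"})
    df["ts"] = pd.to_datetime(df["ts"])
    return df


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_report(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, sort_keys=True, indent=1, default=_json_default))


# ---------------------------------------------------------------------------
# Pipeline runner
# ---------------------------------------------------------------------------

def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage, persist intermediates and reports, return a bundle.

    The bundle maps stage names to in-memory results; ``manifest.json`` in
    the output directory records seeds, row counts and flow totals so stage
    boundaries reconcile.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "mode": cfg.mode, "stages": {}}
    bundle: dict = {}
    recomputed_upstream = False

    def stage(name: str, paths: list[Path], compute, load):
        nonlocal recomputed_upstream
        fresh = all(p.exists() for p in paths)
        if cfg.resume and fresh and not recomputed_upstream:
            logger.info("stage %s: loaded from %s", name, [str(p) for p in paths])
            result = load()
        else:
            logger.info("stage %s: computing", name)
            result = compute()
            recomputed_upstream = True
        bundle[name] = result
        return result

    # --- city ---------------------------------------------------------
    def compute_city():
        city = generate_city(cfg.city)
        write_hospitals(city.hospitals, out / "hospitals.geojson")
        write_polygons(city.districts, out / "districts.geojson")
        return city

    def load_city():
        return SyntheticCity(
            hospitals=read_hospitals(out / "hospitals.geojson"),
            districts=read_polygons(out / "districts.geojson"),
            bbox=cfg.city.bbox,
            river_x=cfg.city.river_x,
        )

    city = stage(
        "city", [out / "hospitals.geojson", out / "districts.geojson"], compute_city, load_city
    )
    manifest["stages"]["city"] = {
        "n_hospitals": len(city.hospitals),
        "n_districts": len(city.districts),
    }

    # --- demand units -------------------------------------------------
    units = stage(
        "units",
        [out / "units.geojson"],
        lambda: (
            lambda u: (write_units(u, out / "units.geojson"), u)[1]
        )(build_thiessen(city.hospitals, city.study_area)),
        lambda: read_units(out / "units.geojson"),
    )
    manifest["stages"]["units"] = {"n_units": len(units)}

    # --- impedance ----------------------------------------------------
    def compute_R():
        R = build_impedance(
            units,
            city.hospitals,
            n_samples=cfg.impedance_n_samples,
            tau_land=cfg.tau_land,
            tau_river=cfg.tau_river,
            river_x=city.river_x,
            seed=cfg.seed,
        )
        write_impedance(R, out / "impedance")
        return R

    R = stage(
        "impedance",
        [out / f"impedance_{s}.csv" for s in ("r", "d", "tau")],
        compute_R,
        lambda: read_impedance(out / "impedance"),
    )

    # --- flows --------------------------------------------------------
    def compute_flows():
        if cfg.mode == "od":
            net, truth = generate_od_flows(city, units, R, cfg.flows)
        elif cfg.mode == "signaling":
            log, truth = generate_signaling_log(city, cfg.population)
            write_signaling_log(log, out / "signaling_log.csv")
            visits, anchors, funnel = run_trajectory_pipeline(log, city.hospitals, units)
            visits.to_csv(out / "visits.csv", index=False)
            anchors.to_csv(out / "anchors.csv", index=False)
            manifest["stages"]["trajectories"] = funnel
            net = aggregate_flows(
                visits, R.unit_ids, R.hospital_ids, month=cfg.population.start_date[:7]
            )
        else:
            raise ValueError(f"unknown mode {cfg.mode!r}")
        write_network(net, out / "edges.csv")
        return net

    net = stage("flows", [out / "edges.csv"], compute_flows, lambda: read_network(out / "edges.csv"))
    manifest["stages"]["flows"] = {"total_flow": net.total_flow, "n_edges": net.n_edges}

    grade_of = city.grade_of
    district_of_hosp = city.district_of
    district_of_unit = {u.id: u.district for u in units}

    # --- network summary (Table-1 shaped) ------------------------------
    summary = network_summary(net, R, grades=grade_of)
    hxy = np.array([[h.x, h.y] for h in city.hospitals])
    if net.in_strength().sum() > 0:
        summary["inflow_sde"] = weighted_sde(hxy, net.in_strength().astype(float))
    write_report(summary, out / "report_network.json")
    bundle["summary"] = summary

    # --- concentration --------------------------------------------------
    conc = {}
    for scope in cfg.null_scopes:
        conc[f"node_{scope}"] = dataclasses.asdict(
            conc_mod.node_inflow_concentration(net, scope)
        )
        conc[f"edge_{scope}"] = dataclasses.asdict(
            conc_mod.edge_weight_concentration(net, scope)
        )
    write_report(conc, out / "report_concentration.json")
    bundle["concentration"] = conc

    # --- null model (Table-2 shaped) ------------------------------------
    null_rows = []
    bundle["null"] = {}
    for scope in cfg.null_scopes:
        res = null_test_suite(
            net, R, NullModelConfig(B=cfg.null_B, scope=scope, seed=cfg.seed)
        )
        bundle["null"][scope] = res
        for metric in res.stats_obs:
            null_rows.append(
                {
                    "scope": scope,
                    "beta_hat": res.beta_hat,
                    "metric": metric,
                    "observed": res.stats_obs[metric],
                    "null_mean": res.null_means[metric],
                    "obs_over_null": res.obs_over_null[metric],
                    "p_two_tailed": res.p_two_tailed[metric],
                }
            )
    pd.DataFrame(null_rows).to_csv(out / "report_nulltest.csv", index=False)

    # --- channels (Table-3 shaped) ---------------------------------------
    chan = channels_mod.channel_decomposition(net, district_of_unit, district_of_hosp)
    chan.to_csv(out / "report_channels.csv", index=False)
    bundle["channels"] = chan

    # --- bypass (Table-4 shaped) -----------------------------------------
    rep = bypass_report(
        net,
        R,
        grade_of,
        district_of_unit,
        district_of_hosp,
        B=cfg.bootstrap_B,
        seed=cfg.seed,
    )
    rep.differentials.to_csv(out / "report_bypass_differentials.csv", index=False)
    write_report(
        {
            "grade_shares": {
                c: rep.grade_shares[c].to_dict() for c in rep.grade_shares.columns
            },
            "upgrade_rates": rep.upgrade_rates,
            "bypass_premiums_km": {
                c: rep.bypass_premiums[c].to_dict() for c in rep.bypass_premiums.columns
            },
            "decomposition": rep.decomposition,
        },
        out / "report_bypass.json",
    )
    bundle["bypass"] = rep

    manifest["stages"]["reports"] = {
        "n_null_rows": len(null_rows),
        "n_channel_rows": len(chan),
    }
    write_report(manifest, out / "manifest.json")
    bundle["manifest"] = manifest
    return bundle
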