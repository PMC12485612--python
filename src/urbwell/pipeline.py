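"""End-to-end orchestration: delineate -> stratify -> associate -> report.

``run_all`` drives the full analysis from one :class:`RunConfig` on a
synthetic cohort: per city it generates nighttime-light rasters,
delineates natural-city masks by head/tail breaks, stacks them into
gradient rings, simulates posts and street-view counts inside the rings,
aggregates covariate surfaces zonally, and assembles the (city, ring)
panel; pooled across cities it computes level trends, the disparity
trajectory, correlations, per-city stepwise models with importance
counts, Geodetector q values and the regression-discontinuity linearity
check, plus a planted-coefficient recovery fit on a generated panel.
Everything is deterministic given the root seed, and the run report
records every artifact path, parameter and a checksum per artifact.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association as assoc
from . import natural_city as nc
from . import street_ecology as se
from . import swb_metrics as swb
from .raster import RasterGrid, write_ascii_grid
from .synthetic import (
    SimulationConfig,
    beta_quantile_truth,
    gen_city_panel,
    gen_covariate_raster,
    gen_ntl_series,
    gen_posts,
    gen_streetview_counts,
)

logger = logging.getLogger(__name__)

RASTER_FACTORS = ("NDVI", "AT", "RD", "POP", "PS", "GDP")
STREET_FACTORS = ("SE", "GN", "GY", "OP", "CR")


@dataclass
class RunConfig:
    """All stage parameters for one analysis run."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    n_cities: int = 3
    balance_tol: float = 0.05
    connectivity: int = 8
    min_cells: int = 4
    min_posts: int = 50
    min_rings: int = 10          # inclusion: strictly more rings than this
    min_street_points: int = 2000
    street_points_per_ring: int = 170
    quantiles: tuple[float, ...] = swb.DEFAULT_QUANTILES
    alpha_enter: float = 0.05
    alpha_remove: float = 0.10
    geodetector_bins: int = 5
    geodetector_levels: tuple[str, ...] = ("P1", "P8")
    geodetector_permutations: int = 199
    rd_factor: str = "NDVI"
    panel_zones: int = 500
    out_dir: str | None = None

    def validate(self) -> None:
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if not 0 < self.balance_tol <= 0.5:
            raise ValueError("balance_tol must lie in (0, 0.5]")
        for name in ("min_posts", "min_street_points", "panel_zones",
                     "street_points_per_ring", "n_cities"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**raw.pop("sim", {}))
        cfg = cls(sim=sim, **raw)
        cfg.validate()
        return cfg


def zonal_aggregate(
    raster: RasterGrid,
    zones: nc.GradientZones,
    min_valid: int = 1,
) -> pd.DataFrame:
    """Per-ring mean of valid raster cells.

    Nodata cells are excluded; rings with fewer than ``min_valid``
    contributing cells are flagged ``ok = False`` and carry NaN.
    """
    if raster.shape != zones.label.shape:
        raise ValueError("raster and zones are not aligned")
    valid = raster.valid_mask()
    rows = []
    for t in range(1, zones.n_rings + 1):
        cells = zones.ring_mask(t) & valid
        n = int(cells.sum())
        mean = float(raster.values[cells].mean()) if n >= min_valid else np.nan
        if n < min_valid:
            logger.warning("ring U%d has %d valid cells (< %d)", t, n, min_valid)
        rows.append({"ring": t, "mean": mean, "n_cells": n,
                     "ok": n >= min_valid})
    return pd.DataFrame(rows)


def filter_cities(summaries: pd.DataFrame, cfg: RunConfig) -> pd.DataFrame:
    """Apply the city-inclusion rule and log a reason per exclusion.

    A city is kept when it has strictly more than ``min_rings`` nonempty
    rings, at least ``min_posts`` posts in every ring, and at least
    ``min_street_points`` street-view sample points.  ``summaries``
    needs columns city_id, n_rings, min_posts_per_ring, n_street_points.
    """
    out = summaries.copy()
    reasons = []
    for _, row in out.iterrows():
        why = []
        if row["n_rings"] <= cfg.min_rings:
            why.append(f"rings <= {cfg.min_rings}")
        if row["min_posts_per_ring"] < cfg.min_posts:
            why.append(f"posts < {cfg.min_posts}")
        if row["n_street_points"] < cfg.min_street_points:
            why.append(f"street points < {cfg.min_street_points}")
        reasons.append("; ".join(why))
        if why:
            logger.info("city %s excluded: %s", row["city_id"], reasons[-1])
    out["included"] = [r == "" for r in reasons]
    out["exclusion_reason"] = reasons
    return out


def _street_mix(t: int, n_rings: int) -> np.ndarray:
    """Ring-dependent scene mixture: built-up core -> green periphery."""
    frac = (t - 1) / max(n_rings - 1, 1)
    mix = {
        "vegetation": 0.10 + 0.25 * frac,
        "sky": 0.15 + 0.10 * frac,
        "terrain": 0.05 + 0.05 * frac,
        "road": 0.15, "sidewalk": 0.05,
        "building": 0.30 - 0.25 * frac,
        "wall": 0.02, "fence": 0.02, "pole": 0.02,
        "traffic_light": 0.01, "traffic_sign": 0.01,
        "person": 0.04 - 0.02 * frac, "rider": 0.01,
        "car": 0.06 - 0.03 * frac, "truck": 0.01, "bus": 0.01,
        "train": 0.0, "motorcycle": 0.005, "bicycle": 0.005,
    }
    w = np.array([mix[c] for c in se.CLASSES])
    return w / w.sum()


def _delineate_city(ntl: list[RasterGrid], cfg: RunConfig) -> nc.GradientZones:
    # One common threshold for the whole year series (median of the
    # per-year head/tail thresholds): the series is jointly calibrated,
    # and a common cut keeps annual boundaries comparable instead of
    # letting the recursion's stopping depth jitter year to year.
    thresholds = [nc.head_tail_threshold(r, cfg.balance_tol).final_threshold
                  for r in ntl]
    common = float(np.median(thresholds))
    masks = []
    for year, raster in enumerate(ntl):
        comps = nc.delineate_natural_city(
            raster, common, cfg.connectivity, cfg.min_cells)
        member = np.zeros(raster.shape, dtype=bool)
        for m in comps:
            member |= m.member
        masks.append(nc.CityMask(member=member, year=year,
                                 cell_area=raster.cell_area()))
    return nc.build_gradient_zones(masks)


def _city_seed(root_seed: int, city: int) -> int:
    return (root_seed + 7919 * (city + 1)) % (2 ** 31)


def run_city(cfg: RunConfig, city: int) -> dict:
    """All single-city stages; returns panel pieces and summaries."""
    sim = cfg.sim.with_seed(_city_seed(cfg.sim.seed, city))
    ntl = gen_ntl_series(sim)
    zones = _delineate_city(ntl, cfg)

    cell_area = ntl[0].cell_area()
    cum = np.zeros(zones.label.shape, dtype=bool)
    areas = []
    for t in range(1, zones.n_rings + 1):
        cum |= zones.ring_mask(t)
        areas.append(cum.sum() * cell_area)
    r_pct = nc.expansion_rate(areas) if min(areas) > 0 else np.nan

    posts = gen_posts(zones, sim, raster=ntl[0])
    levels = swb.stratify_posts(posts, posts["ring"].to_numpy(),
                                min_posts=cfg.min_posts,
                                quantiles=cfg.quantiles)

    # street-view points, ring-dependent mixtures
    street_rows, n_points = [], 0
    for t in range(1, zones.n_rings + 1):
        if not zones.ring_mask(t).any():
            continue
        sub = replace(sim, seed=(sim.seed + 31 * t) % 2 ** 31,
                      sentiment_params=list(sim.sentiment_params))
        counts = gen_streetview_counts(
            cfg.street_points_per_ring, _street_mix(t, zones.n_rings), sub,
            mix_concentration=150.0, void_fraction=0.05)
        counts["point_id"] = counts["point_id"] + n_points
        counts["ring"] = t
        n_points += cfg.street_points_per_ring
        street_rows.append(counts)
    street = pd.concat(street_rows, ignore_index=True)
    pt_idx = se.indices_from_table(street)
    ring_of_point = street.groupby("point_id")["ring"].first()
    street_zone = se.aggregate_points(pt_idx, ring_of_point)

    covars = {}
    for k, name in enumerate(RASTER_FACTORS):
        direction = (np.cos(k * np.pi / 3), np.sin(k * np.pi / 3))
        surf = gen_covariate_raster(sim, name, direction=direction)
        covars[name] = zonal_aggregate(surf, zones)

    panel = levels[levels["ok"]].copy()
    panel.insert(0, "city_id", city)
    street_zone = street_zone.rename(columns={"zone": "ring"})
    panel = panel.merge(
        street_zone[["ring", *STREET_FACTORS]], on="ring", how="left")
    for name, tbl in covars.items():
        panel = panel.merge(
            tbl[["ring", "mean"]].rename(columns={"mean": name}),
            on="ring", how="left")

    summary = {
        "city_id": city,
        "n_rings": int((levels["n_posts"] > 0).sum()),
        "min_posts_per_ring": int(levels["n_posts"].min()),
        "n_street_points": n_points,
        "area_km2_final": areas[-1] if areas else 0.0,
        "area_km2_first": areas[0] if areas else 0.0,
        "r_pct_per_yr": r_pct,
    }
    return {"zones": zones, "panel": panel, "summary": summary,
            "areas": areas}


def run_all(cfg: RunConfig) -> dict:
    """Full deterministic analysis; returns a result bundle + report."""
    cfg.validate()
    results = [run_city(cfg, c) for c in range(cfg.n_cities)]
    summaries = pd.DataFrame([r["summary"] for r in results])
    summaries = filter_cities(summaries, cfg)
    included = set(summaries.loc[summaries["included"], "city_id"])
    panels = [r["panel"] for r in results
              if r["summary"]["city_id"] in included]
    if not panels:
        raise RuntimeError("no city passed the inclusion filter")
    pooled = pd.concat(panels, ignore_index=True).dropna()
    pooled = assoc.minmax_normalize(pooled)

    level_names = [f"P{k}" for k in range(1, len(cfg.quantiles) + 1)]

    # level trends: per-ring mean across cities, then OLS on ring index
    ring_means = pooled.groupby("ring")[level_names].mean()
    trends = pd.DataFrame([
        vars(swb.gradient_trend(ring_means[lev].to_numpy(),
                                ring_means.index.to_numpy(), level=lev))
        for lev in level_names
    ])

    # disparity trajectory and its relative change along the gradient
    _, per_ring = swb.inequality_profile(
        ring_means.reset_index(), level_names=tuple(level_names))
    disp = per_ring.sort_values("ring")["disparity"].to_numpy()
    disparity_change_pct = swb.relative_change(disp[0], disp[-1])

    per_level, _ = swb.inequality_profile(
        pooled, level_names=tuple(level_names))

    correlations = pd.concat(
        [assoc.level_factor_correlation(pooled, lev).assign(level=lev)
         for lev in level_names], ignore_index=True)

    stepwise_results = []
    for city in sorted(included):
        sub = pooled[pooled["city_id"] == city]
        for lev in level_names:
            if len(sub) <= len(assoc.FACTORS) + 2:
                continue
            stepwise_results.append(assoc.stepwise_fit(
                sub[lev], sub[list(assoc.FACTORS)],
                cfg.alpha_enter, cfg.alpha_remove, level=f"{city}:{lev}"))
    importance = assoc.importance_frequency(stepwise_results) \
        if stepwise_results else pd.DataFrame()

    rng = np.random.default_rng([97, cfg.sim.seed])
    geod = pd.concat(
        [assoc.geodetector_matrix(
            pooled, lev, k=cfg.geodetector_bins,
            n_permutations=cfg.geodetector_permutations, rng=rng,
        ).assign(level=lev) for lev in cfg.geodetector_levels],
        ignore_index=True)

    rd = {lev: assoc.rd_check(pooled[lev].to_numpy(),
                              pooled[cfg.rd_factor].to_numpy())
          for lev in level_names}
    rd_table = pd.DataFrame([
        {"level": lev, "cutoff": r.cutoff, "delta": r.delta,
         "linear": r.linear} for lev, r in rd.items()])

    # planted-coefficient recovery on a generated panel
    panel, truth = gen_city_panel(cfg.sim, n_zones=cfg.panel_zones)
    fit = assoc.stepwise_fit(panel["P1"], panel[list(assoc.FACTORS)],
                             cfg.alpha_enter, cfg.alpha_remove, level="P1")
    recovery = {
        "true_beta": truth["beta"],
        "true_active": truth["active"],
        "retained": fit.retained,
        "coefficients": fit.coefficients,
        "r_squared": fit.r_squared,
    }

    truth_q = beta_quantile_truth(cfg.sim.sentiment_params, cfg.quantiles)
    planted_trends = {
        lev: float(np.polyfit(np.arange(1, truth_q.shape[0] + 1),
                              truth_q[:, j], 1)[0]) * 100.0
        for j, lev in enumerate(level_names)
    }
    planted_disp = truth_q[:, -1] - truth_q[:, 0]
    planted_disparity_change_pct = swb.relative_change(
        planted_disp[0], planted_disp[-1])

    bundle = {
        "summaries": summaries, "panel": pooled, "trends": trends,
        "per_level": per_level, "disparity": per_ring,
        "disparity_change_pct": disparity_change_pct,
        "planted_trends_pct": planted_trends,
        "planted_disparity_change_pct": planted_disparity_change_pct,
        "correlations": correlations, "stepwise": stepwise_results,
        "importance": importance, "geodetector": geod, "rd": rd_table,
        "recovery": recovery,
        "n_models": len(stepwise_results),
        "zones": {r["summary"]["city_id"]: r["zones"] for r in results},
    }
    if cfg.out_dir is not None:
        bundle["report"] = write_outputs(bundle, cfg)
    return bundle


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_outputs(bundle: dict, cfg: RunConfig) -> dict:
    """Write CSV/ASC artifacts and the JSON run report; returns report."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts = {}

    tables = {
        "city_summaries.csv": bundle["summaries"],
        "panel.csv": bundle["panel"],
        "level_trends.csv": bundle["trends"],
        "level_summary.csv": bundle["per_level"],
        "disparity.csv": bundle["disparity"],
        "correlations.csv": bundle["correlations"],
        "importance.csv": bundle["importance"],
        "geodetector_q.csv": bundle["geodetector"],
        "rd_report.csv": bundle["rd"],
    }
    for name, df in tables.items():
        path = out / name
        df.to_csv(path, index=False)
        artifacts[name] = _sha256(path)

    sw = pd.DataFrame([
        {"model": r.level, "retained": "+".join(r.retained),
         "r_squared": r.r_squared, "model_p": r.model_p}
        for r in bundle["stepwise"]])
    sw_path = out / "stepwise_models.csv"
    sw.to_csv(sw_path, index=False)
    artifacts["stepwise_models.csv"] = _sha256(sw_path)

    for city, zones in bundle["zones"].items():
        path = out / f"zones_city{city}.asc"
        write_ascii_grid(RasterGrid(zones.label.astype(float)), path)
        artifacts[path.name] = _sha256(path)

    sim_cfg = asdict(cfg.sim)
    sim_cfg["sentiment_params"] = [list(p) for p in sim_cfg["sentiment_params"]]
    report = {
        "parameters": {
            **{k: v for k, v in vars(cfg).items() if k != "sim"},
            "sim": sim_cfg,
        },
        "n_models": bundle["n_models"],
        "disparity_change_pct": bundle["disparity_change_pct"],
        "planted_disparity_change_pct": bundle["planted_disparity_change_pct"],
        "artifacts": artifacts,
    }
    report["parameters"]["quantiles"] = list(cfg.quantiles)
    report["parameters"]["geodetector_levels"] = list(cfg.geodetector_levels)
    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report
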