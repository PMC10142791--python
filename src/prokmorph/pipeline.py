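"""Pipeline driver: simulate -> (render -> measure) -> classify -> stats.

One run generates per-station cell populations for each requested cruise,
optionally routes them through micrograph rendering and automated
measurement (with bead calibration), classifies morphotypes, summarises
each station sample, and computes the community statistics (Kruskal-Wallis
across cruises on cell volume, Shannon diversity per station, PCA of the
station x variable table). Outputs are plain CSV/JSON stamped with the
seed and a configuration hash; identical configurations produce
byte-identical outputs.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field as dfield
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .measure import Calibration, calibrate_with_beads, measure_image
from .morphometry import CarbonModel, cell_volume, classify_table, summarize_cells
from .profiles import (CRUISES, ENV_VARIABLES, CommunityProfile,
                       MorphotypeProfile, builtin_cruise_profiles)
from .render import FieldSpec, bead_field, render_micrograph
from .community_stats import kruskal_wallis, pca_ordination

log = logging.getLogger(__name__)

BEAD_DIAMETER_UM = 2.13


@dataclass
class PipelineConfig:
    cruises: tuple = CRUISES
    n_cells: int = 2000            # per cruise
    n_stations: int = 5            # per cruise
    seed: int = 0
    render: bool = False           # route cells through images + measurement
    field: FieldSpec = dfield(default_factory=FieldSpec)
    carbon_model: str = "flat:350"
    shannon_base: float = 2.0
    out_dir: str | None = None
    profiles_file: str | None = None

    def validate(self):
        known = set(CRUISES) | set(self._file_profiles() or {})
        unknown = [c for c in self.cruises if c not in known]
        if unknown:
            raise ValueError(f"unknown cruise(s): {unknown}")
        if self.n_cells <= 0 or self.n_stations <= 0:
            raise ValueError("n_cells and n_stations must be > 0")
        if self.render and self.n_cells // self.n_stations > 800:
            raise ValueError("too many cells per rendered field (max 800)")
        CarbonModel.from_string(self.carbon_model)
        if self.profiles_file and not Path(self.profiles_file).exists():
            raise FileNotFoundError(self.profiles_file)

    def _file_profiles(self):
        if not self.profiles_file or not Path(self.profiles_file).exists():
            return None
        return load_profiles_yaml(self.profiles_file)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("cruises", "n_cells", "n_stations", "seed", "render",
              "carbon_model", "shannon_base", "profiles_file")}
        d["field"] = vars(self.field).copy() if hasattr(self.field, "__dict__") \
            else {f: getattr(self.field, f) for f in self.field.__dataclass_fields__}
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "field" in raw:
            raw["field"] = FieldSpec(**raw["field"])
        if "cruises" in raw:
            raw["cruises"] = tuple(raw["cruises"])
        return cls(**raw)


def load_profiles_yaml(path) -> dict:
    """Community profiles from YAML: label -> {density, composition, morphotypes}."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    out = {}
    for label, spec in raw.items():
        profs = tuple(MorphotypeProfile(morphotype=m, **p)
                      for m, p in spec["morphotypes"].items())
        out[label] = CommunityProfile(
            cruise_label=label,
            composition={m: float(f) for m, f in spec["composition"].items()},
            density=float(spec.get("density", 1.0e6)),
            profiles=profs)
    return out


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
            log.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)
            return result
        return inner
    return wrap


@_stage("measure")
def _measure_station(cells, cfg, calibration, seed):
    img, truth = render_micrograph(cells, cfg.field, seed=seed)
    measured = measure_image(img, cfg.field.pixel_size, calibration)
    return pd.DataFrame({
        "cell_id": np.arange(len(measured)),
        "cruise": truth["cruise"].iloc[0] if len(truth) else "",
        "station": truth["station"].iloc[0] if len(truth) else "",
        "depth_m": truth["depth_m"].iloc[0] if len(truth) else 0.0,
        "L_um": [c.L_um for c in measured],
        "W_um": [c.W_um for c in measured],
        "curvature_class": [c.curvature_class for c in measured],
    })


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns tables and writes them if out_dir set.

    Returns a dict with ``cells`` (per-cruise tables), ``summary``
    (station rows with environmental covariates), ``kruskal_wallis``,
    ``ordination`` and (when ``out_dir`` is set) the written paths.
    """
    from .synthetic import sample_cells, sample_environment

    config.validate()
    chash = pio.config_hash(config.to_dict())
    meta = {"seed": config.seed, "config_hash": chash}
    profiles = config._file_profiles() or builtin_cruise_profiles()
    carbon = CarbonModel.from_string(config.carbon_model)

    calibration = None
    if config.render:
        beads = bead_field(24, BEAD_DIAMETER_UM, config.field,
                           seed=np.random.SeedSequence([config.seed, 1]))
        bead_img, _ = render_micrograph(beads, config.field,
                                        seed=np.random.SeedSequence([config.seed, 2]))
        calibration = calibrate_with_beads(bead_img, BEAD_DIAMETER_UM,
                                           config.field.pixel_size)

    cells_by_cruise = {}
    summary_rows = []
    vol_by_cruise = {}
    for ci, cruise in enumerate(config.cruises):
        profile = profiles[cruise]
        env = sample_environment(cruise, config.n_stations,
                                 seed=np.random.SeedSequence([config.seed, ci, 101]))
        per_station = config.n_cells // config.n_stations
        station_tables = []
        for si in range(config.n_stations):
            truth = sample_cells(profile, per_station,
                                 seed=np.random.SeedSequence([config.seed, ci, si]),
                                 station=env["station"].iloc[si],
                                 depth_m=float(env["depth_m"].iloc[si]))
            if config.render:
                cells = _measure_station(
                    truth, config, calibration,
                    np.random.SeedSequence([config.seed, ci, si, 7]))
                cells["cruise"] = cruise
                cells["station"] = env["station"].iloc[si]
            else:
                cells = truth
            cells = cells.copy()
            cells["morphotype"] = classify_table(cells)
            station_tables.append(cells)
            summ = summarize_cells(cells, PA=profile.density,
                                   carbon_model=carbon,
                                   shannon_base=config.shannon_base)
            row = {"cruise": cruise, "station": env["station"].iloc[si],
                   "depth_m": float(env["depth_m"].iloc[si])}
            row.update(summ.to_row())
            for v in ENV_VARIABLES:
                row[v] = float(env[v].iloc[si])
            summary_rows.append(row)
        table = pd.concat(station_tables, ignore_index=True)
        table["cell_id"] = np.arange(len(table))
        cells_by_cruise[cruise] = table
        vol_by_cruise[cruise] = cell_volume(table["L_um"].to_numpy(),
                                            table["W_um"].to_numpy())

    summary = pd.DataFrame(summary_rows)
    kw = (kruskal_wallis(list(vol_by_cruise.values()))
          if len(vol_by_cruise) >= 2 else None)

    ord_cols = ["PA", "PB", "mean_VOL", "depth_m", *ENV_VARIABLES]
    mat = summary[ord_cols]
    keep = [c for c in ord_cols if mat[c].nunique() > 1]
    dropped = sorted(set(ord_cols) - set(keep))
    if dropped:
        log.warning("ordination: dropped constant column(s) %s", dropped)
    ordination = pca_ordination(mat[keep]) if len(keep) >= 2 and len(mat) >= 3 else None

    result = {"cells": cells_by_cruise, "summary": summary,
              "kruskal_wallis": kw, "ordination": ordination,
              "config_hash": chash}

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for cruise, table in cells_by_cruise.items():
            slug = cruise.lower().replace("-", "_")
            paths[f"cells_{cruise}"] = pio.write_cell_table(
                table, out / f"cells_{slug}.csv", metadata=meta)
        with open(out / "summary.csv", "w", newline="") as fh:
            fh.write(pio._metadata_lines(meta))
            summary.to_csv(fh, index=False)
        paths["summary"] = out / "summary.csv"
        stats_obj = {}
        if kw is not None:
            stats_obj["kruskal_wallis_VOL"] = {
                "statistic": kw.statistic, "p_value": kw.p_value,
                "df": kw.df, "group_sizes": list(kw.group_sizes)}
        stats_obj["shannon_range_per_cruise"] = {
            c: [float(summary.loc[summary["cruise"] == c, "H_prime"].min()),
                float(summary.loc[summary["cruise"] == c, "H_prime"].max())]
            for c in config.cruises}
        if ordination is not None:
            stats_obj["pca_variance_explained_pct"] = ordination.variance_explained
            ordination.loadings.to_csv(out / "pca_loadings.csv")
            ordination.scores.to_csv(out / "pca_scores.csv")
            paths["pca_loadings"] = out / "pca_loadings.csv"
            paths["pca_scores"] = out / "pca_scores.csv"
        paths["stats"] = pio.write_json(stats_obj, out / "stats.json", metadata=meta)
        result["paths"] = paths
    return result
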