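"""End-to-end pipeline: generate -> lock-in -> cost -> climate -> connect ->
scenarios -> benefits -> report.

The pipeline is a pure function of (config, seed): every stage writes its
outputs into a shared artifact directory and is skipped on re-runs when
those outputs already exist, so deleting a late stage's files and re-running
recomputes only that stage.  A structured run log records, per stage,
whether it was computed or loaded from disk along with its key parameters
and counts.
"""

from __future__ import annotations

import dataclasses
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import benefits as benefits_mod
from . import cost as cost_mod
from . import lockin as lockin_mod
from . import marxan_io as io_mod
from .climate import (
    TrajectoryParams,
    degradation_rate,
    interpolate_to_grid,
    run_trajectory,
)
from .objectives import OBJECTIVES, build_scenario
from .prioritizer import RunEnsemble, Solution, objective_score, run_scenario
from .seascape import SeascapeConfig, generate_seascape


class ConfigError(ValueError):
    """Raised for malformed pipeline configuration."""


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one full analysis.

    Unknown keys in a config file are rejected rather than ignored so typos
    cannot silently change a run.
    """

    out_dir: str = "artifacts"
    seed: int = 0
    seascape: SeascapeConfig = field(default_factory=SeascapeConfig)
    objectives: tuple[str, ...] = OBJECTIVES
    n_runs: int = 100
    iterations: int | None = None
    init_fraction: float = 0.3
    conn_weight_scale: float = 0.1
    spf: float | None = None
    catchment_radius_km: float = 20.0
    benefit_threshold: float = 0.5
    hotspot_percentile: float = 75.0
    decile_percentile: float = 90.0
    n_clusters: int = 4
    delimiter: str = ","
    verbose: bool = False

    def __post_init__(self) -> None:
        unknown = set(self.objectives) - set(OBJECTIVES)
        if unknown:
            raise ConfigError(f"unknown objectives: {sorted(unknown)}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["objectives"] = list(self.objectives)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "seascape" in data and isinstance(data["seascape"], dict):
            sknown = {f.name for f in dataclasses.fields(SeascapeConfig)}
            sunknown = set(data["seascape"]) - sknown
            if sunknown:
                raise ConfigError(f"unknown seascape keys: {sorted(sunknown)}")
            data["seascape"] = SeascapeConfig(**data["seascape"])
        if "objectives" in data:
            data["objectives"] = tuple(data["objectives"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


STAGES = (
    "generate", "lockin", "cost", "climate", "connect",
    "scenario", "benefits", "report",
)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _province_geojson(planning_units: pd.DataFrame, cell_size: float,
                      properties: dict[int, dict]) -> dict:
    from shapely.geometry import box, mapping
    from shapely.ops import unary_union

    features = []
    for province, grp in planning_units.groupby("province"):
        cells = [
            box(c * cell_size, r * cell_size, (c + 1) * cell_size, (r + 1) * cell_size)
            for r, c in zip(grp["row"], grp["col"])
        ]
        geom = unary_union(cells)
        props = {"province": int(province), "country": int(grp["country"].iloc[0])}
        props.update(properties.get(int(province), {}))
        features.append(
            {"type": "Feature", "geometry": mapping(geom), "properties": props}
        )
    return {"type": "FeatureCollection", "features": features}


def _linkage_json(Z: np.ndarray, labels: list[str]):
    from scipy.cluster.hierarchy import to_tree

    def recurse(node):
        if node.is_leaf():
            return labels[node.id]
        return [recurse(node.left), recurse(node.right), round(float(node.dist), 6)]

    return recurse(to_tree(Z))


class Pipeline:
    """Stage runner over a shared artifact directory."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.log: list[dict] = []
        self._scape = None
        self._ensembles: dict[str, RunEnsemble] = {}
        self._eligible: dict[str, np.ndarray] = {}
        self._benefits: pd.DataFrame | None = None

    # -- logging -----------------------------------------------------

    def _record(self, stage: str, cached: bool, **info) -> None:
        entry = {"stage": stage, "cached": cached, "time": time.time(), **info}
        self.log.append(entry)
        if self.config.verbose:
            print(f"[reefplan] {stage}: {'cached' if cached else 'computed'} {info}")

    def _write_log(self) -> None:
        (self.out / "run_log.json").write_text(json.dumps(self.log, indent=2))

    # -- stages ------------------------------------------------------

    def stage_generate(self):
        directory = self.out / "seascape"
        sep = self.config.delimiter
        if (directory / "seascape.json").exists():
            self._scape = io_mod.read_seascape(directory, sep)
            self._record("generate", cached=True, n_units=self._scape.n_units)
        else:
            try:
                self._scape = generate_seascape(self.config.seascape)
            except Exception as exc:
                raise PipelineError("generate", exc) from exc
            io_mod.write_seascape(self._scape, directory, sep)
            self._record(
                "generate", cached=False,
                n_units=self._scape.n_units, seed=self.config.seascape.seed,
                checksum=self._scape.checksum(),
            )
        return self._scape

    def stage_lockin(self) -> set[int]:
        scape = self.stage_generate()
        path = self.out / "locked.csv"
        if path.exists():
            locked = set(pd.read_csv(path)["pu_id"].tolist())
            self._record("lockin", cached=True, n_locked=len(locked))
            return locked
        try:
            locked = lockin_mod.locked_union(
                scape.mpas, scape.habitat_amounts, self.config.seed
            )
        except Exception as exc:
            raise PipelineError("lockin", exc) from exc
        pd.DataFrame({"pu_id": sorted(locked)}).to_csv(path, index=False)
        self._record("lockin", cached=False, n_locked=len(locked),
                     seed=self.config.seed)
        return locked

    def stage_cost(self) -> pd.Series:
        scape = self.stage_generate()
        path = self.out / "cost.csv"
        if path.exists():
            frame = pd.read_csv(path, index_col="pu_id")
            self._record("cost", cached=True)
            return frame["cost"]
        try:
            costs = cost_mod.build_cost(
                scape.planning_units["fishing_profit"],
                scape.planning_units["population_density"],
                scape.habitat_amounts,
            )
        except Exception as exc:
            raise PipelineError("cost", exc) from exc
        costs.rename_axis("pu_id").to_csv(path)
        self._record("cost", cached=False, total_cost=float(costs.sum()))
        return costs

    def stage_climate(self) -> pd.Series:
        scape = self.stage_generate()
        path = self.out / "degradation.csv"
        if path.exists():
            frame = pd.read_csv(path, index_col="pu_id")
            self._record("climate", cached=True)
            return frame["rate"]
        try:
            traj = run_trajectory(scape.forcing, TrajectoryParams())
            coarse_d = degradation_rate(traj)
            fine = interpolate_to_grid(
                coarse_d, scape.forcing,
                scape.planning_units[["x_km", "y_km"]].to_numpy(),
            )
        except Exception as exc:
            raise PipelineError("climate", exc) from exc
        rates = pd.Series(
            np.clip(fine, 0.0, 1.0), index=scape.planning_units.index, name="rate"
        )
        rates.rename_axis("pu_id").to_csv(path)
        self._record("climate", cached=False,
                     mean_degradation=float(rates.mean()))
        return rates

    def stage_scenario(self, objective: str) -> RunEnsemble:
        if objective in self._ensembles:
            return self._ensembles[objective]
        scape = self.stage_generate()
        locked = self.stage_lockin()
        costs = self.stage_cost()
        degradation = self.stage_climate() if objective == "climate" else None
        cfg = self.config
        try:
            scenario = build_scenario(
                scape, objective, degradation=degradation,
                locked=locked, costs=costs,
                conn_weight_scale=cfg.conn_weight_scale, spf=cfg.spf,
                n_runs=cfg.n_runs, seed=cfg.seed,
                iterations=cfg.iterations, init_fraction=cfg.init_fraction,
            )
        except Exception as exc:
            raise PipelineError("scenario", exc) from exc
        self._eligible[objective] = benefits_mod.eligible_units(scenario)
        directory = self.out / "scenarios" / objective
        ssoln = directory / "ssoln.csv"
        best_path = directory / "best.csv"
        if ssoln.exists() and best_path.exists():
            freq_frame = pd.read_csv(ssoln, index_col="pu_id")
            best_frame = pd.read_csv(best_path, index_col="pu_id")
            sel = best_frame["selected"].to_numpy().astype(bool)
            best = Solution(selected=sel, breakdown=objective_score(sel, scenario))
            ensemble = RunEnsemble(
                scenario_name=objective,
                solutions=[],
                selection_frequency=freq_frame["frequency"],
                best=best,
            )
            self._record("scenario", cached=True, objective=objective)
        else:
            directory.mkdir(parents=True, exist_ok=True)
            io_mod.write_scenario(scenario, directory, cfg.delimiter)
            try:
                ensemble = run_scenario(scenario)
            except Exception as exc:
                raise PipelineError("scenario", exc) from exc
            counts = (ensemble.selection_frequency * scenario.n_runs).round()
            pd.DataFrame(
                {
                    "pu_id": scenario.pu_ids,
                    "count": counts.to_numpy().astype(int),
                    "frequency": ensemble.selection_frequency.to_numpy(),
                }
            ).to_csv(ssoln, index=False)
            pd.DataFrame(
                {
                    "pu_id": scenario.pu_ids,
                    "selected": ensemble.best.selected.astype(int),
                }
            ).to_csv(best_path, index=False)
            (directory / "objective.json").write_text(
                json.dumps(
                    {
                        "best_total": ensemble.best.total,
                        "best_cost": ensemble.best.breakdown.cost,
                        "best_shortfall": ensemble.best.breakdown.shortfall_total,
                        "best_connectivity": ensemble.best.breakdown.connectivity,
                        "run_totals": [s.total for s in ensemble.solutions],
                    },
                    indent=2,
                )
            )
            self._record(
                "scenario", cached=False, objective=objective,
                n_runs=scenario.n_runs, seed=scenario.seed,
                best_total=ensemble.best.total,
            )
        self._ensembles[objective] = ensemble
        return ensemble

    def stage_benefits(self):
        if self._benefits is not None:
            return self._benefits
        cfg = self.config
        directory = self.out / "benefits"
        bpath = directory / "benefits.csv"
        ensembles = {obj: self.stage_scenario(obj) for obj in cfg.objectives}
        if bpath.exists():
            table = pd.read_csv(bpath, index_col="province")
            self._record("benefits", cached=True)
            self._benefits = table
            return table
        directory.mkdir(parents=True, exist_ok=True)
        scape = self.stage_generate()
        try:
            table = benefits_mod.benefit_table(
                ensembles, scape.planning_units["province"], self._eligible
            )
        except Exception as exc:
            raise PipelineError("benefits", exc) from exc
        countries = scape.planning_units.groupby("province")["country"].first()
        table.rename_axis("province").join(countries).to_csv(bpath)
        self._record("benefits", cached=False, n_provinces=len(table))
        self._benefits = table
        return table

    def stage_report(self):
        cfg = self.config
        directory = self.out / "benefits"
        table = self.stage_benefits()
        table = table.drop(columns=["country"], errors="ignore")
        geo_path = directory / "hotspots.geojson"
        nwk_path = directory / "dendrogram.nwk"
        if geo_path.exists() and nwk_path.exists():
            self._record("report", cached=True)
            return
        scape = self.stage_generate()
        try:
            hotspots = benefits_mod.find_hotspots(table, cfg.hotspot_percentile)
            comp = benefits_mod.complementarity_cluster(
                table, cfg.n_clusters, cfg.decile_percentile
            )
        except Exception as exc:
            raise PipelineError("report", exc) from exc
        props = {
            int(p): {
                "objective_count": int(hotspots.counts[p]),
                "hotspot": bool(hotspots.hotspot[p]),
                **{f"benefit_{obj}": float(table.loc[p, obj]) for obj in table},
            }
            for p in table.index
        }
        geo = _province_geojson(
            scape.planning_units, scape.config.cell_size_km, props
        )
        geo_path.write_text(json.dumps(geo))
        nwk_path.write_text(comp.newick + "\n")
        (directory / "dendrogram.json").write_text(
            json.dumps(
                {
                    "tree": _linkage_json(
                        comp.linkage_matrix, [str(p) for p in table.index]
                    ),
                    "clusters": {
                        str(c): sorted(objs)
                        for c, objs in comp.cluster_objectives.items()
                    },
                    "top_decile": {
                        obj: sorted(int(p) for p in provs)
                        for obj, provs in comp.top_decile.items()
                    },
                },
                indent=2,
            )
        )
        self._render_figures(table, hotspots, comp, directory)
        self._record(
            "report", cached=False,
            n_hotspots=int(hotspots.hotspot.sum()),
        )

    def _render_figures(self, table, hotspots, comp, directory) -> None:
        try:
            import matplotlib

            matplotlib.use("Agg")
            import matplotlib.pyplot as plt
            from scipy.cluster.hierarchy import dendrogram

            fig, ax = plt.subplots(figsize=(6, 4))
            dendrogram(
                comp.linkage_matrix,
                labels=[str(p) for p in table.index],
                ax=ax,
                color_threshold=0.0,
            )
            ax.set_ylabel("Euclidean dissimilarity")
            fig.tight_layout()
            fig.savefig(directory / "dendrogram.png", dpi=100)
            plt.close(fig)

            fig, ax = plt.subplots(figsize=(5, 4))
            ax.bar(
                [str(p) for p in hotspots.counts.index],
                hotspots.counts.to_numpy(),
                color=["firebrick" if h else "steelblue" for h in hotspots.hotspot],
            )
            ax.set_xlabel("province")
            ax.set_ylabel("objectives in upper quartile")
            fig.tight_layout()
            fig.savefig(directory / "hotspot_counts.png", dpi=100)
            plt.close(fig)
        except Exception as exc:  # rendering is best-effort
            warnings.warn(f"figure rendering skipped: {exc}", stacklevel=2)

    def run(self, until: str = "report") -> Path:
        if until not in STAGES:
            raise ConfigError(f"unknown stage {until!r}")
        order = STAGES[: STAGES.index(until) + 1]
        for stage in order:
            if stage == "generate":
                self.stage_generate()
            elif stage == "lockin":
                self.stage_lockin()
            elif stage == "cost":
                self.stage_cost()
            elif stage == "climate":
                self.stage_climate()
            elif stage == "connect":
                pass  # connectivity matrices are built inside their scenarios
            elif stage == "scenario":
                for objective in self.config.objectives:
                    self.stage_scenario(objective)
            elif stage == "benefits":
                self.stage_benefits()
            elif stage == "report":
                self.stage_report()
        self._write_log()
        return self.out


def run_pipeline(config: PipelineConfig, until: str = "report") -> Path:
    """Run (or resume) the full analysis; returns the artifact directory."""
    return Pipeline(config).run(until)
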