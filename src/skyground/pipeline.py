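"""End-to-end orchestration from a single YAML/JSON config.

Stage order is fixed: simulate -> traits -> ground metrics -> spectral
clean -> spectral metrics -> associations -> predictions -> PCD.  Each
stage writes plain-text outputs under the run directory and registers them
in a manifest (with checksums and the seeds used) so every file is
reachable from it.  A stage failure halts the run, naming the stage and
preserving partial outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ground_metrics, models, pcd, phylo_traits, spectral_metrics, spectral_processing
from ._seeds import child_seed
from .synthetic import ScenarioConfig, simulate_landscape

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "validate_config", "run_pipeline", "ConfigError"]

STAGES = ("simulate", "traits", "ground_metrics", "clean", "spectral_metrics",
          "associations", "predictions", "pcd")


class ConfigError(ValueError):
    pass


_SCENARIO_KEYS = {f.name for f in dataclasses.fields(ScenarioConfig)}


@dataclass(frozen=True)
class RunConfig:
    out_dir: str
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    q_orders: tuple[int, ...] = (0, 1, 2)
    n_null: int = 999
    pixel_cap: int = 400
    k_range: tuple[int, int] | None = None
    mcmc: models.MCMCConfig = field(default_factory=models.MCMCConfig)
    pcd_reps: int = 2000
    min_valid_fraction: float = 0.25


def validate_config(raw: dict | str) -> RunConfig:
    """Typed validation with actionable messages; unknown keys rejected."""
    if isinstance(raw, str):
        import yaml

        raw = yaml.safe_load(raw)
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    raw = dict(raw)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "out_dir" not in raw:
        raise ConfigError("missing required key 'out_dir'")
    if "q_orders" in raw:
        qs = tuple(raw["q_orders"])
        bad = [q for q in qs if q not in (0, 1, 2)]
        if bad:
            raise ConfigError(f"q_orders {bad} not allowed; allowed orders are 0, 1, 2")
        raw["q_orders"] = qs
    if "stages" in raw:
        bad = [s for s in raw["stages"] if s not in STAGES]
        if bad:
            raise ConfigError(f"unknown stages {bad}; known: {STAGES}")
        raw["stages"] = tuple(raw["stages"])
    if "scenario" in raw:
        sc = dict(raw["scenario"])
        unknown = set(sc) - _SCENARIO_KEYS
        if unknown:
            raise ConfigError(f"unknown scenario keys: {sorted(unknown)}")
        for tup_key in ("richness_range", "pixel_grid"):
            if tup_key in sc:
                sc[tup_key] = tuple(sc[tup_key])
        try:
            raw["scenario"] = ScenarioConfig(**sc)
        except (TypeError, ValueError) as err:
            raise ConfigError(f"invalid scenario: {err}") from err
    if "mcmc" in raw:
        raw["mcmc"] = models.MCMCConfig(**dict(raw["mcmc"]))
    if "k_range" in raw and raw["k_range"] is not None:
        raw["k_range"] = tuple(raw["k_range"])
    for count_key in ("n_null", "pixel_cap", "pcd_reps"):
        if count_key in raw and int(raw[count_key]) < 1:
            raise ConfigError(f"{count_key} must be positive")
    try:
        return RunConfig(**raw)
    except TypeError as err:
        raise ConfigError(str(err)) from err


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns (and writes) the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "outputs": {}}

    def register(name: str, path: Path):
        manifest["outputs"][name] = {"path": str(path), "sha256": _sha256(path)}

    state: dict = {}
    current = None
    try:
        for stage in config.stages:
            current = stage
            log.info("stage %s", stage)
            if stage == "simulate":
                land = simulate_landscape(
                    dataclasses.replace(config.scenario, seed=config.seed)
                )
                state["land"] = land
                land.community.to_csv(out / "community.csv", index=False)
                register("community", out / "community.csv")
                land.pool.traits.to_csv(out / "traits.csv")
                register("traits", out / "traits.csv")
                from .trees import write_newick

                write_newick(land.pool.phylogeny, str(out / "phylogeny.nwk"))
                register("phylogeny", out / "phylogeny.nwk")
                truth = pd.DataFrame(
                    [(p, t["richness"]) for p, t in land.truth.items()],
                    columns=["plot", "true_richness"],
                )
                truth.to_csv(out / "truth.csv", index=False)
                register("truth", out / "truth.csv")
            elif stage == "traits":
                land = state["land"]
                labels, G = phylo_traits.gower_distance(land.pool.traits)
                state["trait_dist"] = (labels, G)
                from .trees import root_age

                dend = phylo_traits.build_trait_dendrogram(
                    labels, G, root_age(land.pool.phylogeny)
                )
                state["dendrogram"] = dend
                from .trees import write_newick

                write_newick(dend, str(out / "trait_dendrogram.nwk"))
                register("trait_dendrogram", out / "trait_dendrogram.nwk")
            elif stage == "ground_metrics":
                land = state["land"]
                gm = ground_metrics.community_metric_table(
                    land.community,
                    trait_dist=state.get("trait_dist"),
                    tree=land.pool.phylogeny,
                    q_orders=config.q_orders,
                    n_null=config.n_null,
                    seed=child_seed(config.seed, "ses_null"),
                )
                state["ground"] = gm
                gm.to_csv(out / "ground_metrics.csv", index=False)
                register("ground_metrics", out / "ground_metrics.csv")
            elif stage == "clean":
                land = state["land"]
                cleaned, qc = {}, []
                for plot, cube in land.cubes.items():
                    res = spectral_processing.clean_plot_pipeline(
                        cube, min_valid_fraction=config.min_valid_fraction
                    )
                    ok = not isinstance(res, spectral_processing.PlotRejection)
                    qc.append((plot, ok, res.valid_fraction))
                    if ok:
                        cleaned[plot] = res
                state["cleaned"] = cleaned
                pd.DataFrame(qc, columns=["plot", "retained", "valid_fraction"]).to_csv(
                    out / "clean_qc.csv", index=False
                )
                register("clean_qc", out / "clean_qc.csv")
            elif stage == "spectral_metrics":
                rows = []
                cl_seed = child_seed(config.seed, "cluster")
                for i, (plot, cube) in enumerate(sorted(state["cleaned"].items())):
                    vals = spectral_metrics.plot_spectral_metrics(
                        cube, k_range=config.k_range, cap=config.pixel_cap,
                        seed=(cl_seed + i) & 0x7FFFFFFF,
                    )
                    for m, v in vals.items():
                        rows.append((plot, m, v))
                sm = pd.DataFrame(rows, columns=["plot", "metric", "value"])
                state["spectral"] = sm
                sm.to_csv(out / "spectral_metrics.csv", index=False)
                register("spectral_metrics", out / "spectral_metrics.csv")
            elif stage == "associations":
                tab = _merge_tables(state)
                state["merged"] = tab
                fits = []
                for pair in models.model_pair_registry():
                    if not pair.counted:
                        continue
                    sub = _pair_data(tab, pair)
                    if sub is None or len(sub) < 20 or sub["site"].nunique() < 2:
                        continue
                    fit = models.fit_bmlm(
                        sub["y"], sub["x"], sub["site"],
                        dataclasses.replace(config.mcmc, seed=child_seed(config.seed, "mcmc")),
                    )
                    beta = fit.flat("beta")
                    r2c = models.bayes_r2(fit, conditional=True)
                    fits.append({
                        "dimension": pair.dimension, "response": pair.response,
                        "response_q": pair.response_q, "covariate": pair.covariate,
                        "beta_median": float(np.median(beta)),
                        "beta_lo": float(np.percentile(beta, 2.5)),
                        "beta_hi": float(np.percentile(beta, 97.5)),
                        "er_pos": models.evidence_ratio(fit),
                        "r2_conditional": r2c["median"],
                        "rhat_max": max(fit.rhat.values()),
                        "ess_min": min(fit.ess_bulk.values()),
                    })
                assoc = pd.DataFrame(fits)
                state["assoc"] = assoc
                assoc.to_csv(out / "associations.csv", index=False)
                register("associations", out / "associations.csv")
            elif stage == "predictions":
                tab = state.get("merged") or _merge_tables(state)
                rows = []
                for pair in models.model_pair_registry():
                    if not pair.counted:
                        continue
                    sub = _pair_data(tab, pair)
                    if sub is None or len(sub) < 40:
                        continue
                    sc = models.train_test_predict(
                        sub["y"], sub["x"], sub["site"],
                        seed=child_seed(config.seed, "split"),
                        config=dataclasses.replace(config.mcmc, seed=child_seed(config.seed, "mcmc")),
                    )
                    rows.append({
                        "dimension": pair.dimension, "response": pair.response,
                        "response_q": pair.response_q, "covariate": pair.covariate,
                        "rho": sc.rho, "smape": sc.smape, "rmsle": sc.rmsle,
                        "deviation": sc.deviation,
                    })
                pred = pd.DataFrame(rows)
                pred.to_csv(out / "prediction_scores.csv", index=False)
                register("prediction_scores", out / "prediction_scores.csv")
            elif stage == "pcd":
                land = state["land"]
                frames = []
                ps = child_seed(config.seed, "pcd")
                frames.append(pcd.pcd_matrix(
                    land.pool.phylogeny, land.community, reps=config.pcd_reps,
                    seed=ps, dimension="phylogenetic"))
                if "dendrogram" in state:
                    frames.append(pcd.pcd_matrix(
                        state["dendrogram"], land.community, reps=config.pcd_reps,
                        seed=ps, dimension="trait"))
                allpcd = pd.concat(frames, ignore_index=True)
                allpcd.to_csv(out / "pcd.csv", index=False)
                register("pcd", out / "pcd.csv")
            manifest["stages"][stage] = "completed"
    except Exception as err:
        manifest["stages"][current] = f"failed: {err}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise RuntimeError(f"pipeline halted in stage {current!r}: {err}") from err

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _merge_tables(state: dict) -> dict:
    """Bundle the long ground table with the wide spectral table."""
    gm: pd.DataFrame = state["ground"]
    sm: pd.DataFrame = state["spectral"]
    wide = sm.pivot(index="plot", columns="metric", values="value").reset_index()
    return {"ground": gm, "spectral": wide}


def _pair_data(tab: dict, pair) -> pd.DataFrame | None:
    """Aligned (y, x, site) rows for one registry pair, or None if absent."""
    gm: pd.DataFrame = tab["ground"]
    wide: pd.DataFrame = tab["spectral"]
    resp = pair.response
    use_z = resp.endswith("z")
    metric = resp[:-1] if use_z else resp
    sel = gm["metric"] == metric
    if pair.response_q is not None and metric not in ("S", "H", "D"):
        sel &= gm["q"] == pair.response_q
    sub = gm.loc[sel, ["plot", "site", "value", "z"]].copy()
    if sub.empty:
        return None
    sub["y"] = sub["z"] if use_z else sub["value"]
    xcol = f"SS_q{int(pair.covariate_q)}" if pair.covariate == "SS" else pair.covariate
    if xcol not in wide.columns:
        return None
    sub = sub.merge(wide[["plot", xcol]], on="plot").rename(columns={xcol: "x"})
    sub = sub.dropna(subset=["y", "x"])
    return sub[["plot", "site", "y", "x"]] if not sub.empty else None
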