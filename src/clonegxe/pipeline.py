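"""End-to-end orchestration: simulate/load -> cluster -> fit -> summarize
-> ranks -> response surface.

A single YAML (or dict) config drives the whole analysis with one seed.
Each stage writes plain CSV/JSON artifacts into the output directory and
records a signature (config subset + input checksums) in a manifest;
rerunning with unchanged inputs reuses completed outputs.  Stage-tagged
log lines go to standard error.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from clonegxe import clustering as cl
from clonegxe import io as cio
from clonegxe import ranking as rk
from clonegxe import synthetic as syn
from clonegxe import urf as urfmod
from clonegxe.genetics import summarize
from clonegxe.mixed_model import MCMCOptions, ModelSpec, gibbs_sample, standardize_phenotypes

logger = logging.getLogger("clonegxe.pipeline")

__all__ = ["PipelineConfig", "validate_config", "run_pipeline"]

STAGES = ["data", "cluster", "fit", "summarize", "ranks", "urf"]

_DEFAULT_SYNTHETIC = {
    "n_sites": 6,
    "n_locations": 30,
    "reps_per_site": 3,
    "blocks_per_rep": 2,
    "ramets_per_genotype_per_site": 2,
    "sigma2_pop": 0.41,
    "sigma2_gen": 0.35,
    "sigma2_rep": 0.01,
    "sigma2_block": 0.01,
    "sigma2_resid": 0.65,
    "corr_pop": 0.99,
    "corr_gen": 0.75,
    "grid_bounds": [166.0, 179.0, -47.0, -34.0],
    "grid_resolution": 1.0,
}

_DEFAULT_CLUSTERING = {
    "variables": [
        "latitude",
        "distance_from_coast",
        "elevation",
        "tmax",
        "tmin",
        "precipitation",
    ],
    "k_range": [2, 10],
    "scenario": "best",
}

_DEFAULT_MCMC = {"iterations": 500_000, "burn_in": 50_000, "thinning": 10}
_DEFAULT_URF = {"variables": ["tmax", "precipitation"], "cluster": "best"}


@dataclass
class PipelineConfig:
    seed: int
    output_dir: str
    trait: str
    data: dict
    clustering: dict
    mcmc: dict
    urf: dict

    def mcmc_options(self) -> MCMCOptions:
        return MCMCOptions(seed=self.seed, **self.mcmc)


def _reject_unknown(block: dict, allowed: set[str], where: str):
    unknown = set(block) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) in {where}: {sorted(unknown)}")


def validate_config(source) -> PipelineConfig:
    """Normalize a config path/dict into a validated PipelineConfig.

    Fills documented defaults (full-length MCMC settings), rejects unknown
    keys, and enforces basic sanity (burn-in below iterations, exactly one
    data source).
    """
    if isinstance(source, dict):
        raw = dict(source)
    else:
        with open(source) as fh:
            raw = yaml.safe_load(fh)
    _reject_unknown(raw, {"seed", "output_dir", "trait", "data", "clustering", "mcmc", "urf"}, "config")
    for key in ("seed", "output_dir", "data"):
        if key not in raw:
            raise ValueError(f"missing required config key: {key!r}")
    data = dict(raw["data"])
    _reject_unknown(data, {"synthetic", "paths"}, "data")
    if ("synthetic" in data) == ("paths" in data):
        raise ValueError("data must contain exactly one of 'synthetic' or 'paths'")
    if "synthetic" in data:
        blk = dict(data["synthetic"])
        _reject_unknown(blk, set(_DEFAULT_SYNTHETIC), "data.synthetic")
        data["synthetic"] = {**_DEFAULT_SYNTHETIC, **blk}
    else:
        _reject_unknown(dict(data["paths"]), {"trial", "origins", "sites", "grid"}, "data.paths")
        for k in ("trial", "origins", "sites", "grid"):
            if k not in data["paths"]:
                raise ValueError(f"missing required data path: {k!r}")
    clustering = {**_DEFAULT_CLUSTERING, **raw.get("clustering", {})}
    _reject_unknown(clustering, set(_DEFAULT_CLUSTERING), "clustering")
    mcmc = {**_DEFAULT_MCMC, **raw.get("mcmc", {})}
    _reject_unknown(mcmc, set(_DEFAULT_MCMC), "mcmc")
    if mcmc["burn_in"] >= mcmc["iterations"]:
        raise ValueError("mcmc.burn_in must be smaller than mcmc.iterations")
    urf = {**_DEFAULT_URF, **raw.get("urf", {})}
    _reject_unknown(urf, set(_DEFAULT_URF), "urf")
    return PipelineConfig(
        seed=int(raw["seed"]),
        output_dir=str(raw["output_dir"]),
        trait=str(raw.get("trait", "DBH")),
        data=data,
        clustering=clustering,
        mcmc=mcmc,
        urf=urf,
    )


def _signature(stage: str, cfg_subset, input_files: list[Path]) -> str:
    h = hashlib.sha256()
    h.update(stage.encode())
    h.update(json.dumps(cfg_subset, sort_keys=True, default=str).encode())
    for p in input_files:
        h.update(str(p).encode())
        h.update(cio.sha256_file(p).encode())
    return h.hexdigest()


def _uniform_corr(n: int, r: float) -> np.ndarray:
    m = np.full((n, n), float(r))
    np.fill_diagonal(m, 1.0)
    return m


def _stage_data(cfg: PipelineConfig, out: Path) -> dict[str, Path]:
    paths = {k: out / f"{k}.csv" for k in ("trial", "origins", "sites", "grid")}
    if "paths" in cfg.data:
        for k, p in cfg.data["paths"].items():
            df = cio.read_trial(p) if k == "trial" else pd.read_csv(p)
            (cio.write_trial(df, paths[k]) if k == "trial" else df.to_csv(paths[k], index=False))
        return paths
    s = cfg.data["synthetic"]
    origins = syn.generate_origins(s["n_locations"], seed=cfg.seed)
    gt = syn.genotype_table(origins)
    design = syn.TrialDesign(
        n_sites=s["n_sites"],
        n_populations=s["n_locations"],
        genotypes_per_population=[int(x) for x in origins["n_genotypes"]],
        reps_per_site=s["reps_per_site"],
        blocks_per_rep=s["blocks_per_rep"],
        ramets_per_genotype_per_site=s["ramets_per_genotype_per_site"],
    )
    vc = syn.VarianceComponents(
        n_sites=s["n_sites"],
        sigma2_pop=s["sigma2_pop"],
        sigma2_gen=s["sigma2_gen"],
        sigma2_rep=s["sigma2_rep"],
        sigma2_block=s["sigma2_block"],
        sigma2_resid=s["sigma2_resid"],
        corr_pop=_uniform_corr(s["n_sites"], s["corr_pop"]),
        corr_gen=_uniform_corr(s["n_sites"], s["corr_gen"]),
    )
    trial = syn.generate_trial(design, vc, seed=cfg.seed, traits={cfg.trait: syn.TraitSpec()})
    # relabel generated population/genotype ids with origin-table identities
    pop_map = {f"P{i+1:02d}": loc for i, loc in enumerate(origins["location_id"])}
    gen_map = {f"G{i+1:03d}": g for i, g in enumerate(gt["genotype_id"])}
    trial["population"] = trial["population"].map(pop_map)
    trial["genotype"] = trial["genotype"].map(gen_map)
    cio.write_trial(trial, paths["trial"])
    origins.to_csv(paths["origins"], index=False)
    syn.generate_site_climate(s["n_sites"], seed=cfg.seed).to_csv(paths["sites"], index=False)
    syn.generate_grid(tuple(s["grid_bounds"]), s["grid_resolution"], seed=cfg.seed).to_csv(
        paths["grid"], index=False
    )
    return paths


def _stage_cluster(cfg: PipelineConfig, out: Path):
    origins = pd.read_csv(out / "origins.csv")
    feats = cl.standardize_features(origins, cfg.clustering["variables"])
    lo, hi = cfg.clustering["k_range"]
    hi = min(int(hi), len(origins) - 1)
    sel = cl.select_k(feats, range(int(lo), hi + 1))
    scen = cfg.clustering["scenario"]
    if scen == "best":
        k = sel.best_k
    elif scen == "second":
        k = sel.second_best_k
    else:
        k = int(scen)
    res = sel.results[k]
    assignment = pd.DataFrame(
        {
            "location_id": origins["location_id"],
            "cluster": [f"C{c+1:02d}" for c in res.assignment],
        }
    )
    assignment.to_csv(out / "clusters.csv", index=False)
    sel.table.to_csv(out / "kscores.csv", index=False)
    trial = cio.read_trial(out / "trial.csv")
    loc2cl = dict(zip(assignment["location_id"], assignment["cluster"]))
    trial["population"] = trial["population"].map(loc2cl)
    if trial["population"].isna().any():
        raise ValueError("trial contains populations absent from the origin table")
    cio.write_trial(trial, out / "trial_clustered.csv")


def _stage_fit(cfg: PipelineConfig, out: Path):
    trial = cio.read_trial(out / "trial_clustered.csv")
    std, scaling = standardize_phenotypes(trial)
    chains = gibbs_sample(std, ModelSpec(trait=cfg.trait), cfg.mcmc_options())
    cio.save_chains(chains, out / "chains")
    cio.save_scaling(scaling, out / "scaling.json")
    meta = {"seed": cfg.seed, "mcmc": cfg.mcmc, "trait": cfg.trait}
    (out / "fit_meta.json").write_text(json.dumps(meta, indent=2))


def _stage_summarize(cfg: PipelineConfig, out: Path):
    chains = cio.load_chains(out / "chains")
    summ = summarize(chains)
    summ.to_json(out / "summary.json")
    summ.components.to_csv(out / "components.csv", index=False)
    summ.heritability.to_csv(out / "heritability.csv", index=False)
    summ.correlations.to_csv(out / "correlations.csv", index=False)
    summ.correlation_matrix().to_csv(out / "correlation_matrix.csv")


def _stage_ranks(cfg: PipelineConfig, out: Path):
    chains = cio.load_chains(out / "chains")
    rt = rk.rank_genotypes(rk.effects_frame(chains))
    ranks = rt.ranks.copy()
    ranks["avg_rank"] = rt.average
    ranks.to_csv(out / "ranks.csv", index_label="genotype")
    rk.rank_change_stats(rt).to_csv(out / "rankbox.csv", index=False)


def _stage_urf(cfg: PipelineConfig, out: Path):
    chains = cio.load_chains(out / "chains")
    scaling = cio.load_scaling(out / "scaling.json")
    origins = pd.read_csv(out / "origins.csv")
    assignment = pd.read_csv(out / "clusters.csv")
    sites = pd.read_csv(out / "sites.csv")
    grid = pd.read_csv(out / "grid.csv")
    variables = cfg.urf["variables"]
    perf = urfmod.cluster_site_performance(chains, scaling)
    origin_climate = urfmod.cluster_climate(origins, assignment, variables)
    design = urfmod.build_urf_design(perf, origin_climate, sites, variables)
    fit = urfmod.fit_urf(design)
    fit.to_json(out / "urf.json")
    which = cfg.urf["cluster"]
    if which == "best":
        which = perf.groupby("cluster")["performance"].mean().idxmax()
    row = origin_climate.set_index("cluster").loc[which]
    surface = urfmod.predict_surface(fit, grid, {v: float(row[v]) for v in variables})
    surface["extrapolated"] = surface["extrapolated"].astype(int)
    surface.insert(0, "cluster", which)
    surface.to_csv(out / "surface.csv", index=False)


_STAGE_FN = {
    "data": _stage_data,
    "cluster": _stage_cluster,
    "fit": _stage_fit,
    "summarize": _stage_summarize,
    "ranks": _stage_ranks,
    "urf": _stage_urf,
}

_STAGE_INPUTS = {
    "data": [],
    "cluster": ["origins.csv", "trial.csv"],
    "fit": ["trial_clustered.csv"],
    "summarize": ["chains/s2_e.csv", "chains/meta.json"],
    "ranks": ["chains/gen_effect_mean.csv", "chains/meta.json"],
    "urf": ["chains/meta.json", "scaling.json", "origins.csv", "clusters.csv", "sites.csv", "grid.csv"],
}

_STAGE_OUTPUTS = {
    "data": ["trial.csv", "origins.csv", "sites.csv", "grid.csv"],
    "cluster": ["clusters.csv", "kscores.csv", "trial_clustered.csv"],
    "fit": ["chains/meta.json", "chains/s2_e.csv", "scaling.json", "fit_meta.json"],
    "summarize": ["summary.json", "components.csv", "heritability.csv", "correlations.csv"],
    "ranks": ["ranks.csv", "rankbox.csv"],
    "urf": ["urf.json", "surface.csv"],
}

_STAGE_CFG = {
    "data": lambda c: {"seed": c.seed, "data": c.data, "trait": c.trait},
    "cluster": lambda c: {"clustering": c.clustering},
    "fit": lambda c: {"seed": c.seed, "mcmc": c.mcmc, "trait": c.trait},
    "summarize": lambda c: {},
    "ranks": lambda c: {},
    "urf": lambda c: {"urf": c.urf},
}


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; return the run manifest (also written to disk).

    Completed stages whose config subset and input checksums are unchanged
    are skipped and marked as cache hits.  A stage failure halts the run
    with the stage name and upstream artifact paths in the raised error.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    previous = {}
    if manifest_path.exists():
        try:
            previous = {s["name"]: s for s in json.loads(manifest_path.read_text())["stages"]}
        except (json.JSONDecodeError, KeyError):
            previous = {}
    stages_out = []
    for stage in STAGES:
        inputs = [out / rel for rel in _STAGE_INPUTS[stage]]
        missing_inputs = [p for p in inputs if not p.exists()]
        if missing_inputs:
            raise RuntimeError(
                f"stage {stage!r} failed: missing upstream artifacts {[str(p) for p in missing_inputs]}"
            )
        sig = _signature(stage, _STAGE_CFG[stage](cfg), inputs)
        outputs = [out / rel for rel in _STAGE_OUTPUTS[stage]]
        prev = previous.get(stage)
        if prev and prev.get("signature") == sig and all(p.exists() for p in outputs):
            logger.info("[%s] cache hit; outputs reused", stage)
            stages_out.append({**prev, "cached": True})
            continue
        logger.info("[%s] running", stage)
        try:
            _STAGE_FN[stage](cfg, out)
        except Exception as exc:
            raise RuntimeError(
                f"stage {stage!r} failed (inputs: {[str(p) for p in inputs]}): {exc}"
            ) from exc
        stages_out.append(
            {
                "name": stage,
                "signature": sig,
                "inputs": {str(p): cio.sha256_file(p) for p in inputs},
                "outputs": {str(p): cio.sha256_file(p) for p in outputs},
                "cached": False,
            }
        )
    manifest = {
        "seed": cfg.seed,
        "trait": cfg.trait,
        "mcmc": cfg.mcmc,
        "clustering": cfg.clustering,
        "urf": cfg.urf,
        "stages": stages_out,
    }
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest
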