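"""Synthetic clonal-trial data with known generating parameters.

Emulates a multi-site clonal common-garden experiment: genotypes sampled
from origin populations along a climatic gradient, clonally replicated as
ramets across several trial sites laid out in replicates and incomplete
blocks.  Phenotypes follow the hierarchical model assumed downstream,

    y = site intercept + population + genotype + replicate + block + residual,

with population and genotype effects correlated across sites (the source
of GxE signal) and replicate/block/residual effects independent per site.
Every ramet is planted at exactly one site, so residuals are independent
across sites by construction.

All draws are reproducible from a single seed via per-component streams
(:mod:`clonegxe._rng`), so adding a trait or a site never perturbs the
draws of existing components; the cross-site mixing uses the Cholesky
factor, whose nestedness means appending a site leaves earlier sites'
effects bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from clonegxe._rng import component_rng

__all__ = [
    "TrialDesign",
    "VarianceComponents",
    "TraitSpec",
    "generate_trial",
    "generate_origins",
    "generate_grid",
    "genotype_table",
    "DEFAULT_GRADIENT",
]


@dataclass(frozen=True)
class TrialDesign:
    """Dimensions of a multi-site clonal trial.

    ``genotypes_per_population`` may be a single count or one count per
    population.  Each genotype belongs to exactly one population and each
    ramet is planted at exactly one site.
    """

    n_sites: int
    n_populations: int
    genotypes_per_population: int | list[int]
    reps_per_site: int = 3
    blocks_per_rep: int = 2
    ramets_per_genotype_per_site: int = 3

    def __post_init__(self):
        counts = [
            self.n_sites,
            self.n_populations,
            self.reps_per_site,
            self.blocks_per_rep,
            self.ramets_per_genotype_per_site,
        ]
        if any(int(c) < 1 for c in counts):
            raise ValueError("all design counts must be >= 1")
        gpp = self.genotype_counts()
        if len(gpp) != self.n_populations or any(g < 1 for g in gpp):
            raise ValueError(
                "genotypes_per_population must be a positive count or one per population"
            )

    def genotype_counts(self) -> list[int]:
        g = self.genotypes_per_population
        if isinstance(g, int):
            return [g] * self.n_populations
        return [int(x) for x in g]

    @property
    def n_genotypes(self) -> int:
        return sum(self.genotype_counts())


def _as_site_vector(x, n_sites: int, name: str) -> np.ndarray:
    v = np.broadcast_to(np.asarray(x, dtype=float), (n_sites,)).copy()
    if np.any(v < 0):
        raise ValueError(f"{name} must be non-negative")
    return v


def _check_correlation(mat: np.ndarray, name: str, n_sites: int) -> np.ndarray:
    m = np.asarray(mat, dtype=float)
    if m.shape != (n_sites, n_sites):
        raise ValueError(f"{name} must be {n_sites}x{n_sites}")
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValueError(f"{name} is not symmetric")
    if not np.allclose(np.diag(m), 1.0, atol=1e-10):
        raise ValueError(f"{name} must have unit diagonal")
    if np.linalg.eigvalsh(m).min() < -1e-10:
        raise ValueError(f"{name} is not positive semi-definite")
    return m


@dataclass
class VarianceComponents:
    """Per-site variances and cross-site correlations of random effects.

    Variances may be scalars (shared by all sites) or length-``n_sites``
    sequences.  ``corr_pop``/``corr_gen`` are cross-site correlation
    matrices of the population and genotype effects; identity by default
    (no cross-site correlation, maximal GxE).
    """

    n_sites: int
    sigma2_pop: float | list[float] = 0.0
    sigma2_gen: float | list[float] = 0.0
    sigma2_rep: float | list[float] = 0.0
    sigma2_block: float | list[float] = 0.0
    sigma2_resid: float | list[float] = 1.0
    corr_pop: np.ndarray | None = None
    corr_gen: np.ndarray | None = None

    def __post_init__(self):
        n = self.n_sites
        self.sigma2_pop = _as_site_vector(self.sigma2_pop, n, "sigma2_pop")
        self.sigma2_gen = _as_site_vector(self.sigma2_gen, n, "sigma2_gen")
        self.sigma2_rep = _as_site_vector(self.sigma2_rep, n, "sigma2_rep")
        self.sigma2_block = _as_site_vector(self.sigma2_block, n, "sigma2_block")
        self.sigma2_resid = _as_site_vector(self.sigma2_resid, n, "sigma2_resid")
        if self.corr_pop is None:
            self.corr_pop = np.eye(n)
        if self.corr_gen is None:
            self.corr_gen = np.eye(n)
        self.corr_pop = _check_correlation(self.corr_pop, "corr_pop", n)
        self.corr_gen = _check_correlation(self.corr_gen, "corr_gen", n)

    def covariance(self, which: str) -> np.ndarray:
        """Cross-site covariance matrix of the population or genotype term."""
        if which == "pop":
            v, c = self.sigma2_pop, self.corr_pop
        elif which == "gen":
            v, c = self.sigma2_gen, self.corr_gen
        else:
            raise ValueError("which must be 'pop' or 'gen'")
        s = np.sqrt(v)
        return c * np.outer(s, s)


@dataclass(frozen=True)
class TraitSpec:
    """How one trait is generated.

    kind='gaussian': trait value is the linear predictor itself (units are
    whatever the variance components are given in).
    kind='binary': a latent Gaussian with the same effect structure is
    thresholded so that the marginal incidence equals ``incidence``
    (presence/absence coding, e.g. epicormic-sprout occurrence).
    """

    kind: str = "gaussian"
    incidence: float = 0.3

    def __post_init__(self):
        if self.kind not in ("gaussian", "binary"):
            raise ValueError("kind must be 'gaussian' or 'binary'")
        if not 0.0 < self.incidence < 1.0:
            raise ValueError("incidence must be in (0, 1)")


def _cov_factor(cov: np.ndarray) -> np.ndarray:
    """Lower-triangular factor L with cov = L L'.

    Cholesky when possible (its nestedness keeps earlier sites stable when
    a site is appended); eigen factor for singular covariances.
    """
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(cov)
        w = np.clip(w, 0.0, None)
        return v @ np.diag(np.sqrt(w))


def _correlated_effects(
    seed: int, trait: str, component: str, n_levels: int, cov: np.ndarray
) -> np.ndarray:
    """n_levels x n_sites matrix of effects with cross-site covariance cov."""
    n_sites = cov.shape[0]
    z = np.column_stack(
        [
            component_rng(seed, trait, component, "site", j).standard_normal(n_levels)
            for j in range(n_sites)
        ]
    )
    return z @ _cov_factor(cov).T


def generate_trial(
    design: TrialDesign,
    vc: VarianceComponents,
    seed: int,
    traits: dict[str, TraitSpec] | None = None,
    site_intercepts: list[float] | None = None,
    return_effects: bool = False,
):
    """Simulate a multi-site clonal trial.

    Returns a long-format DataFrame with columns
    ``site, rep, block, population, genotype, ramet, trait, value``;
    with ``return_effects=True`` also a dict of the drawn effect arrays per
    trait (for moment checks against the generating parameters).

    Site intercepts default to distinct values per site so that
    within-site standardization downstream is actually exercised.
    """
    if vc.n_sites != design.n_sites:
        raise ValueError("vc.n_sites must match design.n_sites")
    if traits is None:
        traits = {"DBH": TraitSpec("gaussian")}
    if site_intercepts is None:
        site_intercepts = [100.0 + 25.0 * i for i in range(design.n_sites)]
    mu = np.asarray(site_intercepts, dtype=float)
    if mu.shape != (design.n_sites,):
        raise ValueError("site_intercepts must have one value per site")

    n_sites = design.n_sites
    gpp = design.genotype_counts()
    n_gen = design.n_genotypes
    # genotype -> population assignment
    gen_pop = np.repeat(np.arange(design.n_populations), gpp)
    site_ids = [f"S{j+1}" for j in range(n_sites)]
    pop_ids = [f"P{i+1:02d}" for i in range(design.n_populations)]
    gen_ids = [f"G{i+1:03d}" for i in range(n_gen)]

    records = []
    effects_out: dict[str, dict[str, np.ndarray]] = {}
    for trait, tspec in traits.items():
        pop_eff = _correlated_effects(
            seed, trait, "population", design.n_populations, vc.covariance("pop")
        )
        gen_eff = _correlated_effects(seed, trait, "genotype", n_gen, vc.covariance("gen"))
        rep_eff = np.column_stack(
            [
                component_rng(seed, trait, "rep", "site", j).standard_normal(design.reps_per_site)
                * np.sqrt(vc.sigma2_rep[j])
                for j in range(n_sites)
            ]
        )
        blk_eff = np.stack(
            [
                component_rng(seed, trait, "block", "site", j)
                .standard_normal((design.reps_per_site, design.blocks_per_rep))
                * np.sqrt(vc.sigma2_block[j])
                for j in range(n_sites)
            ],
            axis=-1,
        )  # (rep, block, site)
        resid_sd = np.sqrt(vc.sigma2_resid)
        effects_out[trait] = {
            "population": pop_eff,
            "genotype": gen_eff,
            "rep": rep_eff,
            "block": blk_eff,
        }
        residuals = {}
        for j in range(n_sites):
            residuals[j] = component_rng(seed, trait, "residual", "site", j).standard_normal(
                n_gen * design.ramets_per_genotype_per_site
            ) * resid_sd[j]
        effects_out[trait]["residual"] = residuals

        latent_var = vc.sigma2_pop + vc.sigma2_gen + vc.sigma2_rep + vc.sigma2_block + vc.sigma2_resid
        for j in range(n_sites):
            obs = 0
            for i in range(n_gen):
                p = gen_pop[i]
                for t in range(design.ramets_per_genotype_per_site):
                    rep = t % design.reps_per_site
                    blk = (i + t) % design.blocks_per_rep
                    lin = (
                        pop_eff[p, j]
                        + gen_eff[i, j]
                        + rep_eff[rep, j]
                        + blk_eff[rep, blk, j]
                        + residuals[j][obs]
                    )
                    if tspec.kind == "gaussian":
                        value = mu[j] + lin
                    else:
                        # threshold the latent at the upper `incidence` tail
                        from scipy.stats import norm

                        cut = norm.ppf(1.0 - tspec.incidence) * np.sqrt(max(latent_var[j], 1e-300))
                        value = float(lin > cut) if latent_var[j] > 0 else 0.0
                    records.append(
                        (
                            site_ids[j],
                            f"R{rep+1}",
                            f"B{blk+1}",
                            pop_ids[p],
                            gen_ids[i],
                            f"{gen_ids[i]}_{site_ids[j]}_{t+1}",
                            trait,
                            value,
                        )
                    )
                    obs += 1
    df = pd.DataFrame.from_records(
        records,
        columns=["site", "rep", "block", "population", "genotype", "ramet", "trait", "value"],
    )
    if return_effects:
        return df, effects_out
    return df


# Gradient defaults emulate a range-wide coastal-conifer collection:
# latitude spans ~36.5-42.2 degrees N; maximum temperature falls and annual
# precipitation rises with latitude, strongly enough that corr(lat, tmax)
# is about -0.93 and corr(lat, precip) about +0.59, which induces the
# moderate tmax-precipitation correlation of about -0.55 characteristic of
# such collections while most other variable pairs stay highly collinear.
DEFAULT_GRADIENT: dict[str, dict[str, float]] = {
    "distance_from_coast": {"mean": 25.0, "slope": 0.0, "noise_sd": 12.0, "min": 0.5},
    "elevation": {"mean": 300.0, "slope": 25.0, "noise_sd": 140.0, "min": 0.0},
    "tmax": {"mean": 16.5, "slope": -0.60, "noise_sd": 0.39},
    "tmin": {"mean": 7.5, "slope": -0.45, "noise_sd": 0.15},
    "precipitation": {"mean": 1100.0, "slope": 150.0, "noise_sd": 337.0, "min": 50.0},
}


def generate_origins(
    n_locations: int,
    gradient_spec: dict[str, dict[str, float]] | None = None,
    seed: int = 0,
    lat_range: tuple[float, float] = (36.5, 42.2),
    max_genotypes_per_location: int = 6,
) -> pd.DataFrame:
    """Generate an origin (sampling-location) covariate table.

    Each climate/geography variable is a linear function of latitude plus
    Gaussian noise; a gradient entry may give either ``slope`` directly or
    ``corr_with_lat`` (the target correlation with latitude, from which the
    slope is derived — infeasible |r| > 1 raises).  Genotype counts per
    location are uniform on {1..max_genotypes_per_location}.
    """
    if n_locations < 1:
        raise ValueError("n_locations must be >= 1")
    spec = gradient_spec if gradient_spec is not None else DEFAULT_GRADIENT
    rng_lat = component_rng(seed, "origins", "latitude")
    lat = np.sort(rng_lat.uniform(lat_range[0], lat_range[1], size=n_locations))
    lat_c = lat - lat.mean() if n_locations > 1 else lat * 0.0
    lat_sd = lat.std(ddof=1) if n_locations > 1 else 1.0

    out = {"location_id": [f"L{i+1:03d}" for i in range(n_locations)], "latitude": lat}
    for var, g in spec.items():
        noise_sd = float(g.get("noise_sd", 0.0))
        if "corr_with_lat" in g:
            r = float(g["corr_with_lat"])
            if abs(r) > 1.0:
                raise ValueError(f"requested |corr_with_lat| > 1 for {var}: {r}")
            if abs(r) == 1.0 and noise_sd > 0:
                raise ValueError(f"corr_with_lat = +-1 for {var} requires zero noise")
            if abs(r) < 1.0 and noise_sd == 0.0 and r != 0.0:
                raise ValueError(f"corr_with_lat for {var} needs noise_sd > 0 unless |r| = 1")
            slope = (
                np.sign(r) * np.inf
                if noise_sd == 0
                else r / np.sqrt(1.0 - r * r) * noise_sd / lat_sd
            )
            if not np.isfinite(slope):
                slope = np.sign(r)  # pure collinearity, scale irrelevant
        else:
            slope = float(g.get("slope", 0.0))
        rng = component_rng(seed, "origins", var)
        vals = g["mean"] + slope * lat_c + noise_sd * rng.standard_normal(n_locations)
        if "min" in g:
            vals = np.clip(vals, g["min"], None)
        out[var] = vals
    rng_g = component_rng(seed, "origins", "genotype_counts")
    out["n_genotypes"] = rng_g.integers(1, max_genotypes_per_location + 1, size=n_locations)
    return pd.DataFrame(out)


def genotype_table(origins: pd.DataFrame) -> pd.DataFrame:
    """Expand an origin table into one row per genotype (genotype_id, location_id)."""
    rows = []
    for _, r in origins.iterrows():
        for k in range(int(r["n_genotypes"])):
            rows.append((f"{r['location_id']}g{k+1}", r["location_id"]))
    return pd.DataFrame(rows, columns=["genotype_id", "location_id"])


def generate_site_climate(
    n_sites: int,
    seed: int = 0,
    tmax_range: tuple[float, float] = (13.9, 16.6),
    precip_range: tuple[float, float] = (900.0, 2010.0),
) -> pd.DataFrame:
    """Climate table for the trial sites (one row per site).

    Sites span the given maximum-temperature and precipitation ranges
    (defaults are typical of temperate maritime trial networks) with small
    jitter so site climates are pairwise distinct; ancillary variables
    (tmin, radiation, vapour pressure, wind) co-vary with tmax.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = component_rng(seed, "site_climate")
    t = np.linspace(0.0, 1.0, n_sites) if n_sites > 1 else np.array([0.5])
    tmax = tmax_range[0] + t * (tmax_range[1] - tmax_range[0]) + rng.normal(0, 0.1, n_sites)
    # precipitation deliberately not monotone in tmax (shuffled levels)
    precip_levels = precip_range[0] + np.linspace(0, 1, n_sites) * (
        precip_range[1] - precip_range[0]
    )
    precip = rng.permutation(precip_levels) + rng.normal(0, 30.0, n_sites)
    return pd.DataFrame(
        {
            "site_id": [f"S{j+1}" for j in range(n_sites)],
            "tmax": tmax,
            "tmin": tmax - 9.0 + rng.normal(0, 0.4, n_sites),
            "precipitation": precip,
            "radiation": 170_000.0 - 2_000.0 * (tmax - tmax.mean()) + rng.normal(0, 2_000.0, n_sites),
            "vapour_pressure": 1.0 + 0.05 * (tmax - tmax.mean()) + rng.normal(0, 0.03, n_sites),
            "wind_speed": 4.3 + rng.normal(0, 0.3, n_sites),
        }
    )


def default_climate_fn(lon: np.ndarray, lat: np.ndarray, rng=None):
    """Smooth deterministic climate surface used when none is supplied."""
    tmax = 28.0 - 0.35 * np.abs(lat) + 0.05 * (lon - lon.mean())
    precip = 600.0 + 25.0 * np.abs(lat) - 8.0 * (lon - lon.mean())
    return {"tmax": tmax, "precipitation": precip}


def generate_grid(
    bounds: tuple[float, float, float, float],
    resolution: float,
    climate_fn=None,
    seed: int = 0,
) -> pd.DataFrame:
    """Regular lon/lat grid of climate cells (cell centres).

    ``bounds`` is (lon_min, lon_max, lat_min, lat_max); the number of cells
    per axis is extent / resolution.  ``climate_fn(lon, lat, rng)`` returns
    a dict of climate arrays; it may be deterministic (for exact prediction
    tests) or use ``rng`` for noise.
    """
    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    lon_min, lon_max, lat_min, lat_max = map(float, bounds)
    nx = int(round((lon_max - lon_min) / resolution))
    ny = int(round((lat_max - lat_min) / resolution))
    if nx < 1 or ny < 1 or lon_max <= lon_min or lat_max <= lat_min:
        raise ValueError("empty bounding box")
    lon = lon_min + (np.arange(nx) + 0.5) * resolution
    lat = lat_min + (np.arange(ny) + 0.5) * resolution
    glon, glat = np.meshgrid(lon, lat)
    glon, glat = glon.ravel(), glat.ravel()
    fn = climate_fn if climate_fn is not None else default_climate_fn
    climate = fn(glon, glat, component_rng(seed, "grid", "climate"))
    out = pd.DataFrame({"lon": glon, "lat": glat})
    for k, v in climate.items():
        out[k] = np.broadcast_to(np.asarray(v, dtype=float), glon.shape)
    return out
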