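"""Bayesian multivariate multi-environment mixed model.

The phenotype of ramet m of genotype g from population p, grown in
replicate r / block b of environment (site) i, is modelled as

    y = beta_i + p_{pi} + g_{gi} + r_{ri} + b_{bi} + e,

treating environment as a dimension of a multivariate response: the
population effect of each population is a vector across environments with
unstructured covariance G1, and likewise genotype-within-population
effects with covariance G2.  Replicate, block-within-replicate and
residual terms get independent per-environment variances — no ramet is
grown at two sites, so their cross-environment covariances are
unidentifiable and are fixed at zero by design.

Inference is by Gibbs sampling with the standard conjugate updates:

1. all location effects (intercepts and random-effect vectors) jointly
   from their conditional multivariate normal given current covariances;
2. translation-group sweep moves (generalized Gibbs) that resample the
   likelihood-invariant directions — the shared offset between the
   intercepts and the population effects, and between each population's
   effect and its genotypes' effects.  These directions are where the
   nested terms are confounded; without the sweeps the sampler mixes them
   by a slow random walk and can stick in states where one term absorbs
   the other's variance;
3. G1 and G2 from inverse-Wishart conditionals built from the outer
   products of the population / genotype effect vectors;
4. each per-environment scalar variance from its scaled-inverse-chi-square
   (inverse-gamma) conditional.

Priors (configurable): inverse-Wishart(scale = I*s, df = n_env + 1) for
G1/G2 and inverse-gamma(0.001, 0.001) for scalar variances — weak on the
standardized scale the model is fitted on.  Phenotypes are z-scored
within environment before fitting so variance components are comparable
across sites and sum to roughly one per site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.stats import gaussian_kde, invwishart

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "MCMCOptions",
    "ScalingRecord",
    "Design",
    "PosteriorChains",
    "standardize_phenotypes",
    "build_design",
    "gibbs_sample",
    "posterior_mode",
    "hpd_interval",
    "quantile_interval",
]

MULTIVARIATE_TERMS = ("population", "genotype")
SCALAR_TERMS = ("rep", "block")


@dataclass
class ModelSpec:
    """Which trait to fit and with which random terms and priors."""

    trait: str
    random_terms: tuple[str, ...] = ("population", "genotype", "rep", "block")
    # weakly-informative default: with scale I*s the prior contributes the
    # equivalent of df0 pseudo-observations of variance s, so s must be small
    # relative to the per-term sums of squares on the standardized scale or
    # weakly-identified cross-site correlations get pulled toward zero; very
    # small s re-introduces a prior spike at zero variance (collapse risk in
    # weakly identified designs)
    iw_scale: float = 0.1  # inverse-Wishart scale = I * iw_scale
    iw_df: float | None = None  # default n_env + 1
    ig_shape: float = 0.001
    ig_scale: float = 0.001

    def __post_init__(self):
        unknown = set(self.random_terms) - set(MULTIVARIATE_TERMS + SCALAR_TERMS)
        if unknown:
            raise ValueError(f"unknown random terms: {sorted(unknown)}")


@dataclass
class MCMCOptions:
    """Chain settings; defaults are the full-length production run."""

    iterations: int = 500_000
    burn_in: int = 50_000
    thinning: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be smaller than iterations")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.iterations - self.burn_in + self.thinning - 1) // self.thinning


@dataclass
class ScalingRecord:
    """Per (site, trait) mean/SD used for within-environment z-scoring."""

    params: dict[tuple[str, str], tuple[float, float]]

    def unstandardize(self, site: str, trait: str, values):
        mean, sd = self.params[(site, trait)]
        return np.asarray(values, dtype=float) * sd + mean

    def sd(self, site: str, trait: str) -> float:
        return self.params[(site, trait)][1]

    def mean(self, site: str, trait: str) -> float:
        return self.params[(site, trait)][0]


def standardize_phenotypes(data: pd.DataFrame) -> tuple[pd.DataFrame, ScalingRecord]:
    """Z-score each trait within each environment (sample SD).

    A trait with zero variance at some site cannot be standardized — the
    degenerate no-signal site must be handled explicitly upstream, so the
    error names the site and trait.
    """
    out = data.copy()
    params: dict[tuple[str, str], tuple[float, float]] = {}
    for (site, trait), grp in data.groupby(["site", "trait"], sort=False):
        vals = grp["value"].to_numpy(dtype=float)
        mean = float(np.nanmean(vals))
        sd = float(np.nanstd(vals, ddof=1))
        if not np.isfinite(sd) or sd == 0.0:
            raise ValueError(f"zero within-environment variance at site {site!r}, trait {trait!r}")
        params[(str(site), str(trait))] = (mean, sd)
        out.loc[grp.index, "value"] = (vals - mean) / sd
    return out, ScalingRecord(params)


@dataclass
class Design:
    """Dense incidence structure for one trait.

    Columns of ``W`` are grouped as [per-environment intercepts | random
    terms in ``spec.random_terms`` order]; multivariate terms are ordered
    environment-major (column e*n_levels + level).
    """

    y: np.ndarray
    W: np.ndarray
    env_index: np.ndarray  # row -> environment position
    environments: list[str]
    slices: dict[str, slice]  # term -> column slice ("beta" included)
    levels: dict[str, list[str]]  # term -> level labels
    col_env: dict[str, np.ndarray]  # scalar terms: column -> environment position

    @property
    def n_env(self) -> int:
        return len(self.environments)


def build_design(data: pd.DataFrame, spec: ModelSpec) -> Design:
    """Build incidence matrices for the model from a long trial table.

    Every observation is assigned to exactly one environment, one
    population x environment level, one genotype x environment level, one
    replicate and one block (row sums of each incidence block are 1).
    """
    df = data[data["trait"] == spec.trait].copy()
    if df.empty:
        raise ValueError(f"no rows for trait {spec.trait!r}")
    df = df.dropna(subset=["value"])
    g2p = df.groupby("genotype")["population"].nunique()
    bad = g2p[g2p > 1]
    if len(bad):
        raise ValueError(f"genotype(s) mapped to multiple populations: {list(bad.index)}")

    environments = sorted(df["site"].astype(str).unique())
    env_pos = {s: i for i, s in enumerate(environments)}
    env_index = df["site"].astype(str).map(env_pos).to_numpy()
    n_obs, n_env = len(df), len(environments)
    y = df["value"].to_numpy(dtype=float)

    blocks: list[np.ndarray] = []
    slices: dict[str, slice] = {}
    levels: dict[str, list[str]] = {}
    col_env: dict[str, np.ndarray] = {}
    start = 0

    def add(name, mat, lev, env_of_col=None):
        nonlocal start
        blocks.append(mat)
        slices[name] = slice(start, start + mat.shape[1])
        levels[name] = lev
        if env_of_col is not None:
            col_env[name] = env_of_col
        start += mat.shape[1]

    X = np.zeros((n_obs, n_env))
    X[np.arange(n_obs), env_index] = 1.0
    add("beta", X, environments)

    for term, col in (("population", "population"), ("genotype", "genotype")):
        if term not in spec.random_terms:
            continue
        lev = sorted(df[col].astype(str).unique())
        pos = {l: i for i, l in enumerate(lev)}
        idx = df[col].astype(str).map(pos).to_numpy()
        Z = np.zeros((n_obs, n_env * len(lev)))
        Z[np.arange(n_obs), env_index * len(lev) + idx] = 1.0
        add(term, Z, lev)

    for term, cols in (("rep", ["site", "rep"]), ("block", ["site", "rep", "block"])):
        if term not in spec.random_terms:
            continue
        key = df[cols].astype(str).agg("/".join, axis=1)
        lev = sorted(key.unique())
        pos = {l: i for i, l in enumerate(lev)}
        idx = key.map(pos).to_numpy()
        Z = np.zeros((n_obs, len(lev)))
        Z[np.arange(n_obs), idx] = 1.0
        env_of_col = np.array([env_pos[l.split("/")[0]] for l in lev])
        add(term, Z, lev, env_of_col)

    W = np.concatenate(blocks, axis=1)
    return Design(
        y=y, W=W, env_index=env_index, environments=environments,
        slices=slices, levels=levels, col_env=col_env,
    )


@dataclass
class PosteriorChains:
    """Thinned post-burn-in samples of every variance-covariance component.

    ``G1``/``G2`` are (n_samples, n_env, n_env) covariance stacks for the
    population and genotype terms (None if the term was not in the model);
    scalar terms are (n_samples, n_env).  Posterior-mean random-effect
    matrices (levels x environments) are kept for ranking and response-
    surface work.
    """

    trait: str
    environments: list[str]
    options: MCMCOptions
    beta: np.ndarray
    G1: np.ndarray | None
    G2: np.ndarray | None
    s2_rep: np.ndarray | None
    s2_block: np.ndarray | None
    s2_e: np.ndarray
    populations: list[str] | None = None
    genotypes: list[str] | None = None
    pop_effect_mean: np.ndarray | None = None
    gen_effect_mean: np.ndarray | None = None

    @property
    def n_samples(self) -> int:
        return self.s2_e.shape[0]

    def env_pos(self, site: str) -> int:
        return self.environments.index(site)

    def var_chain(self, term: str, site: str) -> np.ndarray:
        """Chain of one variance component at one site."""
        i = self.env_pos(site)
        if term == "population":
            return self.G1[:, i, i]
        if term == "genotype":
            return self.G2[:, i, i]
        if term == "rep":
            return self.s2_rep[:, i]
        if term == "block":
            return self.s2_block[:, i]
        if term in ("residual", "error"):
            return self.s2_e[:, i]
        raise KeyError(term)

    def cov_chain(self, level: str, site_i: str, site_j: str) -> np.ndarray:
        """Chain of a cross-site covariance at population or genotype level."""
        G = {"population": self.G1, "genotype": self.G2}[level]
        if G is None:
            raise ValueError(f"model has no {level} term")
        return G[:, self.env_pos(site_i), self.env_pos(site_j)]

    def check_psd(self) -> bool:
        """True iff every retained G1/G2 sample is positive definite."""
        for G in (self.G1, self.G2):
            if G is None:
                continue
            for s in range(G.shape[0]):
                if np.linalg.eigvalsh(G[s]).min() <= 0:
                    return False
        return True


def _chol_with_jitter(C: np.ndarray, max_tries: int = 4):
    jitter = 0.0
    for attempt in range(max_tries):
        try:
            return linalg.cho_factor(
                C + jitter * np.eye(C.shape[0]) if jitter else C,
                lower=True,
                check_finite=False,
            )
        except np.linalg.LinAlgError:
            jitter = 1e-10 * 10.0**attempt * max(1.0, np.abs(np.diag(C)).max())
            logger.warning("Cholesky failed; retrying with jitter %.2e", jitter)
    raise np.linalg.LinAlgError("conditional covariance not positive definite after jitter retries")


def gibbs_sample(data: pd.DataFrame, spec: ModelSpec, opts: MCMCOptions) -> PosteriorChains:
    """Run the Gibbs sampler on (already standardized) trial data.

    Retains every ``thinning``-th post-burn-in draw; fully reproducible
    from ``opts.seed``.  Data should have been through
    :func:`standardize_phenotypes`; the priors assume unit-scale traits.
    """
    design = build_design(data, spec)
    n_env = design.n_env
    y, W = design.y, design.W
    d = W.shape[1]
    rng = np.random.default_rng(opts.seed)

    for term in spec.random_terms:
        if len(design.levels[term]) < 2:
            raise ValueError(f"random term {term!r} needs >= 2 levels")

    # per-environment Gram matrices and projections (residual precision is
    # diagonal by environment, so W'R^-1 W = sum_e (1/s2_e) W_e' W_e)
    rows_e = [np.flatnonzero(design.env_index == e) for e in range(n_env)]
    gram = np.stack([W[r].T @ W[r] for r in rows_e])
    wy = np.stack([W[r].T @ y[r] for r in rows_e])
    n_per_env = np.array([len(r) for r in rows_e], dtype=float)

    iw_df0 = spec.iw_df if spec.iw_df is not None else n_env + 1
    S0 = spec.iw_scale * np.eye(n_env)
    a0, b0 = spec.ig_shape, spec.ig_scale

    has = {t: t in spec.random_terms for t in MULTIVARIATE_TERMS + SCALAR_TERMS}
    n_pop = len(design.levels["population"]) if has["population"] else 0
    n_gen = len(design.levels["genotype"]) if has["genotype"] else 0

    pop_indicator = pop_sizes = gen_pop_idx = None
    if has["population"] and has["genotype"]:
        df_t = data[data["trait"] == spec.trait].dropna(subset=["value"])
        g2p = df_t.astype({"genotype": str, "population": str}).groupby("genotype")[
            "population"
        ].first()
        pop_pos = {p: i for i, p in enumerate(design.levels["population"])}
        gen_pop_idx = np.array([pop_pos[g2p[g]] for g in design.levels["genotype"]])
        pop_indicator = np.zeros((n_gen, n_pop))
        pop_indicator[np.arange(n_gen), gen_pop_idx] = 1.0
        pop_sizes = pop_indicator.sum(axis=0).astype(int)

    # state
    G1 = np.eye(n_env) * 0.5 if has["population"] else None
    G2 = np.eye(n_env) * 0.5 if has["genotype"] else None
    s2_rep = np.full(n_env, 0.1) if has["rep"] else None
    s2_block = np.full(n_env, 0.1) if has["block"] else None
    s2_e = np.ones(n_env)

    S = opts.n_retained
    out = {
        "beta": np.empty((S, n_env)),
        "G1": np.empty((S, n_env, n_env)) if has["population"] else None,
        "G2": np.empty((S, n_env, n_env)) if has["genotype"] else None,
        "s2_rep": np.empty((S, n_env)) if has["rep"] else None,
        "s2_block": np.empty((S, n_env)) if has["block"] else None,
        "s2_e": np.empty((S, n_env)),
    }
    pop_sum = np.zeros((n_pop, n_env)) if has["population"] else None
    gen_sum = np.zeros((n_gen, n_env)) if has["genotype"] else None

    sl = design.slices
    kept = 0
    for it in range(opts.iterations):
        inv_e = 1.0 / s2_e
        # ---- joint location-effect update -------------------------------
        C = np.tensordot(inv_e, gram, axes=1)
        rhs = inv_e @ wy
        if has["population"]:
            G1inv = np.linalg.inv(G1)
            base = sl["population"].start
            for e in range(n_env):
                for f in range(n_env):
                    idx = base + np.arange(n_pop)
                    C[idx + e * n_pop, idx + f * n_pop] += G1inv[e, f]
        if has["genotype"]:
            G2inv = np.linalg.inv(G2)
            base = sl["genotype"].start
            for e in range(n_env):
                for f in range(n_env):
                    idx = base + np.arange(n_gen)
                    C[idx + e * n_gen, idx + f * n_gen] += G2inv[e, f]
        if has["rep"]:
            idx = np.arange(d)[sl["rep"]]
            C[idx, idx] += 1.0 / s2_rep[design.col_env["rep"]]
        if has["block"]:
            idx = np.arange(d)[sl["block"]]
            C[idx, idx] += 1.0 / s2_block[design.col_env["block"]]
        cf = _chol_with_jitter(C)
        mean = linalg.cho_solve(cf, rhs, check_finite=False)
        z = rng.standard_normal(d)
        theta = mean + linalg.solve_triangular(
            cf[0], z, lower=True, trans="T", check_finite=False
        )

        # ---- sweep moves along likelihood-invariant translations --------
        Pv = theta[sl["population"]].reshape(n_env, n_pop) if has["population"] else None
        Gv = theta[sl["genotype"]].reshape(n_env, n_gen) if has["genotype"] else None
        if has["population"]:
            # intercept <-> population offset: delta ~ N(mean_q p_q, G1/n_pop)
            delta = Pv.mean(axis=1) + np.linalg.cholesky(G1 / n_pop) @ rng.standard_normal(n_env)
            theta[sl["beta"]] += delta
            Pv -= delta[:, None]
        elif has["genotype"]:
            delta = Gv.mean(axis=1) + np.linalg.cholesky(G2 / n_gen) @ rng.standard_normal(n_env)
            theta[sl["beta"]] += delta
            Gv -= delta[:, None]
        if has["population"] and has["genotype"]:
            # population <-> its genotypes' shared offset:
            # delta_q ~ N(A^-1 (G2inv s_q - G1inv p_q), A^-1), A = G1inv + n_q G2inv,
            # s_q the sum of genotype effects in population q
            G1inv_s, G2inv_s = np.linalg.inv(G1), np.linalg.inv(G2)
            Sgp = Gv @ pop_indicator
            delta_all = np.empty((n_env, n_pop))
            for m in np.unique(pop_sizes):
                cols = np.flatnonzero(pop_sizes == m)
                Ainv = np.linalg.inv(G1inv_s + m * G2inv_s)
                B = G2inv_s @ Sgp[:, cols] - G1inv_s @ Pv[:, cols]
                delta_all[:, cols] = Ainv @ B + np.linalg.cholesky(Ainv) @ rng.standard_normal(
                    (n_env, len(cols))
                )
            Pv += delta_all
            Gv -= delta_all[:, gen_pop_idx]

        # ---- covariance updates ----------------------------------------
        if has["population"]:
            P = Pv.T
            G1 = invwishart.rvs(df=iw_df0 + n_pop, scale=S0 + P.T @ P, random_state=rng)
            G1 = np.atleast_2d(G1)
        if has["genotype"]:
            Gm = Gv.T
            G2 = invwishart.rvs(df=iw_df0 + n_gen, scale=S0 + Gm.T @ Gm, random_state=rng)
            G2 = np.atleast_2d(G2)
        for term, state in (("rep", s2_rep), ("block", s2_block)):
            if not has[term]:
                continue
            eff = theta[sl[term]]
            env_of = design.col_env[term]
            for e in range(n_env):
                u = eff[env_of == e]
                shape = a0 + 0.5 * len(u)
                rate = b0 + 0.5 * float(u @ u)
                state[e] = rate / rng.gamma(shape)
        resid = y - W @ theta
        for e in range(n_env):
            r = resid[rows_e[e]]
            s2_e[e] = (b0 + 0.5 * float(r @ r)) / rng.gamma(a0 + 0.5 * n_per_env[e])

        # ---- retain -----------------------------------------------------
        if it >= opts.burn_in and (it - opts.burn_in) % opts.thinning == 0:
            out["beta"][kept] = theta[sl["beta"]]
            if has["population"]:
                out["G1"][kept] = G1
                pop_sum += P
            if has["genotype"]:
                out["G2"][kept] = G2
                gen_sum += Gm
            if has["rep"]:
                out["s2_rep"][kept] = s2_rep
            if has["block"]:
                out["s2_block"][kept] = s2_block
            out["s2_e"][kept] = s2_e
            kept += 1

    return PosteriorChains(
        trait=spec.trait,
        environments=design.environments,
        options=opts,
        beta=out["beta"],
        G1=out["G1"],
        G2=out["G2"],
        s2_rep=out["s2_rep"],
        s2_block=out["s2_block"],
        s2_e=out["s2_e"],
        populations=design.levels.get("population"),
        genotypes=design.levels.get("genotype"),
        pop_effect_mean=None if pop_sum is None else pop_sum / kept,
        gen_effect_mean=None if gen_sum is None else gen_sum / kept,
    )


def posterior_mode(chain: np.ndarray) -> float:
    """Mode of a Gaussian KDE (Silverman bandwidth) on a 512-point grid.

    A constant chain returns that constant.
    """
    x = np.asarray(chain, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) == 0:
        raise ValueError("empty chain")
    lo, hi = x.min(), x.max()
    if hi == lo:
        return float(lo)
    kde = gaussian_kde(x, bw_method="silverman")
    grid = np.linspace(lo, hi, 512)
    return float(grid[np.argmax(kde(grid))])


def hpd_interval(chain: np.ndarray, prob: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``ceil(prob*n)`` samples."""
    if not 0.0 < prob < 1.0:
        raise ValueError("prob must be in (0, 1)")
    x = np.sort(np.asarray(chain, dtype=float))
    n = len(x)
    m = int(np.ceil(prob * n))
    if m < 1 or n == 0:
        raise ValueError("chain too short for the requested probability")
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m - 1 :] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


def quantile_interval(chain: np.ndarray, prob: float = 0.95) -> tuple[float, float]:
    """Central (equal-tail) credible interval, offered alongside the HPD."""
    if not 0.0 < prob < 1.0:
        raise ValueError("prob must be in (0, 1)")
    a = (1.0 - prob) / 2.0
    lo, hi = np.quantile(np.asarray(chain, dtype=float), [a, 1.0 - a])
    return float(lo), float(hi)
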