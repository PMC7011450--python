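"""Universal response function (URF).

The URF regresses performance Y_ij of population cluster i at planting
site j on climate at the origin (transfer-function part) and at the site
(response-function part), with quadratic terms and the within-variable
origin x site product:

    Y_ij = b0 + b1*X1i + b2*X1i^2 + b3*X2j + b4*X2j^2 + b5*X1i*X2j + e_ij

extended additively over the selected climate variables (no cross-variable
products).  Predictors are z-scored before the polynomial expansion —
with raw units the squared and product columns are wildly scaled — and
the scaling record is stored so grid prediction applies the identical
transform.  Predictions outside the training climate box are flagged as
extrapolated, never clipped: extreme out-of-range predictions are a real
failure mode of response surfaces fitted on few sites and must stay
visible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SingularDesignError",
    "URFDesign",
    "URFFit",
    "cluster_climate",
    "cluster_site_performance",
    "build_urf_design",
    "fit_urf",
    "predict_surface",
]


class SingularDesignError(ValueError):
    """Raised when the response-surface design is rank deficient."""


def cluster_climate(origins: pd.DataFrame, assignment: pd.DataFrame, variables: list[str]) -> pd.DataFrame:
    """Cluster-level origin climate: mean over member locations.

    ``assignment`` maps location_id -> cluster.
    """
    merged = origins.merge(assignment, on="location_id")
    return merged.groupby("cluster", as_index=False)[variables].mean()


def cluster_site_performance(
    chains,
    scaling,
    mode: str = "posterior",
    data: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Cluster-by-site performance table in original trait units.

    mode='posterior' (default): back-transformed posterior mean of
    site intercept + cluster effect from the mixed model, i.e.
    mean_j + sd_j * (beta_j + p_ij).  mode='raw': plain cluster-by-site
    mean of the raw trait values (``data`` required).
    """
    if mode == "raw":
        if data is None:
            raise ValueError("raw mode needs the trial data")
        df = data[data["trait"] == chains.trait]
        out = (
            df.groupby(["population", "site"], as_index=False)["value"]
            .mean()
            .rename(columns={"population": "cluster", "value": "performance"})
        )
        return out
    if chains.pop_effect_mean is None:
        raise ValueError("chains carry no population effects")
    beta = chains.beta.mean(axis=0)
    rows = []
    for i, cl in enumerate(chains.populations):
        for j, site in enumerate(chains.environments):
            std_value = beta[j] + chains.pop_effect_mean[i, j]
            rows.append((cl, site, float(scaling.unstandardize(site, chains.trait, std_value))))
    return pd.DataFrame(rows, columns=["cluster", "site", "performance"])


@dataclass
class URFDesign:
    """Expanded, scaled regression design for the response surface."""

    y: np.ndarray
    X: np.ndarray  # without intercept column
    columns: list[str]
    variables: list[str]
    scaling: dict[str, tuple[float, float]]  # scaled base column -> (mean, sd)
    train_ranges: dict[str, tuple[float, float]]  # raw min/max per base column
    rows: pd.DataFrame  # (cluster, site) bookkeeping


def _zscore(col: np.ndarray, name: str):
    mean, sd = float(col.mean()), float(col.std(ddof=1))
    if sd == 0 or not np.isfinite(sd):
        raise SingularDesignError(f"climate column {name!r} is constant in the training data")
    return (col - mean) / sd, (mean, sd)


def _expand(origin_scaled: dict[str, np.ndarray], site_scaled: dict[str, np.ndarray], variables):
    cols, names = [], []
    for v in variables:
        o, s = origin_scaled[v], site_scaled[v]
        for name, col in (
            (f"{v}_origin", o),
            (f"{v}_origin_sq", o * o),
            (f"{v}_site", s),
            (f"{v}_site_sq", s * s),
            (f"{v}_origin_x_site", o * s),
        ):
            names.append(name)
            cols.append(col)
    return np.column_stack(cols), names


def _check_rank(X: np.ndarray, names: list[str]):
    A = np.column_stack([np.ones(len(X)), X])
    u, sv, vt = np.linalg.svd(A, full_matrices=False)
    tol = sv.max() * max(A.shape) * np.finfo(float).eps * 1e3
    rank = int((sv > tol).sum())
    if rank < A.shape[1]:
        # name columns loading on the null space
        null = vt[rank:]
        involved = sorted(
            {(["intercept"] + names)[j] for row in null for j in np.flatnonzero(np.abs(row) > 1e-6)}
        )
        raise SingularDesignError(
            f"rank-deficient design (rank {rank} < {A.shape[1]}); "
            f"linearly dependent columns involve: {involved}. "
            "Too few distinct site climates for the site-level polynomial terms."
        )


def build_urf_design(
    performance: pd.DataFrame,
    origins: pd.DataFrame,
    sites: pd.DataFrame,
    variables: list[str],
) -> URFDesign:
    """Assemble the URF design from cluster performance and climates.

    ``performance`` has columns (cluster, site, performance); ``origins``
    gives cluster-level climate (column ``cluster`` + variables);
    ``sites`` gives site climate (column ``site`` or ``site_id`` +
    variables).  Each climate column is z-scored over the design rows,
    then squares and within-variable origin x site products are formed
    from the scaled columns.  Rank deficiency — e.g. fewer distinct site
    climates than site-level parameters plus intercept — raises a
    :class:`SingularDesignError` naming the dependent columns.
    """
    sites = sites.rename(columns={"site_id": "site"})
    df = performance.merge(origins, on="cluster", how="left", suffixes=("", "_origin"))
    df = df.merge(sites, on="site", how="left", suffixes=("_origin", "_site"))
    for v in variables:
        for side in ("origin", "site"):
            if f"{v}_{side}" not in df.columns:
                if v in df.columns:  # unsuffixed (only one table had it)
                    df = df.rename(columns={v: f"{v}_{side}"})
                else:
                    raise ValueError(f"missing climate variable {v!r} for the {side} side")
        if df[[f"{v}_origin", f"{v}_site"]].isna().any().any():
            missing = df.loc[df[[f"{v}_origin", f"{v}_site"]].isna().any(axis=1), ["cluster", "site"]]
            raise ValueError(f"rows missing {v!r} climate: {missing.to_records(index=False)}")

    scaling, train_ranges = {}, {}
    origin_scaled, site_scaled = {}, {}
    for v in variables:
        o_raw = df[f"{v}_origin"].to_numpy(dtype=float)
        s_raw = df[f"{v}_site"].to_numpy(dtype=float)
        origin_scaled[v], scaling[f"{v}_origin"] = _zscore(o_raw, f"{v}_origin")
        site_scaled[v], scaling[f"{v}_site"] = _zscore(s_raw, f"{v}_site")
        train_ranges[f"{v}_origin"] = (float(o_raw.min()), float(o_raw.max()))
        train_ranges[f"{v}_site"] = (float(s_raw.min()), float(s_raw.max()))
    X, names = _expand(origin_scaled, site_scaled, variables)
    _check_rank(X, names)
    return URFDesign(
        y=df["performance"].to_numpy(dtype=float),
        X=X,
        columns=names,
        variables=list(variables),
        scaling=scaling,
        train_ranges=train_ranges,
        rows=df[["cluster", "site"]].copy(),
    )


@dataclass
class URFFit:
    """OLS fit of the response surface with per-term diagnostics."""

    variables: list[str]
    columns: list[str]  # regressor names, intercept first
    coef: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    r2: float
    term_r2: dict[str, float]  # marginal squared correlation with Y
    scaling: dict[str, tuple[float, float]]
    train_ranges: dict[str, tuple[float, float]]
    n: int
    residuals: np.ndarray

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.columns,
                "estimate": self.coef,
                "se": self.se,
                "t": self.t,
                "p": self.p,
                "marginal_r2": [self.term_r2.get(c, np.nan) for c in self.columns],
            }
        )

    def to_json(self, path=None) -> str:
        import json

        payload = {
            "variables": self.variables,
            "columns": self.columns,
            "coef": self.coef.tolist(),
            "se": self.se.tolist(),
            "t": self.t.tolist(),
            "p": self.p.tolist(),
            "r2": self.r2,
            "term_r2": self.term_r2,
            "scaling": {k: list(v) for k, v in self.scaling.items()},
            "train_ranges": {k: list(v) for k, v in self.train_ranges.items()},
            "n": self.n,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "URFFit":
        import json

        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            try:
                payload = json.loads(source)
            except (json.JSONDecodeError, TypeError):
                with open(source) as fh:
                    payload = json.load(fh)
        return cls(
            variables=payload["variables"],
            columns=payload["columns"],
            coef=np.asarray(payload["coef"]),
            se=np.asarray(payload["se"]),
            t=np.asarray(payload["t"]),
            p=np.asarray(payload["p"]),
            r2=payload["r2"],
            term_r2=payload["term_r2"],
            scaling={k: tuple(v) for k, v in payload["scaling"].items()},
            train_ranges={k: tuple(v) for k, v in payload["train_ranges"].items()},
            n=payload["n"],
            residuals=np.array([]),
        )


def fit_urf(design: URFDesign) -> URFFit:
    """Ordinary least squares on the expanded design.

    Standard errors from the residual variance times the inverse
    cross-product diagonal; two-sided t p-values on n - p - 1 degrees of
    freedom (p regressors plus intercept).  A singular cross-product is
    an error — never a silent pseudo-inverse.
    """
    n = len(design.y)
    A = np.column_stack([np.ones(n), design.X])
    p_cols = A.shape[1]
    if n <= p_cols:
        raise ValueError(f"need n > parameters ({n} rows, {p_cols} parameters)")
    AtA = A.T @ A
    cond = np.linalg.cond(AtA)
    if not np.isfinite(cond) or cond > 1e12:
        raise SingularDesignError(f"singular normal equations (condition number {cond:.3g})")
    try:
        L = np.linalg.cholesky(AtA)
    except np.linalg.LinAlgError as exc:
        raise SingularDesignError("singular normal equations") from exc
    coef = np.linalg.solve(AtA, A.T @ design.y)
    fitted = A @ coef
    resid = design.y - fitted
    dof = n - p_cols
    sse = float(resid @ resid)
    sst = float(((design.y - design.y.mean()) ** 2).sum())
    sigma2 = sse / dof
    AtA_inv = np.linalg.inv(AtA)
    se = np.sqrt(sigma2 * np.diag(AtA_inv))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = coef / se
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    r2 = 1.0 - sse / sst if sst > 0 else float("nan")
    term_r2 = {}
    yc = design.y - design.y.mean()
    for j, name in enumerate(design.columns):
        xc = design.X[:, j] - design.X[:, j].mean()
        denom = np.sqrt((xc @ xc) * (yc @ yc))
        term_r2[name] = float((xc @ yc) ** 2 / denom**2) if denom > 0 else float("nan")
    return URFFit(
        variables=design.variables,
        columns=["intercept"] + design.columns,
        coef=coef,
        se=se,
        t=t,
        p=p,
        r2=float(r2),
        term_r2=term_r2,
        scaling=design.scaling,
        train_ranges=design.train_ranges,
        n=n,
        residuals=resid,
    )


def predict_surface(fit: URFFit, grid: pd.DataFrame, origin_climate: dict[str, float]) -> pd.DataFrame:
    """Evaluate the fitted surface over a climate grid for one cluster.

    ``origin_climate`` fixes the origin-side values (the chosen cluster's
    climate); the grid supplies site-side climate per cell.  The training
    z-scaling is applied to both sides.  Cells whose climate (site side,
    or the fixed origin values) falls outside the training min-max box are
    flagged ``extrapolated``; predictions are never clipped.
    """
    for v in fit.variables:
        if v not in grid.columns:
            raise ValueError(f"grid is missing climate variable {v!r}")
        if v not in origin_climate:
            raise ValueError(f"origin_climate is missing variable {v!r}")
    n = len(grid)
    origin_scaled, site_scaled = {}, {}
    extrapolated = np.zeros(n, dtype=bool)
    origin_out = False
    for v in fit.variables:
        mo, so = fit.scaling[f"{v}_origin"]
        ms, ss = fit.scaling[f"{v}_site"]
        o_raw = float(origin_climate[v])
        s_raw = grid[v].to_numpy(dtype=float)
        origin_scaled[v] = np.full(n, (o_raw - mo) / so)
        site_scaled[v] = (s_raw - ms) / ss
        lo, hi = fit.train_ranges[f"{v}_site"]
        extrapolated |= (s_raw < lo) | (s_raw > hi)
        olo, ohi = fit.train_ranges[f"{v}_origin"]
        origin_out |= not (olo <= o_raw <= ohi)
    X, names = _expand(origin_scaled, site_scaled, fit.variables)
    assert names == fit.columns[1:]
    pred = fit.coef[0] + X @ fit.coef[1:]
    out = grid[["lon", "lat"]].copy() if {"lon", "lat"}.issubset(grid.columns) else pd.DataFrame(index=grid.index)
    out["predicted"] = pred
    out["extrapolated"] = extrapolated | origin_out
    return out
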