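"""Climate summaries and the collinearity screen for response-function inputs.

Monthly climate normals are reduced to annual variables (means for
temperature-like variables, the annual sum for precipitation), then a
pairwise Pearson correlation screen identifies a low-collinearity variable
pair for the universal response function — with highly collinear inputs
the response-surface regression becomes singular, so variable selection is
part of the method, not cosmetics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CorrMatrix",
    "summarize_monthly",
    "correlation_matrix",
    "select_variable_pair",
    "SUM_VARIABLES",
]

# variables accumulated over the year rather than averaged
SUM_VARIABLES = frozenset({"precipitation", "precip", "rain", "rainfall"})


def summarize_monthly(monthly: pd.DataFrame, sum_variables=SUM_VARIABLES) -> pd.DataFrame:
    """Annual summary of monthly climate values.

    ``monthly`` is tidy: columns ``entity_id, variable, month, value`` with
    months 1..12.  Temperature-like variables are averaged over the twelve
    months; variables named in ``sum_variables`` (precipitation) are summed.
    A missing month is an error naming the entity and variable.
    """
    required = {"entity_id", "variable", "month", "value"}
    if not required.issubset(monthly.columns):
        raise ValueError(f"monthly table must have columns {sorted(required)}")
    bad = []
    for (ent, var), grp in monthly.groupby(["entity_id", "variable"], sort=False):
        months = set(int(m) for m in grp["month"])
        if months != set(range(1, 13)) or grp["value"].isna().any():
            bad.append((ent, var))
    if bad:
        raise ValueError(f"incomplete monthly records (entity, variable): {bad}")

    def agg(grp):
        var = grp.name[1]
        vals = grp["value"].to_numpy(dtype=float)
        return vals.sum() if var.lower() in sum_variables else vals.mean()

    wide = (
        monthly.groupby(["entity_id", "variable"], sort=True)
        .apply(agg, include_groups=False)
        .unstack("variable")
        .sort_index()
    )
    wide.index.name = "entity_id"
    return wide


@dataclass
class CorrMatrix:
    """Pairwise-complete Pearson correlations with per-pair sample sizes."""

    variables: list[str]
    r: pd.DataFrame  # square, unit diagonal, NaN where undefined
    n: pd.DataFrame  # rows used per pair

    def pairs(self) -> pd.DataFrame:
        """Long-form table of unordered variable pairs with r, |r| and n."""
        rows = []
        for i, a in enumerate(self.variables):
            for b in self.variables[i + 1 :]:
                rows.append((a, b, self.r.loc[a, b], abs(self.r.loc[a, b]), self.n.loc[a, b]))
        return pd.DataFrame(rows, columns=["var_a", "var_b", "r", "abs_r", "n"])

    def to_csv(self, path):
        self.r.to_csv(path)


def correlation_matrix(table: pd.DataFrame, variables: list[str] | None = None) -> CorrMatrix:
    """Pearson correlation matrix over the numeric columns of ``table``.

    Missing rows are handled pairwise-complete, with the rows used per pair
    reported.  A variable with zero variance (over the rows complete for a
    pair) yields NaN for that pair — undefined, never silently zero.
    """
    if variables is None:
        variables = [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
    if len(table) < 3:
        raise ValueError("need at least 3 rows for a correlation screen")
    k = len(variables)
    r = np.full((k, k), np.nan)
    n = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(i, k):
            x = table[variables[i]].to_numpy(dtype=float)
            y = table[variables[j]].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            n[i, j] = n[j, i] = ok.sum()
            if i == j:
                r[i, i] = 1.0
                continue
            xs, ys = x[ok], y[ok]
            if ok.sum() < 2 or np.ptp(xs) == 0 or np.ptp(ys) == 0:
                continue  # undefined; stays NaN
            xc, yc = xs - xs.mean(), ys - ys.mean()
            r[i, j] = r[j, i] = float(
                (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
            )
    return CorrMatrix(
        variables=list(variables),
        r=pd.DataFrame(r, index=variables, columns=variables),
        n=pd.DataFrame(n, index=variables, columns=variables),
    )


def select_variable_pair(corr: CorrMatrix, threshold: float = 0.7):
    """Pick the variable pair with the smallest |r| below ``threshold``.

    The default threshold of 0.7 is the common collinearity rule of thumb.
    Returns ``(pair, report)`` where ``report`` lists every pair with its
    |r| (sorted ascending, lexicographic tie-break).  If no pair falls
    below the threshold the screen fails loudly: fitting a response surface
    on collinear climate is exactly the singularity this step prevents.
    """
    if len(corr.variables) < 2:
        raise ValueError("need at least 2 variables")
    report = corr.pairs().sort_values(
        ["abs_r", "var_a", "var_b"], kind="mergesort"
    ).reset_index(drop=True)
    candidates = report[(report["abs_r"] < threshold) & report["r"].notna()]
    if candidates.empty:
        raise ValueError(
            f"all variable pairs are collinear (|r| >= {threshold}); "
            "no admissible pair for the response function"
        )
    best = candidates.iloc[0]
    return (best["var_a"], best["var_b"]), report
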