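"""Genotype rank stability across environments.

Genotypes are ranked within each environment on their (posterior-mean)
effects, 1 = best.  The average clonal rank is the arithmetic mean of a
genotype's ranks over the environments where it occurs, and the
dispersion of its pairwise absolute rank changes between environments is
the boxplot statistic used to spot rank-unstable individuals — the
graphical face of GxE.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["RankTable", "rank_genotypes", "rank_change_stats", "effects_frame", "plot_rank_boxes"]


@dataclass
class RankTable:
    """Genotype x environment ranks plus average clonal rank."""

    ranks: pd.DataFrame  # genotypes x environments, NaN where absent
    average: pd.Series  # mean rank per genotype over present environments

    @property
    def environments(self) -> list[str]:
        return list(self.ranks.columns)


def effects_frame(chains) -> pd.DataFrame:
    """Posterior-mean genotype effects as a genotype x environment frame."""
    if chains.gen_effect_mean is None:
        raise ValueError("chains carry no genotype effects")
    return pd.DataFrame(
        chains.gen_effect_mean, index=chains.genotypes, columns=chains.environments
    )


def rank_genotypes(effects: pd.DataFrame) -> RankTable:
    """Rank genotypes within each environment, descending on effect.

    Ties are broken by genotype identifier so each environment's ranks are
    a permutation of 1..n (over genotypes present there).  Genotypes
    absent everywhere are excluded with a log entry.
    """
    present = effects.notna().any(axis=1)
    dropped = list(effects.index[~present])
    if dropped:
        logger.info("excluding genotypes absent in every environment: %s", dropped)
    eff = effects.loc[present]
    ranks = pd.DataFrame(index=eff.index, columns=eff.columns, dtype=float)
    for env in eff.columns:
        col = eff[env].dropna()
        order = sorted(col.index, key=lambda g: (-col[g], str(g)))
        for r, g in enumerate(order, start=1):
            ranks.loc[g, env] = float(r)
    avg = ranks.mean(axis=1, skipna=True)
    return RankTable(ranks=ranks, average=avg)


def rank_change_stats(rt: RankTable) -> pd.DataFrame:
    """Pairwise absolute rank changes per genotype, ordered by average rank.

    Long-form output (one row per genotype and environment pair) carrying
    the genotype's average rank and min/median/max of its changes — the
    data behind the rank-change boxplot.  Rank changes are invariant to
    any strictly monotone transform of the underlying effects.
    """
    envs = rt.environments
    if len(envs) < 2:
        raise ValueError("rank-change statistics need >= 2 environments")
    rows = []
    for g in rt.ranks.index:
        r = rt.ranks.loc[g]
        changes = []
        for i in range(len(envs)):
            for j in range(i + 1, len(envs)):
                if np.isfinite(r[envs[i]]) and np.isfinite(r[envs[j]]):
                    changes.append((envs[i], envs[j], abs(r[envs[i]] - r[envs[j]])))
        if not changes:
            continue
        vals = np.array([c[2] for c in changes])
        for ei, ej, c in changes:
            rows.append(
                (g, float(rt.average[g]), ei, ej, float(c),
                 float(vals.min()), float(np.median(vals)), float(vals.max()))
            )
    out = pd.DataFrame(
        rows,
        columns=["genotype", "avg_rank", "env_i", "env_j", "rank_change", "min", "median", "max"],
    )
    return out.sort_values(["avg_rank", "genotype"], kind="mergesort").reset_index(drop=True)


def plot_rank_boxes(stats: pd.DataFrame, path, max_genotypes: int | None = None):
    """Basic boxplot of pairwise rank changes, genotypes ordered by average rank."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = stats.drop_duplicates("genotype")["genotype"].tolist()
    if max_genotypes:
        order = order[:max_genotypes]
    data = [stats.loc[stats["genotype"] == g, "rank_change"].to_numpy() for g in order]
    fig, ax = plt.subplots(figsize=(max(6, 0.25 * len(order)), 4))
    ax.boxplot(data, tick_labels=order)
    ax.set_xlabel("genotype (ordered by average clonal rank)")
    ax.set_ylabel("pairwise rank change between environments")
    ax.tick_params(axis="x", rotation=90, labelsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
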