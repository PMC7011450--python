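"""Broad-sense heritabilities and between-site genetic correlations.

From the posterior chains of the multi-environment mixed model this
module computes, per site,

    H2_pop = s2_pop / (s2_pop + s2_gen + s2_e)
    H2_gen = s2_gen / (s2_pop + s2_gen + s2_e)

and, per site pair at population or genotype level, the Pearson
product-moment genetic correlation

    r_GE = cov_ij / sqrt(s2_i * s2_j).

The denominator of the heritabilities deliberately excludes the replicate
and block variances: design variance is treated as removable noise, which
matches the formulas above but differs from definitions that include it —
worth remembering when comparing across studies.

Every ratio is evaluated per MCMC sample and the posterior mode / HPD
interval is taken of the *ratio chain*, never the ratio of modes — for
skewed posteriors the two differ.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from clonegxe.mixed_model import PosteriorChains, hpd_interval, posterior_mode

logger = logging.getLogger(__name__)

__all__ = [
    "GeneticSummary",
    "heritability_population",
    "heritability_genotype",
    "genetic_correlation",
    "summarize",
    "GXE_CORRELATION_RULE",
]

# rule of thumb: a between-site genetic correlation whose interval stays
# above this value indicates no practically important GxE
GXE_CORRELATION_RULE = 0.7


def _ratio_summary(num: np.ndarray, den: np.ndarray, prob: float):
    ok = den > 0
    dropped = int((~ok).sum())
    if dropped:
        logger.info("dropped %d samples with zero denominator", dropped)
    if ok.sum() == 0:
        raise ValueError("denominator is zero in every sample")
    ratio = num[ok] / den[ok]
    return float(posterior_mode(ratio)), hpd_interval(ratio, prob), ratio


def heritability_population(chains: PosteriorChains, site: str, prob: float = 0.95):
    """Population-level broad-sense heritability at ``site``.

    Returns (mode, (lower, upper)) of the per-sample ratio chain.
    """
    num = chains.var_chain("population", site)
    den = num + chains.var_chain("genotype", site) + chains.var_chain("residual", site)
    mode, ci, _ = _ratio_summary(num, den, prob)
    return mode, ci


def heritability_genotype(chains: PosteriorChains, site: str, prob: float = 0.95):
    """Genotype-within-population broad-sense heritability at ``site``."""
    num = chains.var_chain("genotype", site)
    den = chains.var_chain("population", site) + num + chains.var_chain("residual", site)
    mode, ci, _ = _ratio_summary(num, den, prob)
    return mode, ci


def genetic_correlation(
    chains: PosteriorChains,
    site_i: str,
    site_j: str,
    level: str = "genotype",
    prob: float = 0.95,
    var_floor: float = 1e-12,
):
    """Between-site genetic correlation at population or genotype level.

    r is computed per sample from the sampled covariance matrix (each
    sample is positive definite, so r lies in [-1, 1] by construction —
    no post-hoc clipping).  When either variance is essentially zero
    across samples the correlation is undefined: returns (nan, (nan, nan))
    with a diagnostic log entry, mirroring the inestimable case of a site
    with no genetic component.
    """
    cov = chains.cov_chain(level, site_i, site_j)
    vi = chains.var_chain(level, site_i)
    vj = chains.var_chain(level, site_j)
    if np.median(vi) < var_floor or np.median(vj) < var_floor:
        logger.warning(
            "correlation %s/%s at %s level undefined: variance ~ 0", site_i, site_j, level
        )
        return float("nan"), (float("nan"), float("nan"))
    r = cov / np.sqrt(vi * vj)
    return float(posterior_mode(r)), hpd_interval(r, prob)


@dataclass
class GeneticSummary:
    """Posterior modes and 95% limits of everything the analysis reports."""

    trait: str
    sites: list[str]
    components: pd.DataFrame  # rows: (site, term) -> mode, lower, upper
    heritability: pd.DataFrame  # rows: (site, level) -> mode, lower, upper
    correlations: pd.DataFrame  # rows: (site_i, site_j, level) -> mode, lower, upper, important_gxe

    def correlation_matrix(self) -> pd.DataFrame:
        """Site-by-site matrix: population level above the diagonal,
        genotype level below, 1 on the diagonal."""
        m = pd.DataFrame(np.eye(len(self.sites)), index=self.sites, columns=self.sites)
        for _, row in self.correlations.iterrows():
            i, j = row["site_i"], row["site_j"]
            if row["level"] == "population":
                m.loc[min(i, j), max(i, j)] = row["mode"]
            else:
                m.loc[max(i, j), min(i, j)] = row["mode"]
        return m

    def to_json(self, path=None) -> str:
        payload = {
            "trait": self.trait,
            "sites": self.sites,
            "components": self.components.to_dict(orient="records"),
            "heritability": self.heritability.to_dict(orient="records"),
            "correlations": self.correlations.to_dict(orient="records"),
        }
        text = json.dumps(payload, indent=2, allow_nan=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "GeneticSummary":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            try:
                payload = json.loads(source)
            except (json.JSONDecodeError, TypeError):
                with open(source) as fh:
                    payload = json.load(fh)
        return cls(
            trait=payload["trait"],
            sites=payload["sites"],
            components=pd.DataFrame(payload["components"]),
            heritability=pd.DataFrame(payload["heritability"]),
            correlations=pd.DataFrame(payload["correlations"]),
        )


def summarize(chains: PosteriorChains, prob: float = 0.95) -> GeneticSummary:
    """Full per-site / per-site-pair report from one trait's chains.

    A site-pair correlation is flagged ``important_gxe`` when the upper
    interval limit stays below 0.7 (the interaction cannot be dismissed).
    """
    sites = chains.environments
    comp_rows = []
    terms = ["population", "genotype", "rep", "block", "residual"]
    for site in sites:
        for term in terms:
            try:
                c = chains.var_chain(term, site)
            except (KeyError, TypeError):
                continue
            if c is None:
                continue
            comp_rows.append(
                (site, term, posterior_mode(c), *hpd_interval(c, prob))
            )
    comps = pd.DataFrame(comp_rows, columns=["site", "term", "mode", "lower", "upper"])

    her_rows = []
    for site in sites:
        m, ci = heritability_population(chains, site, prob)
        her_rows.append((site, "population", m, *ci))
        m, ci = heritability_genotype(chains, site, prob)
        her_rows.append((site, "genotype", m, *ci))
    her = pd.DataFrame(her_rows, columns=["site", "level", "mode", "lower", "upper"])

    cor_rows = []
    for level in ("population", "genotype"):
        if (chains.G1 if level == "population" else chains.G2) is None:
            continue
        for a in range(len(sites)):
            for b in range(a + 1, len(sites)):
                m, ci = genetic_correlation(chains, sites[a], sites[b], level, prob)
                important = bool(np.isfinite(ci[1]) and ci[1] < GXE_CORRELATION_RULE)
                cor_rows.append((sites[a], sites[b], level, m, ci[0], ci[1], important))
    cors = pd.DataFrame(
        cor_rows,
        columns=["site_i", "site_j", "level", "mode", "lower", "upper", "important_gxe"],
    )
    return GeneticSummary(
        trait=chains.trait, sites=list(sites), components=comps,
        heritability=her, correlations=cors,
    )
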