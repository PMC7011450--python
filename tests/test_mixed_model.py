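import math

import numpy as np
import pandas as pd
import pytest

from clonegxe import (
    MCMCOptions,
    ModelSpec,
    build_design,
    gibbs_sample,
    hpd_interval,
    posterior_mode,
    standardize_phenotypes,
)
from clonegxe.mixed_model import quantile_interval


def long_frame(rows):
    return pd.DataFrame(
        rows, columns=["site", "rep", "block", "population", "genotype", "ramet", "trait", "value"]
    )


def one_way_data(n_gen, n_ramets, s2g, s2e, seed, site="S1"):
    """Balanced single-site one-way layout: genotype + residual only."""
    rng = np.random.default_rng(seed)
    g = rng.normal(0, math.sqrt(s2g), n_gen)
    rows = []
    for i in range(n_gen):
        for t in range(n_ramets):
            rows.append(
                (site, "R1", "B1", "P1", f"G{i:03d}", f"G{i:03d}_{t}", "DBH",
                 g[i] + rng.normal(0, math.sqrt(s2e)))
            )
    return long_frame(rows)


class TestStandardize:
    def test_values_and_round_trip(self):
        df = long_frame(
            [("S1", "R1", "B1", "P1", "G1", f"r{i}", "DBH", v) for i, v in enumerate([3.0, 5.0, 7.0])]
        )
        std, scaling = standardize_phenotypes(df)
        np.testing.assert_allclose(std["value"], [-1, 0, 1])
        back = scaling.unstandardize("S1", "DBH", std["value"].to_numpy())
        np.testing.assert_allclose(back, [3, 5, 7], atol=1e-12)

    def test_idempotent_on_standardized(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=30)
        vals = (vals - vals.mean()) / vals.std(ddof=1)
        df = long_frame([("S1", "R1", "B1", "P1", "G1", f"r{i}", "DBH", v) for i, v in enumerate(vals)])
        std, _ = standardize_phenotypes(df)
        np.testing.assert_allclose(std["value"], vals, atol=1e-12)

    def test_zero_variance_names_site_and_trait(self):
        df = long_frame([("Taupo", "R1", "B1", "P1", "G1", f"r{i}", "DBH", 5.0) for i in range(4)])
        with pytest.raises(ValueError, match="Taupo.*DBH"):
            standardize_phenotypes(df)


class TestBuildDesign:
    def test_single_site_two_populations(self):
        df = long_frame(
            [
                ("S1", "R1", "B1", "P1", "G1", "a", "DBH", 1.0),
                ("S1", "R1", "B1", "P2", "G2", "b", "DBH", 2.0),
            ]
        )
        d = build_design(df, ModelSpec("DBH"))
        Zp = d.W[:, d.slices["population"]]
        assert Zp.shape == (2, 2)
        np.testing.assert_allclose(Zp.sum(axis=1), 1.0)

    def test_population_columns_scale_with_environments(self, small_chains):
        _, _, std = small_chains
        d = build_design(std, ModelSpec("DBH"))
        assert d.W[:, d.slices["population"]].shape[1] == 4 * 30
        # every incidence block partitions the observations
        for term in ("beta", "population", "genotype", "rep", "block"):
            np.testing.assert_allclose(d.W[:, d.slices[term]].sum(axis=1), 1.0)

    def test_genotype_in_two_populations_rejected(self):
        df = long_frame(
            [
                ("S1", "R1", "B1", "P1", "G1", "a", "DBH", 1.0),
                ("S1", "R1", "B1", "P2", "G1", "b", "DBH", 2.0),
            ]
        )
        with pytest.raises(ValueError, match="G1"):
            build_design(df, ModelSpec("DBH"))


class TestPosteriorMode:
    def test_constant_chain(self):
        assert posterior_mode(np.full(500, 0.3)) == 0.3

    def test_symmetric_unimodal_mode_near_mean(self):
        x = np.random.default_rng(0).normal(1.7, 0.2, 20_000)
        # within KDE grid resolution of the mean (range/512 ~ 0.003, plus KDE noise)
        assert abs(posterior_mode(x) - x.mean()) < 0.05

    def test_bimodal_mixture_finds_dominant_mode_not_mean(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(0.2, 0.01, 900), rng.normal(0.8, 0.01, 100)])
        m = posterior_mode(x)
        assert abs(m - 0.2) < 0.02
        assert abs(x.mean() - 0.26) < 0.01  # the mean is far from the mode


def hpd_oracle(x, prob):
    xs = sorted(x)
    n = len(xs)
    m = math.ceil(prob * n)
    if m >= n:
        return xs[0], xs[-1]
    return min(((xs[i + m - 1] - xs[i], xs[i], xs[i + m - 1]) for i in range(n - m + 1)))[1:]


class TestIntervals:
    def test_integer_ladder(self):
        lo, hi = hpd_interval(np.arange(1, 101), 0.95)
        assert hi - lo == 94
        assert (lo, hi) == (1, 95)

    def test_constant_chain_zero_width(self):
        lo, hi = hpd_interval(np.full(200, 1.5), 0.95)
        assert lo == hi == 1.5

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_window_enumeration_oracle(self, seed):
        x = np.random.default_rng(seed).gamma(2.0, 1.0, 500)
        assert hpd_interval(x, 0.9) == pytest.approx(hpd_oracle(x, 0.9))

    def test_symmetric_sample_roughly_symmetric_interval(self):
        x = np.random.default_rng(2).normal(0, 1, 50_000)
        lo, hi = hpd_interval(x, 0.95)
        assert abs((hi + lo) / 2) < 0.05
        qlo, qhi = quantile_interval(x, 0.95)
        assert abs(lo - qlo) < 0.05 and abs(hi - qhi) < 0.05

    def test_invalid_probability(self):
        with pytest.raises(ValueError):
            hpd_interval(np.arange(10), 1.5)


class TestGibbs:
    def test_single_environment_recovery_and_anova_oracle(self):
        """Posterior mean of the genotype variance ratio agrees with the
        method-of-moments ANOVA estimator on a balanced one-way layout."""
        n_gen, r = 80, 6
        data = one_way_data(n_gen, r, s2g=0.5, s2e=0.5, seed=42)
        std, _ = standardize_phenotypes(data)
        spec = ModelSpec("DBH", random_terms=("genotype",))
        opts = MCMCOptions(iterations=3000, burn_in=500, thinning=5, seed=0)
        ch = gibbs_sample(std, spec, opts)
        s2g = ch.var_chain("genotype", "S1")
        s2e = ch.var_chain("residual", "S1")
        # parameter recovery: generating ratio is 0.5
        assert abs(s2g.mean() - 0.5) < 3 * s2g.std(ddof=1)
        # independent oracle: one-way ANOVA moment estimator on the same data
        wide = std.pivot_table(index="genotype", columns="ramet", values="value")
        vals = std["value"].to_numpy()
        means = std.groupby("genotype")["value"].mean().to_numpy()
        msb = r * means.var(ddof=1)
        msw = (std.groupby("genotype")["value"].var(ddof=1)).mean()
        s2g_mom = max((msb - msw) / r, 0.0)
        h2_mom = s2g_mom / (s2g_mom + msw)
        h2_post = (s2g / (s2g + s2e)).mean()
        assert abs(h2_post - h2_mom) < 0.06

    def test_seed_determinism(self):
        data = one_way_data(20, 3, 0.4, 0.6, seed=1)
        std, _ = standardize_phenotypes(data)
        spec = ModelSpec("DBH", random_terms=("genotype",))
        opts = MCMCOptions(iterations=400, burn_in=100, thinning=2, seed=9)
        a = gibbs_sample(std, spec, opts)
        b = gibbs_sample(std, spec, opts)
        np.testing.assert_array_equal(a.G2, b.G2)
        np.testing.assert_array_equal(a.s2_e, b.s2_e)

    def test_chain_length_and_psd_invariant(self, small_chains):
        ch, _, _ = small_chains
        assert ch.n_samples == (2000 - 500 + 5 - 1) // 5
        assert ch.check_psd()

    def test_mode_stable_under_doubling_iterations(self):
        data = one_way_data(40, 4, 0.5, 0.5, seed=5)
        std, _ = standardize_phenotypes(data)
        spec = ModelSpec("DBH", random_terms=("genotype",))
        m1 = posterior_mode(
            gibbs_sample(std, spec, MCMCOptions(2000, 400, 2, seed=3)).var_chain("genotype", "S1")
        )
        m2 = posterior_mode(
            gibbs_sample(std, spec, MCMCOptions(4000, 400, 2, seed=3)).var_chain("genotype", "S1")
        )
        assert abs(m1 - m2) < 0.1

    def test_too_few_levels_rejected(self):
        data = one_way_data(1, 5, 0.4, 0.6, seed=0)
        std, _ = standardize_phenotypes(data)
        with pytest.raises(ValueError, match="genotype"):
            gibbs_sample(std, ModelSpec("DBH", random_terms=("genotype",)), MCMCOptions(100, 10, 1, seed=0))

    def test_burn_in_validation(self):
        with pytest.raises(ValueError, match="burn_in"):
            MCMCOptions(iterations=100, burn_in=100)
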