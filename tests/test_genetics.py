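import dataclasses

import numpy as np
import pytest

from clonegxe import (
    MCMCOptions,
    PosteriorChains,
    genetic_correlation,
    heritability_genotype,
    heritability_population,
    posterior_mode,
    summarize,
)
from clonegxe.genetics import GeneticSummary


def make_chains(envs, G1, G2, s2_e, s2_rep=None, s2_block=None):
    """Hand-assembled chains for arithmetic checks."""
    G1, G2, s2_e = np.asarray(G1, float), np.asarray(G2, float), np.asarray(s2_e, float)
    S = s2_e.shape[0]
    return PosteriorChains(
        trait="DBH",
        environments=list(envs),
        options=MCMCOptions(iterations=max(S, 2), burn_in=0 if S > 1 else 1, thinning=1, seed=0),
        beta=np.zeros((S, len(envs))),
        G1=G1,
        G2=G2,
        s2_rep=s2_rep,
        s2_block=s2_block,
        s2_e=s2_e,
    )


class TestHeritabilityArithmetic:
    def test_single_sample_table_values(self):
        """With point-mass chains at variance components 0.41/0.35/0.65 the
        heritability formulas give 0.29 (population) and 0.25 (genotype)."""
        ch = make_chains(["Awaho"], [[[0.41]]], [[[0.35]]], [[0.65]])
        hp, ci_p = heritability_population(ch, "Awaho")
        hg, ci_g = heritability_genotype(ch, "Awaho")
        assert hp == pytest.approx(0.41 / 1.41)
        assert hg == pytest.approx(0.35 / 1.41)
        assert round(hp, 2) == 0.29
        assert round(hg, 2) == 0.25
        assert ci_p == (hp, hp)

    def test_zero_population_variance_gives_zero(self):
        ch = make_chains(["A"], np.zeros((50, 1, 1)), np.full((50, 1, 1), 0.3), np.full((50, 1), 0.7))
        hp, _ = heritability_population(ch, "A")
        assert hp == 0.0

    def test_equal_components_give_one_third(self):
        ch = make_chains(["A"], np.full((1, 1, 1), 0.2), np.full((1, 1, 1), 0.2), np.full((1, 1), 0.2))
        assert heritability_genotype(ch, "A")[0] == pytest.approx(1 / 3)

    def test_bounds_and_shared_denominator(self, small_chains):
        ch, _, _ = small_chains
        for site in ch.environments:
            hp, (lo_p, hi_p) = heritability_population(ch, site)
            hg, _ = heritability_genotype(ch, site)
            assert 0.0 <= lo_p <= hp <= hi_p <= 1.0
            # per-sample sum bound: same denominator, non-negative terms
            num = ch.var_chain("population", site) + ch.var_chain("genotype", site)
            den = num + ch.var_chain("residual", site)
            assert np.all(num / den <= 1.0)

    def test_mode_of_ratio_not_ratio_of_modes(self):
        rng = np.random.default_rng(0)
        s2p = np.exp(rng.normal(-1.0, 1.4, 4000))  # strongly right-skewed
        ch = make_chains(
            ["A"], s2p.reshape(-1, 1, 1), np.zeros((4000, 1, 1)), np.full((4000, 1), 0.65)
        )
        hp, _ = heritability_population(ch, "A")
        samplewise = posterior_mode(s2p / (s2p + 0.65))
        ratio_of_modes = posterior_mode(s2p) / (posterior_mode(s2p) + 0.65)
        assert hp == pytest.approx(samplewise, abs=1e-12)
        assert abs(hp - ratio_of_modes) > 0.01


class TestGeneticCorrelation:
    def test_zero_covariance_chain(self):
        S = 50
        G = np.tile(np.diag([0.4, 0.3]), (S, 1, 1))
        ch = make_chains(["A", "B"], G, G.copy(), np.full((S, 2), 0.6))
        r, (lo, hi) = genetic_correlation(ch, "A", "B", "population")
        assert r == 0.0 and lo == hi == 0.0

    def test_perfect_correlation_chain(self):
        rng = np.random.default_rng(1)
        S = 100
        G = np.empty((S, 2, 2))
        for s in range(S):
            a, b = rng.uniform(0.2, 0.8, 2)
            G[s] = [[a, np.sqrt(a * b)], [np.sqrt(a * b), b]]
        ch = make_chains(["A", "B"], G, G.copy(), np.full((S, 2), 0.6))
        r, _ = genetic_correlation(ch, "A", "B", "population")
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_zero_variance_is_undefined_with_diagnostic(self, caplog):
        S = 50
        G = np.tile(np.diag([0.0, 0.3]), (S, 1, 1))
        ch = make_chains(["A", "B"], G, G.copy(), np.full((S, 2), 0.6))
        r, (lo, hi) = genetic_correlation(ch, "A", "B", "population")
        assert np.isnan(r) and np.isnan(lo)

    def test_recovery_direction_on_simulated_data(self, small_chains):
        """Genotype effects generated with cross-site correlation 0.75 are
        recovered in that regime even by a short chain."""
        ch, _, _ = small_chains
        r, _ = genetic_correlation(ch, "S1", "S2", "genotype")
        assert abs(r - 0.75) < 0.25
        rp, _ = genetic_correlation(ch, "S1", "S2", "population")
        assert rp > 0.7  # generating value 0.99; short chain, directional only

    def test_invariance_to_phenotype_rescaling(self, small_chains):
        ch, _, _ = small_chains
        c = 7.3
        scaled = dataclasses.replace(
            ch, G1=ch.G1 * c**2, G2=ch.G2 * c**2,
            s2_rep=ch.s2_rep * c**2, s2_block=ch.s2_block * c**2, s2_e=ch.s2_e * c**2,
        )
        r1, ci1 = genetic_correlation(ch, "S1", "S3", "genotype")
        r2, ci2 = genetic_correlation(scaled, "S1", "S3", "genotype")
        assert r1 == pytest.approx(r2, abs=1e-9)
        h1, _ = heritability_population(ch, "S1")
        h2, _ = heritability_population(scaled, "S1")
        assert h1 == pytest.approx(h2, abs=1e-9)


class TestSummarize:
    def test_report_shape_and_layout(self, small_chains):
        ch, _, _ = small_chains
        s = summarize(ch)
        assert len(s.heritability) == 4 * 2
        assert len(s.correlations) == 2 * 6  # two levels, C(4,2) pairs
        m = s.correlation_matrix()
        assert list(m.index) == ch.environments
        np.testing.assert_allclose(np.diag(m), 1.0)

    def test_gxe_flag_follows_interval_rule(self):
        rng = np.random.default_rng(3)
        S = 400
        # low-correlation chains: upper limit clearly below 0.7
        G = np.empty((S, 2, 2))
        for s in range(S):
            a, b = rng.uniform(0.3, 0.5, 2)
            r = rng.uniform(-0.1, 0.25)
            G[s] = [[a, r * np.sqrt(a * b)], [r * np.sqrt(a * b), b]]
        ch = make_chains(["A", "B"], G, G.copy(), np.full((S, 2), 0.6))
        s = summarize(ch)
        row = s.correlations[(s.correlations["level"] == "population")].iloc[0]
        assert row["upper"] < 0.7 and bool(row["important_gxe"])

    def test_json_round_trip(self, small_chains, tmp_path):
        ch, _, _ = small_chains
        s = summarize(ch)
        p = tmp_path / "summary.json"
        s.to_json(p)
        back = GeneticSummary.from_json(p)
        assert back.trait == s.trait and back.sites == s.sites
        np.testing.assert_allclose(
            back.heritability["mode"].to_numpy(), s.heritability["mode"].to_numpy()
        )
        np.testing.assert_allclose(
            back.correlations["mode"].to_numpy(), s.correlations["mode"].to_numpy()
        )
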