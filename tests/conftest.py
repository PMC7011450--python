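import numpy as np
import pytest

from clonegxe import (
    MCMCOptions,
    ModelSpec,
    TrialDesign,
    VarianceComponents,
    generate_trial,
    gibbs_sample,
    standardize_phenotypes,
)


def uniform_corr(n: int, r: float) -> np.ndarray:
    m = np.full((n, n), float(r))
    np.fill_diagonal(m, 1.0)
    return m


@pytest.fixture(scope="session")
def study_like_vc() -> VarianceComponents:
    """Variance components of a typical productive-site DBH analysis:
    population 0.41, genotype 0.35, residual 0.65, near-unity cross-site
    population correlation (0.99) and moderate genotype correlation (0.75)."""
    return VarianceComponents(
        n_sites=4,
        sigma2_pop=0.41,
        sigma2_gen=0.35,
        sigma2_rep=0.01,
        sigma2_block=0.01,
        sigma2_resid=0.65,
        corr_pop=uniform_corr(4, 0.99),
        corr_gen=uniform_corr(4, 0.75),
    )


@pytest.fixture(scope="session")
def study_like_design() -> TrialDesign:
    return TrialDesign(
        n_sites=4,
        n_populations=30,
        genotypes_per_population=2,
        reps_per_site=3,
        blocks_per_rep=2,
        ramets_per_genotype_per_site=3,
    )


@pytest.fixture(scope="session")
def small_chains(study_like_design, study_like_vc):
    """A short shared MCMC run on study-like synthetic data.

    Deliberately small (2000 iterations) — enough for structural and
    directional checks; quantitative recovery uses the longer run in the
    acceptance tests.
    """
    data = generate_trial(study_like_design, study_like_vc, seed=11)
    std, scaling = standardize_phenotypes(data)
    opts = MCMCOptions(iterations=2000, burn_in=500, thinning=5, seed=11)
    chains = gibbs_sample(std, ModelSpec("DBH"), opts)
    return chains, scaling, std
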