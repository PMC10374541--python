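import pytest
from hypothesis import HealthCheck, settings

from diallelgs import (
    Phenotypes,
    SimSpec,
    VarianceComponents,
    assemble_mme,
    make_diallel_dataset,
    simulate_phenotypes,
    solve_mme,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_spec():
    return SimSpec(
        N0=10, p=200, vc=VarianceComponents(0.4, 0.2, 0.4), mu=1.0, seed=42
    )


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    """A 10-parent diallel (45 hybrids, 200 SNPs) with kinship built."""
    return make_diallel_dataset(small_spec)


@pytest.fixture(scope="session")
def small_phenotypes(small_dataset, small_spec):
    return simulate_phenotypes(
        small_dataset.kin, small_spec.vc, small_spec.mu, seed=7,
        hybrid_ids=small_dataset.frame.hybrid_ids,
    )


def gls_estimator(vc: VarianceComponents):
    """Cheap deterministic estimator: fixed variance ratios + exact MME solve.

    Useful for exercising the simulation-study and CV harnesses without the
    cost of the Gibbs sampler.
    """

    def estimator(pheno: Phenotypes, kin, seed: int):
        system = assemble_mme(
            pheno, kin.K_A_inv, kin.K_D_inv, vc.lambda_A, vc.lambda_D
        )
        return vc, solve_mme(system)

    return estimator


@pytest.fixture(scope="session")
def fast_estimator():
    return gls_estimator(VarianceComponents(0.4, 0.2, 0.4))
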