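"""Shared fixtures: the published-fit generator truth and reusable
simulated datasets (session-scoped where the computation is heavy)."""

import numpy as np
import pytest

import twinprs as tp

#: point estimates of the published bivariate twin fit: per-trait (A, C, E)
#: proportions, genetic correlation, and the adjusted phenotypic correlation
REPORTED = {
    "components_trait1": (0.85, 0.005, 0.15),
    "components_trait2": (0.47, 0.13, 0.40),
    "r_a": -0.143,
    "r_p": -0.116,
}


@pytest.fixture(scope="session")
def reported_truth() -> tp.GeneratorTruth:
    return tp.calibrate_generator(
        *REPORTED["components_trait1"], *REPORTED["components_trait2"],
        r_a=REPORTED["r_a"], target_rp=REPORTED["r_p"])


@pytest.fixture(scope="session")
def large_twin_data(reported_truth):
    """5000 MZ + 5000 DZ pairs at the calibrated truth (the parameter-
    recovery sample size)."""
    return tp.simulate_twin_dataset(reported_truth, 5000, 5000, seed=20260920)


@pytest.fixture(scope="session")
def recovery_fit(large_twin_data):
    return tp.fit_bivariate_ace(large_twin_data)


@pytest.fixture(scope="session")
def ld_panel():
    """Mid-size LD-block panel shared across PRS tests."""
    return tp.simulate_genotype_panel(600, 100, 10, 0.8, (0.05, 0.5), seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
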