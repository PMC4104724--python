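import numpy as np
import pytest

from plsde import generate_annotation, generate_expression


@pytest.fixture(scope="session")
def cohort():
    """A small separable case/control cohort with planted DE probes."""
    return generate_expression(n_probes=300, n_cases=30, n_controls=14,
                               n_de=20, effect_size=2.0, noise_sd=1.0, seed=42)


@pytest.fixture(scope="session")
def annotation(cohort):
    expr, _, _ = cohort
    return generate_annotation(expr.index, probes_per_gene=1.2,
                               unannotated_fraction=0.02, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
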