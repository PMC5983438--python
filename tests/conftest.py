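"""Shared fixtures: PWM sets and synthetic study bundles.

The scaled study bundle keeps promoter lengths and gene counts small enough
for fast tests while preserving every structural feature of the full study
conditions (three groups, reversal templates, conserved blocks, planted
enriched sites).
"""

import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from promotif.motifs import PWM
from promotif.simulate import (
    SimExpressionConfig,
    SimPromoterConfig,
    make_pwm_set,
    simulate_study,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def pwms():
    return make_pwm_set(n_matrices=6, seed=7)


@pytest.fixture
def toy_pwm():
    """4-position matrix with consensus ACGT and soft preferences."""
    return PWM(
        id="TOY",
        counts=np.array(
            [[8, 2, 1, 1], [1, 7, 2, 2], [2, 1, 8, 1], [1, 2, 2, 7]], dtype=float
        ),
    )


SCALED_EXPR = dict(n_genes=1200, seed=11)
SCALED_PROM = dict(
    promoter_length=1500, conserved_block_lengths=(250, 150, 100), seed=12
)


@pytest.fixture(scope="session")
def scaled_bundle(tmp_path_factory, pwms):
    """A scaled synthetic study written to disk once per session."""
    out = tmp_path_factory.mktemp("bundle")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_study(
            SimExpressionConfig(**SCALED_EXPR),
            SimPromoterConfig(**SCALED_PROM),
            pwms,
            out,
        )


@pytest.fixture(scope="session")
def fitted_results(scaled_bundle):
    """The full chain fitted once on the scaled bundle."""
    from promotif.config import PipelineConfig
    from promotif.model import PromoterOverrepresentationModel

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = PromoterOverrepresentationModel.from_bundle(
            scaled_bundle, PipelineConfig()
        )
        return model.fit()
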