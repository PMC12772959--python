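"""Shared fixtures: one default synthetic tissue mapped end-to-end.

The heavy pipeline products (imputed expression, on/off models, mapping
matrix) are session-scoped so the many tests that need a realistic mapping
share one computation.
"""

import numpy as np
import pytest

import spatmap as sm


@pytest.fixture(scope="session")
def tissue():
    return sm.simulate_tissue(sm.TissueSpec(seed=1))


@pytest.fixture(scope="session")
def signature_grid(tissue):
    spec = tissue.spec
    return sm.aggregate_reads(
        tissue.reads,
        sm.GridSpec(spec.width_px, spec.height_px, spec.tile),
        list(spec.landmarks),
    )


@pytest.fixture(scope="session")
def imputed(tissue):
    return sm.impute(tissue.expr, n_neighbors=15, t=3)


@pytest.fixture(scope="session")
def models(imputed, tissue):
    return sm.fit_all_landmarks(imputed, list(tissue.spec.landmarks), seed=0)


@pytest.fixture(scope="session")
def mapping(imputed, signature_grid, models):
    from spatmap.mapping import mapping_from_tissue

    return mapping_from_tissue(imputed, signature_grid, models, lam=0.9)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
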