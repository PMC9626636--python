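import numpy as np
import pytest

from dfikit.core_model import LangevinParams
from dfikit.synthetic import (
    CohortConfig,
    DEFAULT_BASELINE,
    generate_cohort,
)


@pytest.fixture(scope="session")
def small_cohort():
    """Two-strain cohort with deaths disabled (g = 0), ~320 animals."""
    cfg = CohortConfig(
        n_per_strain_sex=80,
        strains=[("S1", DEFAULT_BASELINE.copy()), ("S2", DEFAULT_BASELINE * 1.05)],
        visit_ages=(26.0, 52.0, 78.0, 104.0),
        seed=42,
    )
    cohort, survival, latent = generate_cohort(cfg)
    return cfg, cohort, survival, latent


@pytest.fixture(scope="session")
def mortal_cohort():
    """Cohort with latent blow-up deaths and light censoring."""
    lang = LangevinParams(alpha=0.03, g=0.03 / (np.e**3 * 0.091), noise_power=5e-4,
                          z_init=0.0)
    cfg = CohortConfig(
        n_per_strain_sex=120,
        strains=[("S1", DEFAULT_BASELINE.copy())],
        langevin=lang,
        visit_ages=(26.0, 52.0, 78.0, 104.0),
        censor_rate=1e-3,
        horizon=220.0,
        seed=7,
    )
    cohort, survival, latent = generate_cohort(cfg)
    return cfg, cohort, survival, latent
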