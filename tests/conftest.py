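import pytest
from hypothesis import settings

import sigstrat as ss

settings.register_profile("det", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("det")


@pytest.fixture(scope="session")
def cohort():
    """Default-condition cohort: n=300, 5000 features, 100 planted per direction."""
    cfg = ss.CohortConfig(seed=11)
    expr, surv, truth = ss.gen_cohort(cfg)
    return cfg, expr, surv, truth


@pytest.fixture(scope="session")
def kd_experiment(cohort):
    _, _, _, truth = cohort
    cfg = ss.KDConfig(
        responders_down=tuple(truth.high_genes),
        responders_up=tuple(truth.low_genes),
        seed=11,
    )
    return cfg, ss.gen_kd(cfg)


@pytest.fixture(scope="session")
def signature(cohort, kd_experiment):
    """Functionally tuned signature derived from the session cohort."""
    _, expr, _, truth = cohort
    _, kd = kd_experiment
    module = ss.coexpr_module(expr, truth.anchor)
    diff = ss.kd_differential(kd)
    return ss.build_signature(module, diff)
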