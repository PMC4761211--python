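import numpy as np
import pandas as pd
import pytest

from consig.simulate import SimulationConfig, generate_expression, generate_survival


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_survival_dataset(rng, n=40, censor_frac=0.3, binary=False):
    """Small random dataset with continuous (untied) times for oracle comparisons."""
    if binary:
        x = (rng.random(n) > 0.5).astype(float)
        while x.std() == 0:
            x = (rng.random(n) > 0.5).astype(float)
    else:
        x = rng.standard_normal(n)
    t = rng.exponential(30.0 * np.exp(-0.4 * x))
    e = (rng.random(n) > censor_frac).astype(int)
    if e.sum() < 3:  # keep the partial likelihood non-trivial
        e[rng.choice(n, 3, replace=False)] = 1
    return x, t, e


@pytest.fixture
def toy_cohort():
    """One small simulated cohort with a single strong prognostic probe."""
    cfg = SimulationConfig(
        cohort_sizes=(120,), n_probes=30, prognostic_probe_count=1,
        log_hazard_effects=(np.log(2.0),), intra_signature_correlation=0.0, seed=7,
    )
    expr = generate_expression(cfg, 0)
    clin = generate_survival(expr, {cfg.prognostic_ids()[0]: np.log(2.0)}, cfg, 0)
    return cfg, expr, clin
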