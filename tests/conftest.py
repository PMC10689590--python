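import numpy as np
import pytest

import fdgki as f


@pytest.fixture(scope="session")
def aarhus():
    return f.aarhus_schedule()


@pytest.fixture(scope="session")
def bern():
    return f.bern_schedule()


@pytest.fixture(scope="session")
def p_default():
    """Aarhus-like tri-exponential input at the population means."""
    return f.TriExpParams(
        A=75.0, B=5.0, C=5.0, lambda1=3.5, lambda2=0.15, lambda3=0.0121, t_appear=0.24
    )


@pytest.fixture(scope="session")
def q_gm():
    return f.TwoTCParams(K1=0.10, k2=0.18, k3=0.097, region="GM")


@pytest.fixture(scope="session")
def noiseless_subject(aarhus, p_default, q_gm):
    """One noiseless virtual subject: (idif, gm tissue, input params, 2TC)."""
    idif = f.simulate_idif(p_default, aarhus, 0.0, 1)
    gm = f.simulate_tissue(p_default, q_gm, aarhus, 0.0, 1)
    return idif, gm, p_default, q_gm


@pytest.fixture(scope="session")
def small_cohort():
    """An 8-subject noisy Aarhus-style cohort for fast integration tests."""
    g = f.CohortGenParams.aarhus(n_subjects=8, seed=5, noise_cv=0.03)
    return f.generate_cohort(g)


def draw_separated_triexp(rng: np.random.Generator) -> f.TriExpParams:
    """Random input params with the phases well separated in absolute rate.

    The terminal-phase recovery guarantee requires the intermediate phase to
    have decayed away by the 35-min tail-window start, i.e. lambda2
    sufficiently above lambda3 in absolute terms (lambda2 >= lambda3 + 0.16
    covers B/C up to 1.5), alongside the usual >= 5x ratio separation.
    """
    lam3 = rng.uniform(0.006, 0.016)
    lam2 = rng.uniform(lam3 + 0.16, 0.32)
    lam1 = rng.uniform(max(2.0, 8 * lam2), 5.0)
    c = rng.uniform(2.0, 8.0)
    return f.TriExpParams(
        A=rng.uniform(20.0, 150.0),
        B=c * rng.uniform(0.4, 1.5),
        C=c,
        lambda1=lam1,
        lambda2=lam2,
        lambda3=lam3,
        t_appear=rng.uniform(0.1, 0.6),
    )
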