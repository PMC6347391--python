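import numpy as np
import pandas as pd
import pytest

from gait_evidence.synthetic import CohortSpec, EffectSpec, default_effect_spec, generate_cohort


def make_effect(channel, pc, mu_oa, sd_oa, mu_np, sd_np, mu_oa_post=None, sd_oa_post=None):
    return EffectSpec(
        feature_id=(channel, pc),
        mean_oa_pre=mu_oa,
        sd_oa_pre=sd_oa,
        mean_oa_post=mu_oa if mu_oa_post is None else mu_oa_post,
        sd_oa_post=sd_oa if sd_oa_post is None else sd_oa_post,
        mean_np=mu_np,
        sd_np=sd_np,
    )


@pytest.fixture(scope="session")
def default_cohort():
    """A default-parameter 30+30 cohort, shared across read-only tests."""
    return generate_cohort(CohortSpec(seed=11))


@pytest.fixture
def random_boe_triples():
    """1,000 random mass triples drawn uniformly on the simplex."""
    rng = np.random.default_rng(42)
    return rng.dirichlet(np.ones(3), size=1000)


@pytest.fixture
def tiny_scores():
    """Well-separated two-class scores for quick classifier checks."""
    rng = np.random.default_rng(3)
    oa = -5.0 + rng.normal(0, 1.0, size=(10, 4))
    np_ = 5.0 + rng.normal(0, 1.0, size=(10, 4))
    subjects = [f"OA{i}" for i in range(10)] + [f"NP{i}" for i in range(10)]
    scores = pd.DataFrame(
        np.vstack([oa, np_]), index=subjects, columns=[f"f{j}_PC1" for j in range(4)]
    )
    labels = pd.Series(["OA"] * 10 + ["NP"] * 10, index=subjects)
    return scores, labels
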