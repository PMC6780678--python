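import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from bdrscreen.lcms import ROLE_POOL, ROLE_STUDY, FeatureMatrix

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def make_feature_matrix(values, roles, snr=None, orders=None):
    """Build a FeatureMatrix from a plain array and per-injection roles.

    `values` is (n_features, n_injections); study injections get sample ids
    smp1, smp2, ... in order of appearance.
    """
    values = np.asarray(values, dtype=float)
    n_feat, n_inj = values.shape
    if orders is None:
        orders = np.arange(1, n_inj + 1)
    inj_ids = [f"inj{k}" for k in range(1, n_inj + 1)]
    sample_ids, s = [], 0
    for role in roles:
        if role == ROLE_STUDY:
            s += 1
            sample_ids.append(f"smp{s}")
        else:
            sample_ids.append(None)
    injections = pd.DataFrame(
        {"injection_order": orders, "role": list(roles), "sample_id": sample_ids},
        index=pd.Index(inj_ids, name="injection_id"),
    )
    feat_ids = [f"f{j}" for j in range(1, n_feat + 1)]
    vdf = pd.DataFrame(values, index=pd.Index(feat_ids, name="feature_id"), columns=inj_ids)
    snr_s = None if snr is None else pd.Series(np.asarray(snr, dtype=float), index=feat_ids)
    return FeatureMatrix(vdf, injections, snr_s)


@pytest.fixture
def feature_matrix_factory():
    return make_feature_matrix


@pytest.fixture
def small_cohort():
    """Six samples over three subjects with simple covariates."""
    rows = []
    rng = np.random.default_rng(5)
    for i, sid in enumerate(["A", "B", "C"]):
        for v, age in [("baseline", 8.0 + i), ("end", 12.0 + i)]:
            rows.append(
                dict(
                    subject_id=sid, visit=v, age_years=age,
                    sex="Male" if i % 2 == 0 else "Female",
                    race="White", clinic="c1", treatment="placebo",
                    pre_fev1_l=2.0, post_fev1_l="2.2",
                    bdr=0.1 + 0.01 * rng.standard_normal(),
                    sample_id=f"smp{2 * i + (v == 'end') + 1}",
                )
            )
    return pd.DataFrame(rows)
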