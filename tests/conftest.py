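import numpy as np
import pandas as pd
import pytest

import psymetab as pm


@pytest.fixture(scope="session")
def small_cohort_config():
    """Reduced cohort (10 pairs per stratum, 60 subjects) used wherever the
    full 139-pair design is not the point."""
    return pm.CohortConfig(
        group_sizes={"schizophrenia": 10, "onap": 10, "affective": 10}, seed=3)


@pytest.fixture(scope="session")
def small_study(small_cohort_config):
    return pm.generate_study(small_cohort_config)


@pytest.fixture(scope="session")
def default_study():
    """Full default design: 45/57/37 matched pairs, both platforms."""
    return pm.generate_study(pm.CohortConfig(seed=0))


@pytest.fixture(scope="session")
def default_truth_scores(default_study):
    allf = pd.concat([default_study.lipid_features,
                      default_study.polar_features], axis=1)
    return pm.cluster_scores(allf, default_study.truth["assignment"])


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def planted_recovery():
    """BIC model selection on 10 replicate planted designs (60 subjects,
    both platforms): selected K and ARI against the ground-truth partition.
    Shared between the recovery acceptance check and partition-quality
    properties."""
    from sklearn.metrics import adjusted_rand_score
    runs = []
    for seed in range(1, 11):
        cfg = pm.CohortConfig(group_sizes={"schizophrenia": 10, "onap": 10,
                                           "affective": 10}, seed=seed)
        study = pm.generate_study(cfg)
        rec = {}
        for platform in ("lipid", "polar"):
            feats = study.features(platform)
            out = pm.select_model(pm.standardize(feats), seed=7)
            truth = [study.truth["assignment"][f] for f in feats.columns]
            rec[platform] = (out.K,
                             adjusted_rand_score(truth, out.labels.to_numpy()))
        runs.append(rec)
    return runs
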