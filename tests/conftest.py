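import numpy as np
import pytest

import attnmil as am


@pytest.fixture(scope="session")
def demo_cohort():
    """Study cohort for end-to-end checks: 60 patients, d=16, 30% witnesses
    with a 2 sd feature shift."""
    return am.generate_cohort(am.demo_spec(seed=1))


@pytest.fixture(scope="session")
def demo_cv(demo_cohort):
    """One full 5-fold cross-validation run on the demo cohort."""
    cfg = am.TrainConfig(L=64, seed=1)
    report, outcomes = am.run_cross_validation(demo_cohort.bags, cfg, k=5, seed=1)
    return report, outcomes


@pytest.fixture(scope="session")
def sparse_cohort():
    """Hotspot-like cohort (5% witnesses, 3 sd shift) for localization."""
    return am.generate_cohort(am.sparse_witness_spec(seed=2))


@pytest.fixture(scope="session")
def sparse_model(sparse_cohort):
    """One model trained on fold 1 of the sparse-witness cohort."""
    ids = [b.patient_id for b in sparse_cohort.bags]
    labels = [b.label for b in sparse_cohort.bags]
    splits = am.stratified_kfold_split(ids, labels, k=5, seed=2)
    by_pid = {b.patient_id: b for b in sparse_cohort.bags}
    result = am.train_model(
        [by_pid[p] for p in splits[0].train_ids],
        [by_pid[p] for p in splits[0].val_ids],
        am.TrainConfig(L=64, seed=2),
    )
    return result.params


@pytest.fixture(scope="session")
def sparse_eval_cohort():
    """Held-out cohort from the sparse-witness distribution with perfectly
    co-localized biomarker masks, for localization and overlap checks."""
    return am.generate_cohort(am.sparse_witness_spec(seed=1002, mask_colocalization=1.0))


@pytest.fixture
def tiny_cohort():
    """Very small cohort for I/O and plumbing tests."""
    spec = am.SyntheticSpec(
        n_patients=12, prevalence=0.5, d=8, bag_size_range=(15, 25),
        grid_shape=(5, 5), signal_dims=8, seed=7,
    )
    return am.generate_cohort(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
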