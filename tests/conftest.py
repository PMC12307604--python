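import warnings

import numpy as np
import pytest

from methatlas.preprocess import combat_correct, impute_batch_mean, qc_cascade
from methatlas.synthetic import CohortSpec, generate_cohort, make_reference

warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_spec():
    # desk cohort scaled down for unit tests
    return CohortSpec(n_samples=240, n_cpgs=600, n_subtypes=4,
                      markers_per_subtype=60, n_candidates=120,
                      n_prognostic=8, missing_rate=0.01, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_cohort(small_spec)


@pytest.fixture(scope="session")
def small_reference(small_spec):
    return make_reference(small_spec)


@pytest.fixture(scope="session")
def small_corrected(small_cohort):
    """QC'd, imputed, batch-corrected matrix plus aligned sample table."""
    matrix, samples, truth = small_cohort
    qc, _ = qc_cascade(matrix, samples,
                       pca_outlier_kwargs={"n_components": 2, "k_sd": 4.0})
    samples = samples.loc[qc.sample_ids]
    corrected = combat_correct(impute_batch_mean(qc, samples["batch"]), samples["batch"])
    return corrected, samples, truth


@pytest.fixture(scope="session")
def small_bundle(small_corrected, small_reference):
    """Embedding + subtype + risk models trained on the small cohort."""
    from methatlas.classify import MortalityRiskClassifier, SubtypeClassifier
    from methatlas.datamodel import ModelBundle
    from methatlas.embedding import ManifoldEmbedding

    corrected, samples, truth = small_corrected
    reference = small_reference.subset(corrected.probe_ids)
    embed5 = ManifoldEmbedding(n_dims=5, seed=11).fit(corrected)
    tiny = {"n_estimators": [100], "num_leaves": [15],
            "reg_alpha": [0.0], "reg_lambda": [0.0]}
    subtype = SubtypeClassifier(seed=11, param_grid=tiny).fit(
        embed5.embedding_, samples["who2022_label"])
    risk = MortalityRiskClassifier(seed=11, param_grid=tiny).fit(
        embed5.embedding_, samples["os_time"], samples["os_event"])
    # first two synthetic subtypes play the myeloid role for gating tests
    myeloid = frozenset(list(truth.marker_probes)[:2])
    return ModelBundle(
        reference=reference,
        discovery_means=corrected.frame.mean(axis=0),
        embedding5d=embed5,
        subtype_model=subtype,
        risk_model=risk,
        myeloid_labels=myeloid,
    )


@pytest.fixture()
def rng():
    # fresh, fixed-seed generator per test so results are order-independent
    return np.random.default_rng(0)
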