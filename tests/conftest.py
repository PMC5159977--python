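import numpy as np
import pytest

from phenoclust import cohort, fuzzy_pam, preprocess

TRUTH_CODES = {"A1": 0, "A2": 1, "A3": 2, "A4": 3}


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (seed 0), all visits."""
    return cohort.generate_cohort(cohort.default_cohort_spec(seed=0))


@pytest.fixture(scope="session")
def baseline(default_cohort):
    return default_cohort[default_cohort["visit"] == "baseline"].reset_index(drop=True)


@pytest.fixture(scope="session")
def scaled_features(baseline):
    return preprocess.mad_scale(preprocess.transform_variables(baseline))


@pytest.fixture(scope="session")
def distances(scaled_features):
    return fuzzy_pam.pairwise_distance(scaled_features)


@pytest.fixture(scope="session")
def partition_k4(distances, scaled_features):
    return fuzzy_pam.fit_fuzzy_pam(distances, 4, m=1.1, restarts=50, seed=0,
                                   subject_ids=scaled_features.subject_ids)


@pytest.fixture(scope="session")
def cluster_labels(partition_k4):
    return np.array([f"C{v + 1}" for v in partition_k4.hard_labels])


@pytest.fixture(scope="session")
def model_a(scaled_features, cluster_labels):
    """Model A trained with a compact grid and 5-fold CV (test-sized)."""
    from phenoclust import classify

    return classify.train_classifier(
        scaled_features, cluster_labels, variant="A",
        alpha_grid=(0.0, 0.5, 1.0), lambda_grid=(1e-3, 1e-2, 1e-1),
        cv=5, seed=0,
    )


@pytest.fixture(scope="session")
def model_b(scaled_features, cluster_labels):
    from phenoclust import classify

    return classify.train_classifier(
        scaled_features, cluster_labels, variant="B",
        alpha_grid=(0.0, 0.5, 1.0), lambda_grid=(1e-3, 1e-2, 1e-1),
        cv=5, seed=0,
    )
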