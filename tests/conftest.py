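import logging

import pytest
from hypothesis import HealthCheck, settings

from defer_dx.reference_labels import loo_label_sets
from defer_dx.synthetic_cohort import (
    CohortConfig,
    default_ai_model,
    default_reader_models,
    generate_ai_scores,
    generate_cohort,
    generate_ratings,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

logging.getLogger("defer_dx").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_study():
    """A 20-patient study with 6 readers — fast, panels survive LOO exclusion."""
    config = CohortConfig(n_patients=20, seed=7)
    cohort = generate_cohort(config)
    readers = default_reader_models(6)
    ratings = generate_ratings(cohort, readers, (4, 6), seed=7)
    scores = generate_ai_scores(cohort, default_ai_model(), seed=7)
    return {"cohort": cohort, "ratings": ratings, "scores": scores}


@pytest.fixture(scope="session")
def study_cohort():
    """A study-scale cohort: 115 patients, 9 readers, panels of 6-9."""
    config = CohortConfig(seed=11)
    cohort = generate_cohort(config)
    ratings = generate_ratings(cohort, default_reader_models(), (6, 9), seed=11)
    scores = generate_ai_scores(cohort, default_ai_model(), seed=11)
    return {"cohort": cohort, "ratings": ratings, "scores": scores}


@pytest.fixture(scope="session")
def study_loo(study_cohort):
    return loo_label_sets(study_cohort["ratings"])
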