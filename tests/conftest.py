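import numpy as np
import pytest

from methpanel import default_panel, default_params, generate_cohort, profile_table


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def cohort(panel):
    """Study-sized synthetic cohort at a fixed seed, shared read-only."""
    return generate_cohort(default_params(panel, seed=7), panel)


@pytest.fixture(scope="session")
def profiles(cohort, panel):
    return profile_table(cohort.assay_levels, panel)


@pytest.fixture(scope="session")
def labels(cohort):
    return cohort.labels


def random_cohort_scores(rng, n_cases, n_controls, max_count=19):
    """Integer count scores + labels for property tests."""
    scores = np.concatenate(
        [rng.integers(0, max_count + 1, n_cases), rng.integers(0, max_count + 1, n_controls)]
    )
    y = np.concatenate([np.ones(n_cases, bool), np.zeros(n_controls, bool)])
    return scores, y


def brute_force_auc(scores, y):
    """Exhaustive pair-counting oracle for the tie-corrected AUC."""
    scores = np.asarray(scores, float)
    y = np.asarray(y, bool)
    cases = scores[y]
    controls = scores[~y]
    wins = ties = 0
    for c in cases:
        for k in controls:
            if c > k:
                wins += 1
            elif c == k:
                ties += 1
    return (wins + 0.5 * ties) / (len(cases) * len(controls))
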