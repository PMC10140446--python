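import numpy as np
import pytest

from cognorm import CohortConfig, crossval_normative, fit_ica, generate_cohort
from cognorm.clinical import component_table


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size cohort (n=6481) with default missingness rates."""
    return generate_cohort(CohortConfig(seed=11, n_snps=50))


@pytest.fixture(scope="session")
def complete_cohort():
    """Full-size cohort without any missingness (for PCA/ICA recovery tests)."""
    cfg = CohortConfig(seed=11, cognitive_missing_rate=0.0, item_missing_rate=0.0, n_snps=0)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def ica_recovery(complete_cohort):
    """Fitted 7-component ICA on the complete cohort plus IC-vs-truth correlations."""
    model = fit_ica(complete_cohort.clinical_items, k=7, n_restarts=20, seed=3)
    comps = component_table(model, complete_cohort.clinical_items["subject_id"])
    truth = complete_cohort.truth
    k = 7
    corr = np.empty((k, k))
    for i in range(k):
        for j in range(k):
            corr[i, j] = np.corrcoef(comps.scores[f"IC{i + 1}"], truth[f"factor_{j + 1}"])[0, 1]
    return {"model": model, "components": comps, "corr": corr}


@pytest.fixture(scope="session")
def gp_calibration():
    """10-fold GP crossval on a well-specified n=2000 cohort (shared: it is slow)."""
    rng = np.random.default_rng(42)
    n = 2000
    age = rng.uniform(8, 21, n)
    sex = (rng.random(n) < 0.5).astype(float)
    y = -4.0 + 1.5 * np.log(age) + 0.2 * sex + 0.5 * rng.standard_normal(n)
    X = np.column_stack([age, sex])
    deviations, metrics = crossval_normative(X, y, k=10, seed=7)
    return {"X": X, "y": y, "deviations": deviations, "metrics": metrics}
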