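import numpy as np
import pandas as pd
import pytest

from pbsig import (
    ExpressionMatrix,
    PlantConfig,
    StudyDesign,
    fit_metagene_model,
    generate_study,
)
from pbsig.signature import labels_from_groups


def make_matrix(values, probe_ids=None, sample_ids=None, groups=None, timepoints=None):
    """Small ExpressionMatrix builder for hand-written toys."""
    values = np.asarray(values, dtype=float)
    n_probes, n_samples = values.shape
    probe_ids = probe_ids or [f"p{i}" for i in range(n_probes)]
    sample_ids = sample_ids or [f"s{j}" for j in range(n_samples)]
    ann = None
    if groups is not None:
        ann = pd.DataFrame(
            {
                "group": groups,
                "timepoint": timepoints or ["exposure"] * n_samples,
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    return ExpressionMatrix(pd.DataFrame(values, index=probe_ids, columns=sample_ids), ann)


@pytest.fixture(scope="session")
def default_study():
    """The default synthetic study (seed 42): matrix + ground-truth table."""
    return generate_study(StudyDesign(), PlantConfig())


@pytest.fixture(scope="session")
def exposure_cohorts(default_study):
    """Per-dose exposure-timepoint cohorts with 0/1 labels."""
    matrix, _ = default_study
    exposure = matrix.select_samples(timepoint="exposure")
    out = {}
    for dose in ("low", "high"):
        cohort = exposure.select_samples(group=["control", dose])
        out[dose] = (cohort, labels_from_groups(cohort, dose))
    return out


@pytest.fixture(scope="session")
def high_model(exposure_cohorts):
    cohort, y = exposure_cohorts["high"]
    return fit_metagene_model(cohort, y, k=250, m=2, mode="map", seed=42)
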