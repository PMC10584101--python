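import logging

import numpy as np
import pandas as pd
import pytest

import rnfldecay as rd

logging.disable(logging.WARNING)


@pytest.fixture(scope="session")
def small_cohort():
    """A small seeded cohort spanning all strata: profiles + truth."""
    profiles, truth = rd.generate_cohort(150, 40, seed=42)
    return profiles, truth


@pytest.fixture(scope="session")
def fitted_reference(small_cohort):
    """Normative reference fitted on the cohort's normal eyes."""
    profiles, _ = small_cohort
    normals = [p for p in profiles if p.status == "normal" and not p.excluded]
    return rd.NormativeReference().fit(normals), normals


@pytest.fixture(scope="session")
def cohort_decay(small_cohort, fitted_reference):
    """Decay matrix for every non-excluded eye, plus status labels."""
    profiles, _ = small_cohort
    ref, _ = fitted_reference
    eyes = [p for p in profiles if not p.excluded]
    decay = ref.transform(eyes)
    status = pd.Series({p.eye_id: p.status for p in eyes}).loc[decay.index]
    return decay, status


@pytest.fixture
def rng():
    return np.random.default_rng(20231018)
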