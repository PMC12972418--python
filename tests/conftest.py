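import numpy as np
import pytest

from gaitmod import CohortSpec, TextNoise, generate_cohort
from gaitmod.annotation import Lexicon, default_condition_lexicon, default_drug_lexicon


@pytest.fixture(scope="session")
def drug_lexicon():
    return default_drug_lexicon()


@pytest.fixture(scope="session")
def condition_lexicon():
    return default_condition_lexicon()


@pytest.fixture(scope="session")
def mini_drug_lexicon():
    """A tiny hand-built drug lexicon for deterministic matcher tests."""
    return Lexicon.from_pairs(
        [
            ("aspirin", "aspirin", "drug-generic"),
            ("ass", "aspirin", "drug-generic"),
            ("atorvastatin", "statin", "drug-generic"),
            ("simvastatin", "statin", "drug-generic"),
            ("bisoprolol", "beta_blocker", "drug-generic"),
            ("metformin", "biguanide", "drug-generic"),
            ("lipitor", "statin", "drug-brand"),
        ]
    )


@pytest.fixture(scope="session")
def analysis_cohort():
    """Mid-size flag-only cohort shared by analysis-stage tests."""
    return generate_cohort(CohortSpec(n=2000, seed=42), text=False)


@pytest.fixture(scope="session")
def clean_text_cohort():
    """Small cohort with noise-free text renderings."""
    return generate_cohort(CohortSpec(n=120, seed=9, text_noise=TextNoise.none()))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
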