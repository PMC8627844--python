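import pandas as pd
import pytest
from hypothesis import settings

import cttolite as ct

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def published_truth() -> ct.GroundTruth:
    """Ground truth seeded from the published analytic-sample decrements."""
    return ct.GroundTruth(decrements=ct.published_decrements("analytic"))


@pytest.fixture(scope="session")
def lite_design() -> ct.ValuationDesign:
    return ct.build_lite_design(ct.generate_synthetic_standard_design(1))


@pytest.fixture(scope="session")
def study_cohort(lite_design, published_truth) -> pd.DataFrame:
    """A study-scale cohort under default (study) conditions, no injection."""
    return ct.simulate_cohort(
        lite_design,
        n_respondents=500,
        truth=published_truth,
        noise=ct.NoiseModel(),
        inconsistency_rate=0.0,
        n_interviewers=6,
        seed=2024,
    )


@pytest.fixture(scope="session")
def quiet_noise() -> ct.NoiseModel:
    """Noise small relative to the 0.5 inconsistency threshold."""
    return ct.NoiseModel(sigma_base=0.04, sigma_slope=0.02, tau=0.01)


def exact_responses(
    design: ct.ValuationDesign,
    truth: ct.GroundTruth,
    respondents_per_block: int = 2,
    shift: float = 0.0,
) -> pd.DataFrame:
    """Noise-free, un-snapped responses equal to the truth values.

    Bypasses grid snapping so closed-form fits recover the truth exactly.
    """
    rows = []
    rid = 0
    for block_id in range(1, 11):
        for _ in range(respondents_per_block):
            rid += 1
            for state in design.block(block_id):
                rows.append(
                    {
                        "respondent_id": rid,
                        "interviewer_id": 1 + rid % 3,
                        "block_id": block_id,
                        "state": str(state),
                        "ctto": truth.value(state) + shift,
                        "wheelchair_seconds": 300.0,
                        "task_seconds": 90.0,
                    }
                )
    return pd.DataFrame(rows)
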