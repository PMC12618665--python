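"""Shared fixtures: a tiny hand-built study and a default simulated one."""

import pytest

from xai_reliance.data_model import (
    EstimateRecord,
    GABin,
    ModelPrediction,
    LikertResponse,
    StudyTable,
    default_bin_scheme,
)
from xai_reliance.synthetic_data import default_config, simulate_study


def make_estimate(**kwargs) -> EstimateRecord:
    """A valid estimate record with overridable fields."""
    base = dict(
        participant_id="p00",
        image_id="img000",
        stage=1,
        true_ga_weeks=25.0,
        estimate_weeks=24.0,
        confidence=3,
        time_sec=12.0,
        features=frozenset(),
    )
    base.update(kwargs)
    return EstimateRecord(**base)


@pytest.fixture()
def scheme():
    return default_bin_scheme()


@pytest.fixture()
def tiny_table(scheme) -> StudyTable:
    """Two participants, two images, three stages, hand-built values.

    Model points: img000 -> bin [24,26) midpoint 25; img001 -> [30,32)
    midpoint 31. Truths 25 and 29.
    """
    predictions = [
        ModelPrediction("img000", scheme.bin_for(25.0), 25.0),
        ModelPrediction("img001", scheme.bin_for(31.0), 31.0),
    ]
    estimates = []
    # participant p00 moves halfway to the model at stage 2, all the way at 3
    est = {
        ("p00", "img000"): {1: 21.0, 2: 23.0, 3: 25.0},
        ("p00", "img001"): {1: 27.0, 2: 29.0, 3: 31.0},
        # p01 never changes their estimate
        ("p01", "img000"): {1: 27.0, 2: 27.0, 3: 27.0},
        ("p01", "img001"): {1: 33.0, 2: 33.0, 3: 33.0},
    }
    truths = {"img000": 25.0, "img001": 29.0}
    for (pid, img), stages in est.items():
        for stage, value in stages.items():
            estimates.append(
                make_estimate(
                    participant_id=pid,
                    image_id=img,
                    stage=stage,
                    true_ga_weeks=truths[img],
                    estimate_weeks=value,
                    confidence=2 + stage,
                    time_sec=10.0 * stage,
                    features=frozenset({"cerebellum", "orbits"}) if stage == 1 else frozenset(),
                )
            )
    likert = [
        LikertResponse("p00", "pre_study", "comfort_practice", 4),
        LikertResponse("p00", "post_stage2", "trust", 4),
        LikertResponse("p00", "post_stage3", "trust", 3),
        LikertResponse("p00", "post_stage3", "explanations_helpful", 5),
        LikertResponse("p00", "post_study", "comfort_practice", 3),
        LikertResponse("p01", "pre_study", "comfort_practice", 5),
        LikertResponse("p01", "post_stage2", "trust", 3),
        LikertResponse("p01", "post_stage3", "trust", 3),
        LikertResponse("p01", "post_stage3", "explanations_helpful", 2),
        LikertResponse("p01", "post_study", "comfort_practice", 4),
    ]
    return StudyTable(estimates, predictions, likert, scheme)


@pytest.fixture(scope="session")
def sim_result():
    return simulate_study(default_config(), seed=123)


@pytest.fixture(scope="session")
def sim_table(sim_result):
    return sim_result.table
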