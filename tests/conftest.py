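import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from coordsam.criteria import (
    assemble_long_data,
    build_accuracy_criterion,
    prepare_observability,
)
from coordsam.simulate import StudyGenConfig, simulate_personality_study


def make_frame(config: StudyGenConfig):
    """Generate a study and assemble its model frame; returns (frame, truth)."""
    study = simulate_personality_study(config)
    criteria = build_accuracy_criterion(study["self_reports"], study["other_reports"])
    obs = prepare_observability(study["observability"])
    frame = assemble_long_data(
        study["perceptions"], criteria, obs, moderators=study["moderators"]
    )
    return frame, study


@pytest.fixture(scope="session")
def small_study():
    """A modest crossed study reused across model tests (40 targets)."""
    cfg = StudyGenConfig(
        seed=202, n_targets=40, n_perceivers=24, n_subsets=3, n_items=12
    )
    return make_frame(cfg)


@pytest.fixture(scope="session")
def small_fit(small_study):
    from coordsam.sam import SAMSpec, fit_sam

    frame, _ = small_study
    return fit_sam(frame, SAMSpec(moderators=("ibc_variability",)))
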