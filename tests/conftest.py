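import numpy as np
import pytest

from semstory import ExperimentDesign, PlantedEffects, make_bold_experiment


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_design():
    return ExperimentDesign(n_subjects=4, n_conditions=3, trials_per_condition=2,
                            ideation_volumes=20, n_rois=8, seed=7)


@pytest.fixture
def null_dataset(small_design):
    """Pure-noise dataset (no planted effects), ideation window only."""
    return make_bold_experiment(small_design, PlantedEffects(), ideation_only=True)
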