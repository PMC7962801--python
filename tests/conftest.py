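import numpy as np
import pytest

from styletax import (
    GazeBehaviorModel,
    ImageRect,
    SearchBehaviorModel,
    StyleSet,
    default_planted_taxonomy,
    make_gaze_design,
    make_search_design,
    simulate_fixations,
    simulate_search_trials,
)


@pytest.fixture(scope="session")
def styles8() -> StyleSet:
    return StyleSet()


@pytest.fixture(scope="session")
def planted():
    return default_planted_taxonomy()


@pytest.fixture(scope="session")
def small_trials(planted):
    """One simulated subject, 4 blocks of all 56 ordered pairs."""
    design = make_search_design(planted.styles, blocks=4, motif_pool=224, seed=42)
    model = SearchBehaviorModel(seed=42)
    return simulate_search_trials(design, planted, model)


@pytest.fixture(scope="session")
def small_gaze(planted):
    """A small free-viewing dataset: 16 subjects, 5 motifs per style."""
    model = GazeBehaviorModel(seed=11)
    design = make_gaze_design(planted.styles, motifs_per_style=5, seed=11, n_subjects=16)
    fixations = simulate_fixations(design, planted, model)
    rect = ImageRect.centered(model.screen_size, model.image_size)
    return fixations, rect, model
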