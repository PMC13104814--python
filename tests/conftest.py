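import numpy as np
import pytest

from oxyallo import synthdata
from oxyallo.paradigm import Epoch, Paradigm


@pytest.fixture(scope="session")
def short_schedule() -> Paradigm:
    """A compressed 8-minute normoxia -> hypoxia paradigm for fast tests."""
    return Paradigm(
        epochs=(
            Epoch("normoxia", 0.0, 240.0, 8.0),
            Epoch("hypoxia", 240.0, 480.0, 4.0),
        ),
        mixing_tau=30.0,
    )


@pytest.fixture(scope="session")
def small_truth() -> synthdata.GroundTruth:
    archetypes = tuple(
        synthdata.Archetype(**{**a.__dict__, "n_cells": 6})
        for a in synthdata.default_archetypes()
    )
    return synthdata.GroundTruth(generator="circuit", seed=11,
                                 archetypes=archetypes)


@pytest.fixture(scope="session")
def small_exp(small_truth, short_schedule) -> synthdata.SyntheticExperiment:
    """One seeded synthetic experiment shared across the suite."""
    return synthdata.make_experiment(small_truth, short_schedule)
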