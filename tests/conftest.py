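import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from melodna import (
    DURATIONS,
    MusicalElement,
    MusicScore,
    build_default_code_table,
    ode_to_joy_fixture,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table():
    return build_default_code_table()


@pytest.fixture(scope="session")
def ancestor():
    return ode_to_joy_fixture()


def random_score(rng: np.random.Generator, n_elements: int, table) -> MusicScore:
    """A uniformly random in-code score of n elements."""
    elements = tuple(
        MusicalElement(
            int(rng.choice(table.notes)),
            DURATIONS[rng.integers(len(DURATIONS))],
        )
        for _ in range(n_elements)
    )
    return MusicScore(elements)
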