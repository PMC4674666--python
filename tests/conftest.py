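from __future__ import annotations

import numpy as np
import pytest

from clutchkit.geometry import ClutchObservation, EggAnnotation
from clutchkit.synthetic import GeneratorConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20140907)


@pytest.fixture
def gen_config():
    return GeneratorConfig()


def make_obs(eggs, nest_id="n1", phase="before", center=(0.0, 0.0), y_down=False, **kw):
    """Build an observation from (egg_id, blunt, sharp[, is_model]) tuples."""
    annos = [EggAnnotation(e[0], e[1], e[2], bool(e[3]) if len(e) > 3 else False) for e in eggs]
    return ClutchObservation(
        nest_id=nest_id, phase=phase, nest_center=center, eggs=annos, y_down=y_down, **kw
    )


def random_clutch(rng, n=None, nest_id="r1", phase="before", y_down=False, spread=100.0):
    """A random (not collision-checked) annotated clutch for metric oracles."""
    n = n or int(rng.integers(3, 7))
    eggs = []
    for i in range(n):
        blunt = tuple(rng.uniform(-spread, spread, 2))
        while True:
            sharp = tuple(blunt + rng.uniform(-40, 40, 2))
            if sharp != blunt:
                break
        eggs.append((f"e{i}", blunt, sharp))
    center = tuple(rng.uniform(-10, 10, 2))
    return make_obs(eggs, nest_id=nest_id, phase=phase, center=center, y_down=y_down)
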