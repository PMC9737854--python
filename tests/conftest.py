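import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from plusqol.fuzzy import PiecewiseLinearFunction, TrapezoidSet
from plusqol.model import build_default_model


@pytest.fixture(scope="session")
def model():
    """One shared default PLUS hierarchy (memoization persists per session)."""
    return build_default_model()


def random_envelope(rng: np.random.Generator) -> PiecewiseLinearFunction:
    """A random accumulated-consequent curve on [-0.5, 1.5].

    Max envelope of 1-4 randomly placed clipped trapezoids, mimicking what
    rule accumulation produces.
    """
    lo, hi = -0.5, 1.5
    n = rng.integers(1, 5)
    curves = []
    for _ in range(n):
        pts = np.sort(rng.uniform(lo, hi, size=4))
        height = rng.uniform(0.05, 1.0)
        trap = TrapezoidSet("s", *pts)
        curves.append(trap.clipped(height, lo, hi))
    return PiecewiseLinearFunction.max_envelope(curves)
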