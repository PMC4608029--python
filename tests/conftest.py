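"""Shared fixtures: phantom curves and volumes reused across the suite.

Rasterizing tube volumes is the expensive step, so clean phantoms are
session-scoped; tests must not mutate them in place.
"""

from __future__ import annotations

import numpy as np
import pytest

from minicircle.synthetic import (PopulationSpec, ShapeSpec, make_curve,
                                  rasterize)

#: Canonical 336 bp contour length used throughout (3.4 A/bp rise).
L336 = 336 * 3.4


@pytest.fixture(scope="session")
def trace_pop():
    """Population spec with a tracing-sized margin (no Rg masking)."""
    return PopulationSpec(counts={}, margin=40.0)


@pytest.fixture(scope="session")
def circle_curve():
    return make_curve(ShapeSpec("open_circle"), seed=5)


@pytest.fixture(scope="session")
def circle_volume(circle_curve, trace_pop):
    return rasterize(circle_curve, trace_pop)


@pytest.fixture(scope="session")
def figure8_curve():
    return make_curve(ShapeSpec("figure8"), seed=1)


@pytest.fixture(scope="session")
def rod_curve():
    return make_curve(ShapeSpec("rod"), seed=5)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
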