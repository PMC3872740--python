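import numpy as np
import pytest

import levelkit as lk


@pytest.fixture
def circle_sdf():
    """Signed distance to a circle sampled on a grid (inside-negative)."""

    def make(shape=(41, 41), center=None, radius=10.0):
        if center is None:
            center = tuple((s - 1) / 2.0 for s in shape)
        grids = np.ogrid[tuple(slice(0, s) for s in shape)]
        r = np.sqrt(sum((g - c) ** 2 for g, c in zip(grids, center)))
        return lk.DenseLevelSet(lk.GridRegion((0,) * len(shape), shape), r - radius)

    return make


@pytest.fixture
def single_system():
    """Assemble a one-level-set system from (image, level set, terms)."""

    def make(image, ls, terms):
        container = lk.LevelSetContainer()
        container.add_level_set(1, ls)
        tc = lk.TermContainer(1)
        for term in terms:
            tc.add_term(term)
        equations = lk.EquationContainer()
        equations.add_equation(1, tc)
        return lk.LevelSetSystem(np.asarray(image, dtype=float), container, equations)

    return make


class RecordingTerm(lk.Term):
    """Stub term returning a constant and recording visited pixels."""

    def __init__(self, value=1.0, weight=1.0, requires=frozenset()):
        super().__init__(weight)
        self.value = value
        self.visited = []
        self.requires = requires

    def evaluate(self, idx, cache):
        self.visited.append(tuple(idx))
        for name in self.requires:
            cache.get(name)
        return self.value


@pytest.fixture
def recording_term():
    return RecordingTerm
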