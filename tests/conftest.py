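import io
import math

import numpy as np
import pytest

from neuroprint.mesh import TriangleMesh
from neuroprint.morphology import (BASAL, SOMA, MorphPoint, Morphology,
                                   Section, read_swc)
from neuroprint.surface import MeshResolution, tessellate

TOY_SWC = """# toy cell: spherical soma + one 2-point dendrite
1 1 0 0 0 5 -1
2 3 10 0 0 1 1
3 3 20 0 0 1 2
"""

BRANCHED_SWC = """# soma + dendrite that bifurcates + an axon
1 1 0 0 0 5 -1
2 3 10 0 0 1 1
3 3 20 0 0 1 2
4 3 30 5 0 0.75 3
5 3 40 8 0 0.75 4
6 3 30 -5 0 0.75 3
7 2 -10 0 0 0.5 1
8 2 -20 0 0 0.5 7
"""


def make_morph(sections_spec):
    """Build a morphology from [(id, kind, [(x,y,z,d)...], parent, pidx)]."""
    secs = []
    for sid, kind, pts, parent, pidx in sections_spec:
        secs.append(
            Section(
                id=sid,
                kind=kind,
                points=[MorphPoint(*p) for p in pts],
                parent_id=parent,
                parent_point_index=pidx,
                name=f"{kind}[{sid}]",
            )
        )
    return Morphology(sections=secs)


@pytest.fixture
def toy_cell():
    return read_swc(io.StringIO(TOY_SWC))


@pytest.fixture
def branched_cell():
    return read_swc(io.StringIO(BRANCHED_SWC))


@pytest.fixture
def cylinder_morph():
    """A single cylinder: length 10, radius 1 (volume 10*pi)."""
    return make_morph([(1, BASAL, [(0, 0, 0, 2), (10, 0, 0, 2)], None, None)])


@pytest.fixture
def sphere_morph():
    """A lone spherical soma of radius 5."""
    return make_morph([(1, SOMA, [(0, 0, 0, 10)], None, None)])


@pytest.fixture(scope="session")
def cylinder_mesh_default():
    m = make_morph([(1, BASAL, [(0, 0, 0, 2), (10, 0, 0, 2)], None, None)])
    return tessellate(m)


@pytest.fixture(scope="session")
def sphere_mesh_default():
    m = make_morph([(1, SOMA, [(0, 0, 0, 10)], None, None)])
    return tessellate(m)


@pytest.fixture
def unit_cube():
    verts = np.array(
        [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
         [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1]], dtype=float
    )
    faces = np.array(
        [[0, 2, 1], [0, 3, 2], [4, 5, 6], [4, 6, 7],
         [0, 1, 5], [0, 5, 4], [1, 2, 6], [1, 6, 5],
         [2, 3, 7], [2, 7, 6], [3, 0, 4], [3, 4, 7]]
    )
    return TriangleMesh(vertices=verts, faces=faces)


CYLINDER_VOLUME = 10 * math.pi
SPHERE_VOLUME = 4.0 / 3.0 * math.pi * 125.0
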