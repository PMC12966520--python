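import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from calciscore.phantom import (
    BranchSpec,
    LesionSpec,
    PhantomConfig,
    make_phantom,
)


@pytest.fixture(scope="session")
def small_tree_cfg():
    """Compact six-branch tree on a 96^3-ish grid; branches 40 mm."""
    return PhantomConfig(
        grid_shape=(112, 112, 72),
        branch_specs=(
            BranchSpec(2, 10, "+x", 40.0),
            BranchSpec(2, 10, "-x", 40.0),
            BranchSpec(3, 40, "+y", 40.0),
            BranchSpec(3, 32, "-y", 40.0),
            BranchSpec(4, 50, "+x", 40.0),
            BranchSpec(4, 46, "-x", 40.0),
        ),
        aorta_z_range=(0, 68),
    )


@pytest.fixture(scope="session")
def small_tree(small_tree_cfg):
    return make_phantom(small_tree_cfg)


@pytest.fixture(scope="session")
def lesion_tree():
    """One-branch tree with two separated aorta lesions and a branch lesion."""
    cfg = PhantomConfig(
        grid_shape=(80, 80, 64),
        aorta_radius_mm=7.0,
        branch_specs=(BranchSpec(4, 40, "+x", 20.0),),
        lesions=(
            LesionSpec((39.5, 39.5, 10.0), 2.5, 1),
            LesionSpec((39.5, 39.5, 24.0), 3.0, 1),
            LesionSpec((58.0, 39.5, 40.0), 2.0, 4),
        ),
        aorta_z_range=(0, 52),
    )
    return make_phantom(cfg)


def straight_tube(shape, start, axis, length, radius=0):
    """Axis-aligned tube mask; radius 0 gives a 1-voxel-thick line."""
    m = np.zeros(shape, dtype=bool)
    x0, y0, z0 = start
    for i in range(length):
        p = [x0, y0, z0]
        p[axis] += i
        if radius == 0:
            m[tuple(p)] = True
        else:
            sl = [slice(max(0, c - radius), c + radius + 1) for c in p]
            m[tuple(sl)] = True
    return m
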