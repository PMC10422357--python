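import numpy as np
import pytest

FS = 120.0


@pytest.fixture(scope="session")
def fs():
    return FS


@pytest.fixture(scope="session")
def t_2s():
    """Two seconds of 120 Hz sample times."""
    return np.arange(int(2 * FS)) / FS


MINIMAL_BVH = """\
HIERARCHY
ROOT root
{
  OFFSET 0.0 0.0 0.0
  CHANNELS 3 Zrotation Xrotation Yrotation
  End Site
  {
    OFFSET 0.0 1.0 0.0
  }
}
MOTION
Frames: 2
Frame Time: 0.0083333
10 20 30
11 21 31
"""


@pytest.fixture
def minimal_bvh_text():
    return MINIMAL_BVH


@pytest.fixture(scope="session")
def swing_clip():
    """One rendered synthetic swing (straight, fixed seed), with ground truth."""
    from swinghht.synthetic import default_recipe, render

    return render(default_recipe(seed=7))
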