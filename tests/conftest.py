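"""Shared fixtures: layouts, plans and small synthetic scenes.

Image-bearing fixtures use reduced FOVs (256-512 px at the native
0.32356 um/px pixel size) so the suite stays fast; the acceptance tests
run the full 2048 px default tiles.
"""

import numpy as np
import pytest

from fractalmea.geometry import (
    GridSpec,
    HTreeSpec,
    PAPER_GRID,
    PAPER_HTREE,
    build_grid,
    build_htree,
)
from fractalmea.masks import plan_fovs
from fractalmea.synth import CultureParams, build_scene

#: native pixel size of the imaging setup (662.65 um / 2048 px)
PX = 662.65 / 2048


@pytest.fixture(scope="session")
def paper_htree_layout():
    return build_htree(PAPER_HTREE)


@pytest.fixture(scope="session")
def paper_grid_layout():
    return build_grid(PAPER_GRID)


@pytest.fixture(scope="session")
def small_grid_layout():
    # 5x5 chambers of ~108 um: both surfaces well represented
    return build_grid(GridSpec(W=660.0, n=5, W_CNT=20.0))


@pytest.fixture(scope="session")
def small_htree_layout():
    return build_htree(HTreeSpec(D=2.0, m=2, W_CNT=20.0, W=600.0))


@pytest.fixture(scope="session")
def small_plan(small_grid_layout):
    # 512 px tiles at the native pixel size
    return plan_fovs(small_grid_layout, fov_size_um=512 * PX, fov_size_px=512)


@pytest.fixture(scope="session")
def quiet_params():
    """Culture with nothing planted (background-only images)."""
    return CultureParams(
        seed=11,
        neuron_density_si=0.0,
        neuron_density_cnt=0.0,
        glia_coverage_si=0.0,
        glia_coverage_cnt=0.0,
    )


@pytest.fixture(scope="session")
def small_scene(small_grid_layout, small_plan):
    """A lively small scene used by several measurement tests."""
    params = CultureParams(
        seed=21,
        neuron_density_si=60.0,
        neuron_density_cnt=150.0,
        mean_process_length=100.0,
        glia_coverage_si=0.25,
        glia_coverage_cnt=0.08,
    )
    return build_scene(small_grid_layout, small_plan, params)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
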