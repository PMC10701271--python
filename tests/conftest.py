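"""Shared fixtures: phantoms and small grids, generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from srsplan.grid import PlanCase, VoxelGrid
from srsplan.phantom import PhantomSpec, generate_case


@pytest.fixture(scope="session")
def bare_case() -> PlanCase:
    """Desk-scale phantom without a reference dose (fast)."""
    return generate_case(PhantomSpec(pgtv_radius=12.0, seed=3, with_reference_dose=False))


@pytest.fixture(scope="session")
def ref_case() -> PlanCase:
    """Desk-scale phantom with its optimized reference dose."""
    return generate_case(PhantomSpec(pgtv_radius=12.0, seed=3))


@pytest.fixture(scope="session")
def mimic_result(ref_case):
    """The full mimic pipeline run against the phantom's reference dose."""
    from srsplan.mimic import mimic_pipeline

    return mimic_pipeline(ref_case, ref_case.reference_dose)


@pytest.fixture()
def sphere_grid() -> tuple[VoxelGrid, VoxelGrid]:
    """A 24^3 grid at 2.5 mm with a 10 mm sphere mask centred in it."""
    n, sp = 24, 2.5
    origin = (-(n - 1) * sp / 2.0,) * 3
    g = VoxelGrid(np.zeros((n, n, n)), origin=origin, spacing=(sp, sp, sp))
    ax = [origin[0] + sp * np.arange(n)] * 3
    x, y, z = np.meshgrid(*ax, indexing="ij")
    mask = x**2 + y**2 + z**2 <= 10.0**2
    return g, g.copy(mask.astype(np.uint8))
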