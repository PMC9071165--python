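"""Shared fixtures: small geometries and default parameter sets.

The "tiny" spine is deliberately coarse -- a few thousand unknowns -- so
solver behaviour (conservation, convergence, oracle equivalence) can be
exercised in seconds.  The reference desk-scale spine used by the sweep
experiments lives in :func:`spinesim.geometry.reference_spine` and is
built once per session where needed.
"""

import numpy as np
import pytest

from spinesim.geometry import SpineParams, build_synthetic_spine
from spinesim.parameters import ModelParameters, SimulationConfig


@pytest.fixture(scope="session")
def params():
    return ModelParameters()


@pytest.fixture(scope="session")
def tiny_spine_params():
    """Small SA-containing spine at coarse resolution (fast to mesh/solve)."""
    return SpineParams(
        head_radius=0.2, neck_length=0.3, neck_radius=0.14,
        dendrite_radius=0.24, dendrite_length=0.8,
        sa_neck_radius=0.065, sa_head_radius=0.075,
        er_tubule_radius=0.08, psd_area=0.06,
        target_edge_length_dendrite=0.08, target_edge_length_spine=0.08,
    )


@pytest.fixture(scope="session")
def tiny_mesh(tiny_spine_params):
    return build_synthetic_spine(tiny_spine_params)


@pytest.fixture(scope="session")
def tiny_mesh_nosa(tiny_spine_params):
    return build_synthetic_spine(tiny_spine_params.replace(include_sa=False))


@pytest.fixture
def quick_config():
    return SimulationConfig(t_end=2e-3, tau_sim=40e-6)
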