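import numpy as np
import pytest

from plaquemetry import SyntheticSpec, add_plaque, make_crown, signed_distance_field
from plaquemetry.pipeline import simulate_study


@pytest.fixture(scope="session")
def crown_spec():
    return SyntheticSpec(edge_length=0.25, seed=42)


@pytest.fixture(scope="session")
def crown(crown_spec):
    mesh, roi = make_crown(crown_spec)
    return mesh, roi


@pytest.fixture(scope="session")
def plaque_pair(crown_spec, crown):
    """T0 crown, T4 offset mesh, and ground truth for the default spec."""
    mesh, roi = crown
    t4, gt = add_plaque(mesh, roi, crown_spec)
    return mesh, t4, gt


@pytest.fixture(scope="session")
def thickness_field(plaque_pair):
    mesh, t4, _ = plaque_pair
    return signed_distance_field(mesh, t4)


@pytest.fixture(scope="session")
def flat_patch():
    """Planar 10 x 10 mm patch (degenerate crown settings)."""
    spec = SyntheticSpec(radius_x=5.0, radius_y=5.0, bulge=0.0, edge_length=0.25, seed=0)
    mesh, roi = make_crown(spec)
    return mesh, roi, spec


@pytest.fixture(scope="session")
def study_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("study")
    simulate_study(out, n_subjects=2, teeth_per_subject=2, seed=7, edge_length=0.3)
    return out
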