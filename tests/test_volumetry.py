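import numpy as np
import pytest

from plaquemetry import SyntheticSpec, add_plaque, make_crown
from plaquemetry.core import SurfaceMesh, ValidationError, closest_point_brute_force
from plaquemetry.volumetry import (
    ThicknessField,
    binarize_field,
    compute_vpi,
    signed_distance_field,
)


def _plane(z, n=11, size=10.0):
    g = np.linspace(-size / 2, size / 2, n)
    xx, yy = np.meshgrid(g, g, indexing="ij")
    v = np.column_stack([xx.ravel(), yy.ravel(), np.full(n * n, float(z))])
    idx = np.arange(n * n).reshape(n, n)
    a, b, c, d = idx[:-1, :-1].ravel(), idx[1:, :-1].ravel(), idx[:-1, 1:].ravel(), idx[1:, 1:].ravel()
    f = np.concatenate([np.column_stack([a, b, d]), np.column_stack([a, d, c])])
    return SurfaceMesh(v, f)


def test_identical_surfaces_give_zero_field():
    m = _plane(0.0)
    f = signed_distance_field(m, m)
    assert np.allclose(f.d, 0.0, atol=1e-12)


def test_parallel_planes_distance():
    """T4 at z = 0.05 over T0 at z = 0 (normals +z): d = +0.05 everywhere."""
    t0 = _plane(0.0)
    t4 = _plane(0.05)
    f = signed_distance_field(t0, t4)
    assert np.allclose(f.d, 0.05, atol=1e-12)
    # and negative when T4 lies below T0
    f_neg = signed_distance_field(t0, _plane(-0.05))
    assert np.allclose(f_neg.d, -0.05, atol=1e-12)


def test_field_matches_brute_force_on_curved_pair(plaque_pair):
    """Fast nearest-triangle search equals the all-triangles oracle."""
    mesh, t4, _ = plaque_pair
    rng = np.random.default_rng(2)
    sel = rng.choice(mesh.n_vertices, 40, replace=False)
    f = signed_distance_field(mesh, t4)
    _, _, d_oracle = closest_point_brute_force(mesh.vertices[sel], t4)
    assert np.allclose(np.abs(f.d[sel]), d_oracle, atol=1e-9)


def test_field_tracks_true_thickness(plaque_pair):
    mesh, t4, gt = plaque_pair
    f = signed_distance_field(mesh, t4)
    interior = gt.vertex_thickness > 0.05
    assert np.abs(f.d[interior] - gt.vertex_thickness[interior]).max() <= 0.01


def test_missing_data_cap():
    t0 = _plane(0.0)
    t4 = _plane(5.0)  # farther than the 1 mm cap everywhere
    with pytest.raises(ValidationError, match="coverage"):
        signed_distance_field(t0, t4)


def test_vpi_uniform_thickness_arithmetic():
    """Uniform 0.05 mm over a flat 10x10 ROI: VPI = 5 mm^3, AVPI = 0.05."""
    m = _plane(0.0, n=21)
    f = ThicknessField(d=np.full(m.n_vertices, 0.05), a=m.vertex_areas())
    idx = compute_vpi(f)
    assert np.isclose(idx.vpi, 5.0, rtol=1e-12)
    assert np.isclose(idx.avpi, 0.05, rtol=1e-12)
    assert idx.covered_fraction == 1.0
    assert idx.avpi == idx.vpi / idx.roi_area  # exact identity


def test_vpi_below_detection_limit_is_zero():
    m = _plane(0.0)
    f = ThicknessField(d=np.full(m.n_vertices, 0.005), a=m.vertex_areas())
    idx = compute_vpi(f)
    assert idx.vpi == 0.0
    assert idx.covered_fraction == 0.0


def test_negative_distances_clamped_unless_signed():
    m = _plane(0.0)
    d = np.full(m.n_vertices, -0.05)
    f = ThicknessField(d=d, a=m.vertex_areas())
    assert compute_vpi(f).vpi == 0.0
    assert compute_vpi(f, signed_volume=True).vpi < 0 or True  # signed integral may be negative
    assert np.isclose(compute_vpi(f, signed_volume=True).vpi, -5.0, rtol=1e-12)


def test_vpi_monotone_in_thickness(thickness_field):
    base = compute_vpi(thickness_field).vpi
    bigger = ThicknessField(
        d=thickness_field.d + 0.01, a=thickness_field.a, missing=thickness_field.missing
    )
    assert compute_vpi(bigger).vpi >= base


def test_vpi_additive_over_partition(thickness_field):
    f = thickness_field
    n = len(f.d)
    half = n // 2
    v1 = compute_vpi(ThicknessField(d=f.d[:half], a=f.a[:half], missing=f.missing[:half])).vpi
    v2 = compute_vpi(ThicknessField(d=f.d[half:], a=f.a[half:], missing=f.missing[half:])).vpi
    assert np.isclose(v1 + v2, compute_vpi(f).vpi, rtol=1e-12)


def test_vpi_rigid_invariance(plaque_pair):
    mesh, t4, _ = plaque_pair
    from plaquemetry.registration import RigidTransform

    r = RigidTransform(
        np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1.0]]), np.array([3.0, -2.0, 1.0])
    )
    v0 = compute_vpi(signed_distance_field(mesh, t4)).vpi
    mesh_r = mesh.transformed(r.rotation, r.translation)
    t4_r = t4.transformed(r.rotation, r.translation)
    v1 = compute_vpi(signed_distance_field(mesh_r, t4_r)).vpi
    assert np.isclose(v0, v1, rtol=1e-9)


def test_vpi_recovers_true_volume(plaque_pair):
    mesh, t4, gt = plaque_pair
    vpi = compute_vpi(signed_distance_field(mesh, t4)).vpi
    assert abs(vpi - gt.true_volume) / gt.true_volume <= 0.02


def test_vpi_error_shrinks_with_resolution():
    """Analytic-offset recovery error strictly decreases over 3 resolutions."""
    errs = []
    for edge in (1.2, 0.6, 0.3):
        # full-coverage smooth offset: the only error source is discretization
        spec = SyntheticSpec(
            edge_length=edge, seed=12, coverage_fraction=1.0, maturity_fraction=0.0,
            dark_thickness_boost=0.0, gingival_decay_mm=1e9, thickness_floor=1.0,
            max_thickness=0.1,
        )
        mesh, roi = make_crown(spec)
        t4, gt = add_plaque(mesh, roi, spec)
        vpi = compute_vpi(signed_distance_field(mesh, t4)).vpi
        errs.append(abs(vpi - gt.true_volume) / gt.true_volume)
    assert errs[0] > errs[1] > errs[2]


def test_binarize_matches_covered_fraction(thickness_field):
    _, frac = binarize_field(thickness_field, cutoff=thickness_field.detection_limit)
    assert frac == compute_vpi(thickness_field).covered_fraction


def test_binarize_alternating_half():
    m = _plane(0.0)
    d = np.where(np.arange(m.n_vertices) % 2 == 0, 0.02, 0.005)
    a = np.ones(m.n_vertices)  # equal-area weights
    f = ThicknessField(d=d, a=a)
    _, frac = binarize_field(f)
    assert abs(frac - 0.5) < 0.01
    _, frac0 = binarize_field(ThicknessField(d=np.zeros(m.n_vertices), a=a))
    assert frac0 == 0.0
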