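import math

import numpy as np
import pytest

from plaquemetry.core import ValidationError
from plaquemetry.projection import (
    ProjectionSpec,
    planivolmap,
    rasterize,
    render_thickness_map,
)
from plaquemetry.volumetry import ThicknessField, binarize_field


def _field(mesh, values):
    return ThicknessField(d=np.asarray(values, float), a=mesh.vertex_areas())


def test_flat_roi_uniform_value(flat_patch):
    mesh, _, _ = flat_patch
    f = _field(mesh, np.full(mesh.n_vertices, 0.05))
    m = render_thickness_map(mesh, f, ProjectionSpec([0, 0, 1], [0, 1, 0], 0.1), mode="continuous")
    vals = m.raster[m.roi_pixel_mask]
    assert np.allclose(vals, 0.05, atol=1e-9)


def test_boolean_render_of_zero_field(flat_patch):
    mesh, _, _ = flat_patch
    f = _field(mesh, np.zeros(mesh.n_vertices))
    m = render_thickness_map(mesh, f, mode="boolean")
    assert not (m.raster[m.roi_pixel_mask] > 0.5).any()
    assert planivolmap(m) == 0.0


def test_planivolmap_half_coverage(flat_patch):
    """Half the ROI above cutoff projects to ~50% coverage."""
    mesh, _, _ = flat_patch
    d = np.where(mesh.vertices[:, 0] > 0, 0.05, 0.0)
    m = render_thickness_map(mesh, _field(mesh, d), ProjectionSpec([0, 0, 1], [0, 1, 0], 0.05), mode="boolean")
    assert abs(planivolmap(m) - 50.0) < 1.5


def test_planivolmap_requires_boolean(flat_patch):
    mesh, _, _ = flat_patch
    m = render_thickness_map(mesh, _field(mesh, np.zeros(mesh.n_vertices)), mode="continuous")
    with pytest.raises(ValidationError):
        planivolmap(m)


def test_raster_matches_ray_cast_oracle(crown):
    """Per-pixel interpolated values agree with an independent ray/triangle oracle."""
    mesh, _ = crown
    values = mesh.vertices[:, 2] * 3.0 + mesh.vertices[:, 0]  # linear per-vertex field
    spec = ProjectionSpec([0, 0, 1], [0, 1, 0], 0.1)
    raster, mask, _ = rasterize(mesh, values, spec)

    u, v, w = spec.basis()
    px = mesh.vertices @ u
    py = mesh.vertices @ v
    x0, y0 = px.min() - spec.pixel_size, py.min() - spec.pixel_size

    rng = np.random.default_rng(4)
    jj, ii = np.nonzero(mask)
    pick = rng.choice(len(ii), 200, replace=False)
    tri = mesh.faces
    for j, i in zip(jj[pick], ii[pick]):
        # oracle: exact 2D point-in-triangle + barycentric interpolation,
        # front-most triangle by interpolated depth
        qx = x0 + (i + 0.5) * spec.pixel_size
        qy = y0 + (j + 0.5) * spec.pixel_size
        best_z, best_val = -np.inf, None
        for f in tri:
            ax, ay = px[f[0]], py[f[0]]
            bx, by = px[f[1]], py[f[1]]
            cx, cy = px[f[2]], py[f[2]]
            det = (bx - ax) * (cy - ay) - (cx - ax) * (by - ay)
            if abs(det) < 1e-14:
                continue
            l1 = ((qx - ax) * (cy - ay) - (cx - ax) * (qy - ay)) / det
            l2 = ((bx - ax) * (qy - ay) - (qx - ax) * (by - ay)) / det
            l0 = 1 - l1 - l2
            if l0 < -1e-9 or l1 < -1e-9 or l2 < -1e-9:
                continue
            depth = l0 * (mesh.vertices[f[0]] @ w) + l1 * (mesh.vertices[f[1]] @ w) + l2 * (mesh.vertices[f[2]] @ w)
            if depth > best_z:
                best_z = depth
                best_val = l0 * values[f[0]] + l1 * values[f[1]] + l2 * values[f[2]]
        assert best_val is not None
        assert abs(raster[j, i] - best_val) < 1e-6


def test_foreshortening_cosine(flat_patch):
    """Tilting a flat ROI 60 degrees halves its projected pixel count."""
    mesh, _, _ = flat_patch
    f = _field(mesh, np.zeros(mesh.n_vertices))
    m0 = render_thickness_map(mesh, f, ProjectionSpec([0, 0, 1], [0, 1, 0], 0.05), mode="boolean")
    th = math.radians(60)
    m1 = render_thickness_map(
        mesh, f, ProjectionSpec([math.sin(th), 0, math.cos(th)], [0, 1, 0], 0.05), mode="boolean"
    )
    ratio = m1.roi_pixel_mask.sum() / m0.roi_pixel_mask.sum()
    assert abs(ratio - 0.5) < 0.01


def test_planivolmap_stable_under_pixel_halving(plaque_pair):
    mesh, t4, _ = plaque_pair
    from plaquemetry.volumetry import signed_distance_field

    f = signed_distance_field(mesh, t4)
    spec1 = ProjectionSpec.for_roi(mesh, pixel_size=0.08)
    spec2 = ProjectionSpec.for_roi(mesh, pixel_size=0.04)
    p1 = planivolmap(render_thickness_map(mesh, f, spec1, mode="boolean"))
    p2 = planivolmap(render_thickness_map(mesh, f, spec2, mode="boolean"))
    assert abs(p1 - p2) < 1.0


def test_flat_planivolmap_equals_area_fraction(flat_patch):
    """No foreshortening when viewing a flat ROI along its normal."""
    mesh, roi, spec = flat_patch
    from plaquemetry import add_plaque
    from plaquemetry.volumetry import signed_distance_field

    t4, _ = add_plaque(mesh, roi, spec)
    f = signed_distance_field(mesh, t4)
    _, frac = binarize_field(f)
    m = render_thickness_map(mesh, f, ProjectionSpec([0, 0, 1], [0, 1, 0], 0.05), mode="boolean")
    assert abs(planivolmap(m) - 100 * frac) < 1.0


def test_too_coarse_pixels_rejected(flat_patch):
    mesh, _, _ = flat_patch
    f = _field(mesh, np.zeros(mesh.n_vertices))
    with pytest.raises(ValidationError, match="pixel"):
        render_thickness_map(mesh, f, ProjectionSpec([0, 0, 1], [0, 1, 0], 20.0), mode="boolean")


def test_map_exports(tmp_path, flat_patch):
    mesh, _, _ = flat_patch
    from plaquemetry.projection import save_map_png, save_thickness_tiff

    f = _field(mesh, np.full(mesh.n_vertices, 0.05))
    for mode in ("continuous", "categorized", "boolean"):
        m = render_thickness_map(mesh, f, mode=mode)
        save_map_png(m, tmp_path / f"{mode}.png")
        assert (tmp_path / f"{mode}.png").exists()
        assert (tmp_path / f"{mode}.png.legend.json").exists()
    save_thickness_tiff(render_thickness_map(mesh, f, mode="continuous"), tmp_path / "t.tiff")
    import tifffile

    assert tifffile.imread(tmp_path / "t.tiff").dtype == np.uint16
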