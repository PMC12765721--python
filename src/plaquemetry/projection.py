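"""Orthographic rendering of thickness fields into 2D maps.

The study's screenshots came from scanner software with an unstated
camera; here a deterministic canonical projection is defined instead and
stored with every run: orthographic (no camera-distance dependence), view
axis defaulting to the area-weighted mean outward ROI normal, up axis to
the occluso-gingival direction. Hidden surfaces are resolved by a depth
test (front-most triangle wins), matching what a screenshot would show.

Rendered Boolean maps (0.01 mm cutoff) feed the planimetric coverage
measure PLANIvolmap = 100 x plaque pixels / ROI pixels. Note that for
curved surfaces this 2D quantity differs from the area-weighted 3D
coverage — map-projection-style distortion grows toward the silhouette —
which is why both numbers are reported by the pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import SurfaceMesh, ValidationError
from .volumetry import DETECTION_LIMIT_MM, ThicknessField

DEFAULT_PIXEL_SIZE_MM = 0.02
DEFAULT_CATEGORY_EDGES_MM = (0.01, 0.05, 0.10, 0.20)
MIN_ROI_PIXELS = 10


@dataclass
class ProjectionSpec:
    """Canonical orthographic projection: view axis, up axis, pixel size (mm/px)."""

    view_direction: np.ndarray
    up_vector: np.ndarray
    pixel_size: float = DEFAULT_PIXEL_SIZE_MM

    def __post_init__(self) -> None:
        self.view_direction = np.asarray(self.view_direction, dtype=float)
        self.up_vector = np.asarray(self.up_vector, dtype=float)
        nv = np.linalg.norm(self.view_direction)
        nu = np.linalg.norm(self.up_vector)
        if nv == 0 or nu == 0:
            raise ValidationError("view and up vectors must be non-zero")
        self.view_direction = self.view_direction / nv
        self.up_vector = self.up_vector / nu
        if self.pixel_size <= 0:
            raise ValidationError("pixel_size must be positive")
        if np.linalg.norm(np.cross(self.view_direction, self.up_vector)) < 1e-9:
            raise ValidationError("view and up vectors are parallel")

    def basis(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Right, up, view unit vectors (view points from surface toward camera)."""
        w = self.view_direction
        u = np.cross(self.up_vector, w)
        u = u / np.linalg.norm(u)
        v = np.cross(w, u)
        return u, v, w

    @classmethod
    def for_roi(cls, roi_mesh: SurfaceMesh, pixel_size: float = DEFAULT_PIXEL_SIZE_MM) -> "ProjectionSpec":
        """Default projection for a ROI: along its mean outward normal.

        The up axis is the ROI's major principal direction projected
        orthogonal to the view axis (occluso-gingival for a buccal patch).
        """
        fa = roi_mesh.face_areas()
        fn = roi_mesh.face_normals()
        view = (fa[:, None] * fn).sum(axis=0)
        if np.linalg.norm(view) < 1e-12:
            raise ValidationError("ROI has no net outward normal (closed or degenerate)")
        view = view / np.linalg.norm(view)
        centered = roi_mesh.vertices - roi_mesh.vertices.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        up = vt[0]
        up = up - np.dot(up, view) * view
        if np.linalg.norm(up) < 1e-9:
            up = vt[1] - np.dot(vt[1], view) * view
        return cls(view, up, pixel_size)


@dataclass
class RenderedMap:
    """Rasterized map of a ROI: value grid, ROI pixel mask, projection, legend."""

    raster: np.ndarray
    roi_pixel_mask: np.ndarray
    spec: ProjectionSpec
    mode: str
    legend: list[tuple[float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.raster.shape != self.roi_pixel_mask.shape:
            raise ValidationError("raster and roi_pixel_mask shapes differ")


def rasterize(
    mesh: SurfaceMesh,
    values: np.ndarray,
    spec: ProjectionSpec,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Orthographic rasterization with z-buffer and barycentric interpolation.

    Returns (value_raster, roi_pixel_mask, depth_raster). Pixels are
    sampled at their centres; a pixel belongs to the ROI if its centre
    falls inside some projected triangle, and it takes the value of the
    front-most such triangle interpolated barycentrically.
    """
    u, v, w = spec.basis()
    values = np.asarray(values, dtype=float)
    if len(values) != mesh.n_vertices:
        raise ValidationError("one value per mesh vertex required")
    px = mesh.vertices @ u
    py = mesh.vertices @ v
    depth = mesh.vertices @ w  # larger = closer to camera

    pad = spec.pixel_size
    x0, y0 = px.min() - pad, py.min() - pad
    nx = int(np.ceil((px.max() + pad - x0) / spec.pixel_size))
    ny = int(np.ceil((py.max() + pad - y0) / spec.pixel_size))
    raster = np.full((ny, nx), np.nan)
    zbuf = np.full((ny, nx), -np.inf)
    mask = np.zeros((ny, nx), dtype=bool)

    # pixel-centre coordinates
    fx = (px - x0) / spec.pixel_size - 0.5
    fy = (py - y0) / spec.pixel_size - 0.5

    for f in mesh.faces:
        ax, ay, bx, by, cx, cy = fx[f[0]], fy[f[0]], fx[f[1]], fy[f[1]], fx[f[2]], fy[f[2]]
        det = (bx - ax) * (cy - ay) - (cx - ax) * (by - ay)
        if abs(det) < 1e-14:
            continue
        i0 = max(int(np.floor(min(ax, bx, cx))), 0)
        i1 = min(int(np.ceil(max(ax, bx, cx))) + 1, nx)
        j0 = max(int(np.floor(min(ay, by, cy))), 0)
        j1 = min(int(np.ceil(max(ay, by, cy))) + 1, ny)
        if i0 >= i1 or j0 >= j1:
            continue
        gi, gj = np.meshgrid(np.arange(i0, i1), np.arange(j0, j1))
        qx = gi.ravel().astype(float)
        qy = gj.ravel().astype(float)
        l1 = ((qx - ax) * (cy - ay) - (cx - ax) * (qy - ay)) / det
        l2 = ((bx - ax) * (qy - ay) - (qx - ax) * (by - ay)) / det
        l0 = 1.0 - l1 - l2
        inside = (l0 >= -1e-12) & (l1 >= -1e-12) & (l2 >= -1e-12)
        if not inside.any():
            continue
        ii = gi.ravel()[inside]
        jj = gj.ravel()[inside]
        zz = l0[inside] * depth[f[0]] + l1[inside] * depth[f[1]] + l2[inside] * depth[f[2]]
        vv = l0[inside] * values[f[0]] + l1[inside] * values[f[1]] + l2[inside] * values[f[2]]
        closer = zz > zbuf[jj, ii]
        jj, ii = jj[closer], ii[closer]
        zbuf[jj, ii] = zz[closer]
        raster[jj, ii] = vv[closer]
        mask[jj, ii] = True

    return raster, mask, zbuf


def render_thickness_map(
    roi_mesh: SurfaceMesh,
    fieldv: ThicknessField,
    spec: ProjectionSpec | None = None,
    mode: str = "continuous",
    cutoff: float = DETECTION_LIMIT_MM,
    category_edges: tuple[float, ...] = DEFAULT_CATEGORY_EDGES_MM,
) -> RenderedMap:
    """Render a per-vertex thickness field into a 2D map.

    Modes: ``continuous`` (thickness in mm per pixel), ``categorized``
    (bin index per configurable thresholds), ``boolean`` (plaque present
    at the detection cutoff).
    """
    if mode not in ("continuous", "categorized", "boolean"):
        raise ValidationError(f"unknown render mode {mode!r}")
    if len(fieldv.d) != roi_mesh.n_vertices:
        raise ValidationError("thickness field does not match ROI mesh")
    if spec is None:
        spec = ProjectionSpec.for_roi(roi_mesh)
    raster, mask, _ = rasterize(roi_mesh, fieldv.d, spec)
    n_roi = int(mask.sum())
    if n_roi < MIN_ROI_PIXELS:
        raise ValidationError(
            f"ROI projects to only {n_roi} pixels; decrease pixel_size ({spec.pixel_size} mm/px)"
        )
    if mode == "boolean":
        out = np.where(mask, raster >= cutoff, False).astype(float)
        legend = [(cutoff, "white = plaque present")]
    elif mode == "categorized":
        edges = np.asarray(category_edges, dtype=float)
        out = np.where(mask, np.digitize(np.nan_to_num(raster), edges), 0).astype(float)
        legend = [(float(e), f"bin >= {e:g} mm") for e in edges]
    else:
        out = raster
        legend = [(0.0, "thickness mm, perceptually-uniform scale")]
    return RenderedMap(raster=out, roi_pixel_mask=mask, spec=spec, mode=mode, legend=legend)


def planivolmap(rendered: RenderedMap) -> float:
    """Percent plaque coverage of the rendered Boolean map (PLANIvolmap)."""
    if rendered.mode != "boolean":
        raise ValidationError("planivolmap requires a boolean-mode map")
    n_roi = int(rendered.roi_pixel_mask.sum())
    if n_roi == 0:
        raise ValidationError("empty ROI pixel mask")
    n_true = int(np.count_nonzero(rendered.raster[rendered.roi_pixel_mask] > 0.5))
    return 100.0 * n_true / n_roi


# -- export ----------------------------------------------------------------


def save_map_png(rendered: RenderedMap, path: str | Path) -> None:
    """Export a rendered map as PNG with a JSON legend sidecar."""
    from PIL import Image

    r = rendered.raster
    m = rendered.roi_pixel_mask
    if rendered.mode == "boolean":
        img = np.where(m & (r > 0.5), 255, 0).astype(np.uint8)
        Image.fromarray(img, mode="L").save(path)
    elif rendered.mode == "categorized":
        n_bins = len(rendered.legend) + 1
        g = np.where(m, (255 * r / max(n_bins - 1, 1)), 0).astype(np.uint8)
        Image.fromarray(g, mode="L").save(path)
    else:
        import matplotlib.cm as cm

        vmax = np.nanmax(r[m]) if m.any() and np.isfinite(r[m]).any() else 1.0
        vmax = vmax if vmax > 0 else 1.0
        norm = np.clip(np.nan_to_num(r) / vmax, 0, 1)
        rgba = (cm.viridis(norm) * 255).astype(np.uint8)
        rgba[~m] = (0, 0, 0, 255)
        Image.fromarray(rgba, mode="RGBA").save(path)
    sidecar = Path(str(path) + ".legend.json")
    sidecar.write_text(
        json.dumps(
            {
                "mode": rendered.mode,
                "pixel_size_mm": rendered.spec.pixel_size,
                "view_direction": rendered.spec.view_direction.tolist(),
                "up_vector": rendered.spec.up_vector.tolist(),
                "legend": [[t, lbl] for t, lbl in rendered.legend],
            },
            sort_keys=True,
        )
    )


def save_thickness_tiff(rendered: RenderedMap, path: str | Path, scale_um: float = 1.0) -> None:
    """16-bit grayscale TIFF of the raw thickness raster (micrometre units)."""
    import tifffile

    r = np.where(rendered.roi_pixel_mask, np.nan_to_num(rendered.raster), 0.0)
    um = np.clip(r * 1000.0 / scale_um, 0, 65535).astype(np.uint16)
    tifffile.imwrite(str(path), um)
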