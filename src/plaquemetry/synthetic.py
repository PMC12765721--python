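"""Synthetic tooth surfaces with known plaque ground truth.

Emulates what the real study measures — paired buccal-surface scans of
the same tooth before (T0, clean) and after (T4) four days of undisturbed
plaque formation — with every quantity of interest known exactly:

* a smooth superellipse-profiled crown patch (open surface, outward
  normals, plausible premolar/incisor buccal dimensions);
* a de-novo plaque layer as an outward normal offset: a smoothed random
  coverage field biased toward the gingival margin (plaque forms as
  flecks or a band at the gingival crevice), thickness shaped by a
  gingival decay profile and a smooth random modulation; the thickest
  fraction of the covered area is "mature" and stains dark;
* scanner corruption: zero-mean Gaussian noise along normals plus a
  rigid pose offset;
* a two-tone disclosed-image render (pink new plaque, purple mature
  plaque, pale enamel) with per-pixel ground-truth class masks;
* whole-cohort generation with TMQHPlI-like site scores derived from
  true coverage through the Turesky band definitions plus ordinal noise.

Ground-truth volume is always computed by high-resolution quadrature in
the surface's parameter space, with the analytic area element — never by
the volumetry module, which it serves to check.

Plaque-thickness fields live on a fixed fine parameter grid and are
interpolated to mesh vertices, so truth and mesh sample one and the same
realization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator

from .core import SurfaceMesh, ValidationError
from .io import ROIMask
from .planimetry import CLASS_DARK_PURPLE, CLASS_LIGHT_PINK, CLASS_NON_PLAQUE, DisclosedImage
from .projection import ProjectionSpec, rasterize
from .registration import RigidTransform
from .volumetry import DETECTION_LIMIT_MM

FINE_GRID = 257  # parameter-space resolution for truth quadrature

# two-tone disclosing dye appearance (RGB): pink ~ erythrosine, purple ~
# erythrosine + patent blue in thick plaque; enamel pale yellow-white
COLOR_TOOTH = (245, 240, 222)
COLOR_PINK = (231, 105, 160)
COLOR_PURPLE = (104, 62, 142)


@dataclass
class SyntheticSpec:
    """Study-condition parameters for one synthetic tooth surface.

    Crown: half-width/half-height radii (mm) and bulge height of a
    superellipse-profiled dome; ``bulge = 0`` degenerates to a flat patch.
    Plaque: target covered area fraction, maximum thickness (mm), decay
    length of the gingival thickness gradient (mm), fraction of covered
    area that is mature/dark, and a thickness boost for the mature
    sub-region (mature plaque is denser and thicker). Scan: normal-noise
    SD (mm) and rigid pose perturbation.
    """

    radius_x: float = 5.0
    radius_y: float = 6.0
    bulge: float = 2.0
    exponent_x: float = 2.0
    exponent_y: float = 2.0
    asym_x: float = 0.15  # dome lean; real crowns are not mirror-symmetric,
    asym_y: float = 0.10  # and symmetry would make rigid recovery ambiguous
    edge_length: float = 0.1

    coverage_fraction: float = 0.35
    max_thickness: float = 0.15
    gingival_decay_mm: float = 3.0
    maturity_fraction: float = 0.5
    dark_thickness_boost: float = 1.0
    plaque_patch_scale_mm: float = 2.0
    thickness_floor: float = 0.35  # min interior thickness as a fraction of the local profile
    edge_smoothing_mm: float = 0.5  # lateral taper scale: biofilm is far wider than thick
    margin_thickness_mm: float = 0.04  # film thinner than this is smoothly suppressed at margins

    scan_noise_sd: float = 0.0
    pose_rotation_deg: float = 0.0
    pose_translation_mm: float = 0.0

    image_pixel_size: float = 0.05
    image_noise_sd: float = 6.0

    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.coverage_fraction <= 1 and 0 <= self.maturity_fraction <= 1):
            raise ValidationError("coverage and maturity fractions must lie in [0, 1]")
        for name in ("radius_x", "radius_y", "edge_length", "gingival_decay_mm", "plaque_patch_scale_mm"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.bulge < 0 or self.max_thickness < 0:
            raise ValidationError("bulge and max_thickness must be non-negative")
        if self.exponent_x < 1 or self.exponent_y < 1:
            raise ValidationError("profile exponents must be >= 1 for a smooth boundary")


@dataclass
class GroundTruth:
    """Exact per-surface truth, independent of the measurement modules."""

    true_volume: float  # mm^3, fine-grid quadrature of the thickness field
    true_area: float  # mm^2, fine-grid quadrature of the area element
    true_coverage_fraction: float  # area fraction with thickness >= detection limit
    covered_area_fraction: float  # area fraction of the generative covered region
    true_dark_fraction: float  # dark area / covered area
    vertex_thickness: np.ndarray
    vertex_covered: np.ndarray
    vertex_dark: np.ndarray
    applied_transform: RigidTransform | None = None


# -- crown geometry --------------------------------------------------------


def _surface_derivs(
    u: np.ndarray, v: np.ndarray, spec: SyntheticSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Height z(u, v) and its parameter derivatives z_u, z_v.

    z = bulge * cos^ex * cos^ey * A with the lean factor
    A = 1 + asym_x (2u - 1) + asym_y (2v - 1) breaking mirror symmetry.
    """
    cu = np.cos(np.pi * (2 * u - 1) / 2)
    cv = np.cos(np.pi * (2 * v - 1) / 2)
    su = np.sin(np.pi * (2 * u - 1) / 2)
    sv = np.sin(np.pi * (2 * v - 1) / 2)
    lean = 1 + spec.asym_x * (2 * u - 1) + spec.asym_y * (2 * v - 1)
    shape = cu**spec.exponent_x * cv**spec.exponent_y
    z = spec.bulge * shape * lean
    d_shape_u = -spec.exponent_x * np.pi * cu ** (spec.exponent_x - 1) * su * cv**spec.exponent_y
    d_shape_v = -spec.exponent_y * np.pi * cv ** (spec.exponent_y - 1) * sv * cu**spec.exponent_x
    zu = spec.bulge * (d_shape_u * lean + shape * 2 * spec.asym_x)
    zv = spec.bulge * (d_shape_v * lean + shape * 2 * spec.asym_y)
    return z, zu, zv


def _surface_z(u: np.ndarray, v: np.ndarray, spec: SyntheticSpec) -> np.ndarray:
    return _surface_derivs(u, v, spec)[0]


def _surface_normal(u: np.ndarray, v: np.ndarray, spec: SyntheticSpec) -> np.ndarray:
    """Analytic outward (+z side) unit normals at parameter points."""
    _, zu, zv = _surface_derivs(u, v, spec)
    # r_u = (2rx, 0, zu), r_v = (0, 2ry, zv)
    n = np.stack(
        [-2 * spec.radius_y * zu, -2 * spec.radius_x * zv, np.full_like(zu, 4 * spec.radius_x * spec.radius_y)],
        axis=-1,
    )
    return n / np.linalg.norm(n, axis=-1, keepdims=True)


def _area_element(u: np.ndarray, v: np.ndarray, spec: SyntheticSpec) -> np.ndarray:
    """|r_u x r_v| at parameter points (area per unit du dv)."""
    _, zu, zv = _surface_derivs(u, v, spec)
    return np.sqrt(
        (2 * spec.radius_y * zu) ** 2 + (2 * spec.radius_x * zv) ** 2 + (4 * spec.radius_x * spec.radius_y) ** 2
    )


def _vertex_uv(mesh: SurfaceMesh, spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    """Recover parameter coordinates from crown vertex x, y (linear map)."""
    u = (mesh.vertices[:, 0] / spec.radius_x + 1) / 2
    v = (mesh.vertices[:, 1] / spec.radius_y + 1) / 2
    return np.clip(u, 0, 1), np.clip(v, 0, 1)


def make_crown(spec: SyntheticSpec) -> tuple[SurfaceMesh, ROIMask]:
    """Smooth open buccal-like crown patch and its full-surface ROI.

    The grid spacing is 0.85x the requested edge length so that both grid
    edges and quad diagonals stay within 20% of the target.
    """
    spacing = 0.85 * spec.edge_length
    nu = max(3, int(round(2 * spec.radius_x / spacing)) + 1)
    nv = max(3, int(round(2 * spec.radius_y / spacing)) + 1)
    if nu * nv > 4_000_000:
        raise ValidationError("tessellation infeasible: edge length too small for patch size")
    u = np.linspace(0, 1, nu)
    v = np.linspace(0, 1, nv)
    uu, vv = np.meshgrid(u, v, indexing="ij")
    x = (2 * uu - 1) * spec.radius_x
    y = (2 * vv - 1) * spec.radius_y
    z = _surface_z(uu, vv, spec)
    vertices = np.column_stack([x.ravel(), y.ravel(), z.ravel()])

    idx = np.arange(nu * nv).reshape(nu, nv)
    a = idx[:-1, :-1].ravel()
    b = idx[1:, :-1].ravel()
    c = idx[:-1, 1:].ravel()
    d = idx[1:, 1:].ravel()
    # counter-clockwise seen from +z (outward)
    faces = np.concatenate([np.column_stack([a, b, d]), np.column_stack([a, d, c])])
    mesh = SurfaceMesh(vertices, faces)
    roi = ROIMask(tooth_id="11", vertex_ids=np.arange(mesh.n_vertices), timepoint="T0")
    return mesh, roi


# -- plaque layer ----------------------------------------------------------


def _smooth_unit_field(rng: np.random.Generator, sigma_cells: float) -> np.ndarray:
    f = ndimage.gaussian_filter(rng.standard_normal((FINE_GRID, FINE_GRID)), sigma_cells, mode="nearest")
    sd = f.std()
    return f / sd if sd > 0 else f


def _weighted_quantile(values: np.ndarray, weights: np.ndarray, q: float) -> float:
    order = np.argsort(values)
    cw = np.cumsum(weights[order])
    cw /= cw[-1]
    return float(np.interp(q, cw, values[order]))


def _smoothstep(x: np.ndarray) -> np.ndarray:
    s = np.clip(x, 0.0, 1.0)
    return s * s * (3 - 2 * s)


def _thickness_grid(spec: SyntheticSpec, rng: np.random.Generator) -> dict:
    """One realization of the plaque layer on the fine parameter grid."""
    g = np.linspace(0, 1, FINE_GRID)
    uu, vv = np.meshgrid(g, g, indexing="ij")
    da = _area_element(uu, vv, spec)  # relative weights (uniform du dv)
    y_mm = (2 * vv - 1) * spec.radius_y
    gingival_dist = y_mm + spec.radius_y  # gingival margin at v = 0

    sigma_cells = spec.plaque_patch_scale_mm / (2 * spec.radius_x / FINE_GRID)
    score = _smooth_unit_field(rng, sigma_cells) + 1.5 * np.exp(-gingival_dist / spec.gingival_decay_mm)
    modulation = 0.7 + 0.3 * (np.tanh(_smooth_unit_field(rng, sigma_cells)) + 1) / 2

    if spec.coverage_fraction <= 0:
        thickness = np.zeros_like(score)
        covered = np.zeros_like(score, dtype=bool)
        tau = np.inf
    elif spec.coverage_fraction >= 1:
        covered = np.ones_like(score, dtype=bool)
        tau = -np.inf
    else:
        tau = _weighted_quantile(score.ravel(), da.ravel(), 1 - spec.coverage_fraction)
        covered = score >= tau

    if spec.coverage_fraction > 0:
        profile = spec.thickness_floor + (1 - spec.thickness_floor) * np.exp(
            -gingival_dist / spec.gingival_decay_mm
        )
        ramp_width = 0.25  # in score SD units; narrow taper at the coverage boundary
        ramp = _smoothstep((score - tau) / ramp_width) if np.isfinite(tau) else np.ones_like(score)
        thickness = spec.max_thickness * profile * modulation * ramp
        thickness[~covered] = 0.0

    dark = np.zeros_like(covered)
    if covered.any() and spec.maturity_fraction > 0:
        t_cov = thickness[covered]
        w_cov = da[covered]
        if spec.maturity_fraction >= 1:
            t_thr = 0.0
        else:
            t_thr = _weighted_quantile(t_cov, w_cov, 1 - spec.maturity_fraction)
        if spec.dark_thickness_boost > 0:
            # smooth ramp, not a step: a thickness discontinuity along the
            # maturity boundary would not survive scanning or meshing
            width = 0.35 * max(t_thr, 0.05 * spec.max_thickness)
            boost = _smoothstep((thickness - t_thr) / width + 0.5)
            thickness = thickness * (1 + spec.dark_thickness_boost * boost)

    if covered.any() and spec.edge_smoothing_mm > 0:
        # final lateral smoothing: a deposit a quarter-millimetre thick
        # tapers over at least half a millimetre, never a near-vertical wall
        sig = spec.edge_smoothing_mm / (2 * spec.radius_x / FINE_GRID)
        thickness = ndimage.gaussian_filter(thickness, sig, mode="nearest")

    if covered.any() and spec.margin_thickness_mm > DETECTION_LIMIT_MM:
        # the smoothed taper leaves a wide micron-scale film apron; a scan
        # surface cannot express film below the ~10 um resolvable limit and
        # real deposit margins end at finite thickness, so sub-margin film
        # is smoothly shrunk to zero rather than spread over the surface
        thickness = thickness * _smoothstep(
            (thickness - DETECTION_LIMIT_MM) / (spec.margin_thickness_mm - DETECTION_LIMIT_MM)
        )

    if covered.any() and spec.maturity_fraction > 0:
        if spec.maturity_fraction >= 1:
            dark = covered.copy()
        else:
            t_thr = _weighted_quantile(thickness[covered], da[covered], 1 - spec.maturity_fraction)
            dark = covered & (thickness >= t_thr)

    return {"grid": g, "thickness": thickness, "covered": covered, "dark": dark, "da": da}


def add_plaque(
    mesh: SurfaceMesh, roi: ROIMask, spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> tuple[SurfaceMesh, GroundTruth]:
    """Offset the crown outward by a random plaque layer; return T4 mesh + truth.

    Raises if the offset would self-intersect (thickness too large for the
    local curvature — detected as a flipped face normal).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    layer = _thickness_grid(spec, rng)
    g = layer["grid"]

    interp_t = RegularGridInterpolator((g, g), layer["thickness"], bounds_error=False, fill_value=0.0)
    interp_c = RegularGridInterpolator((g, g), layer["covered"].astype(float), bounds_error=False, fill_value=0.0)
    interp_d = RegularGridInterpolator((g, g), layer["dark"].astype(float), bounds_error=False, fill_value=0.0)
    u, v = _vertex_uv(mesh, spec)
    pts = np.column_stack([u, v])
    t_vert = interp_t(pts)
    covered_vert = interp_c(pts) >= 0.5
    dark_vert = interp_d(pts) >= 0.5

    normals = _surface_normal(u, v, spec)
    t4 = SurfaceMesh(mesh.vertices + t_vert[:, None] * normals, mesh.faces.copy())
    if spec.max_thickness > 0:
        before = mesh.face_normals()
        after = t4.face_normals()
        if (np.einsum("ij,ij->i", before, after) < 0).any():
            raise ValidationError("plaque offset self-intersects (thickness too large for curvature)")

    da = layer["da"]
    # trapezoidal quadrature over the unit parameter square (boundary rows
    # carry half weight; a plain node mean would overweight the gingival
    # margin, where plaque is thickest)
    wt = np.ones(FINE_GRID)
    wt[0] = wt[-1] = 0.5
    wq = np.outer(wt, wt) / (FINE_GRID - 1) ** 2
    w = wq * da
    w = w / w.sum()
    true_area = float(np.sum(wq * da))
    true_volume = float(np.sum(wq * layer["thickness"] * da))
    detectable = layer["thickness"] >= DETECTION_LIMIT_MM
    true_cov = float(np.sum(w[detectable]))
    covered_area_fraction = float(np.sum(w[layer["covered"]]))
    cov_w = np.sum(w[layer["covered"]])
    dark_frac = float(np.sum(w[layer["dark"]]) / cov_w) if cov_w > 0 else 0.0

    gt = GroundTruth(
        true_volume=true_volume,
        true_area=true_area,
        true_coverage_fraction=true_cov,
        covered_area_fraction=covered_area_fraction,
        true_dark_fraction=dark_frac,
        vertex_thickness=t_vert,
        vertex_covered=covered_vert,
        vertex_dark=dark_vert,
    )
    return t4, gt


def corrupt_scan(
    mesh: SurfaceMesh, spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> tuple[SurfaceMesh, RigidTransform]:
    """Scanner emulation: Gaussian normal noise plus a rigid pose offset.

    Returns the corrupted mesh and the applied transform (so registration
    recovery can be scored against truth).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    v = mesh.vertices.copy()
    if spec.scan_noise_sd > 0:
        v = v + rng.normal(0, spec.scan_noise_sd, size=mesh.n_vertices)[:, None] * mesh.vertex_normals()
    transform = RigidTransform.identity()
    if spec.pose_rotation_deg != 0 or spec.pose_translation_mm != 0:
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        theta = np.deg2rad(spec.pose_rotation_deg)
        kx = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
        r = np.eye(3) + np.sin(theta) * kx + (1 - np.cos(theta)) * (kx @ kx)
        tdir = rng.normal(size=3)
        tdir /= np.linalg.norm(tdir)
        transform = RigidTransform(r, spec.pose_translation_mm * tdir)
        v = transform.apply(v)
    return SurfaceMesh(v, mesh.faces.copy()), transform


# -- disclosed image -------------------------------------------------------


def render_disclosed_image(
    t0_mesh: SurfaceMesh,
    gt: GroundTruth,
    spec: SyntheticSpec,
    rng: np.random.Generator | None = None,
) -> tuple[DisclosedImage, np.ndarray]:
    """Orthographic two-tone disclosed-plaque render with truth class masks.

    Covered regions are pink, the mature sub-region purple, clean enamel
    pale yellow-white; additive Gaussian pixel noise emulates screenshot
    grain. Returns the image and the per-pixel ground-truth class raster.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    pspec = ProjectionSpec.for_roi(t0_mesh, pixel_size=spec.image_pixel_size)
    cov_r, mask, _ = rasterize(t0_mesh, gt.vertex_covered.astype(float), pspec)
    dark_r, _, _ = rasterize(t0_mesh, gt.vertex_dark.astype(float), pspec)

    truth = np.full(mask.shape, CLASS_NON_PLAQUE, dtype=np.uint8)
    truth[mask & (np.nan_to_num(cov_r) >= 0.5)] = CLASS_LIGHT_PINK
    truth[mask & (np.nan_to_num(dark_r) >= 0.5)] = CLASS_DARK_PURPLE

    img = np.empty((*mask.shape, 3), dtype=float)
    img[:] = (30, 30, 30)  # background outside ROI
    img[truth == CLASS_NON_PLAQUE] = COLOR_TOOTH
    img[~mask] = (30, 30, 30)
    img[truth == CLASS_LIGHT_PINK] = COLOR_PINK
    img[truth == CLASS_DARK_PURPLE] = COLOR_PURPLE
    if spec.image_noise_sd > 0:
        img = img + rng.normal(0, spec.image_noise_sd, size=img.shape)
    rgb = np.clip(img, 0, 255).astype(np.uint8)
    return DisclosedImage(rgb=rgb, roi_pixel_mask=mask, tooth_id=None), truth


def labels_from_truth(
    truth: np.ndarray, mask: np.ndarray, rng: np.random.Generator, n_per_class: int = 300
) -> np.ndarray:
    """Sparse annotation raster sampled from truth (-1 = unannotated)."""
    lab = -np.ones(truth.shape, dtype=np.int16)
    for c in (CLASS_NON_PLAQUE, CLASS_LIGHT_PINK, CLASS_DARK_PURPLE):
        ii, jj = np.nonzero((truth == c) & mask)
        if len(ii) == 0:
            continue
        pick = rng.choice(len(ii), size=min(n_per_class, len(ii)), replace=False)
        lab[ii[pick], jj[pick]] = c
    return lab


# -- cohort ----------------------------------------------------------------

#: Turesky band thresholds on covered area fraction: 0 none; 1 flecks;
#: 2 thin continuous band (<= 1 mm); 3 band wider than 1 mm but < 1/3 of
#: the surface; 4 between 1/3 and 2/3; 5 more than 2/3.
TURESKY_BANDS = (0.005, 0.05, 0.10, 1 / 3, 2 / 3)


def turesky_score(coverage_fraction: float) -> int:
    return int(np.searchsorted(TURESKY_BANDS, coverage_fraction, side="right"))


def synth_site_scores(
    coverage_fraction: float, rng: np.random.Generator, ordinal_noise_p: float = 0.1
) -> tuple[int, int, int]:
    """Three TMQHPlI site scores from true coverage.

    Site-level coverage jitters around the surface value (sites see
    different parts of the band) and examiner variability is modelled as
    +-1 ordinal noise with probability ``ordinal_noise_p``.
    """
    scores = []
    for _ in range(3):
        c = np.clip(coverage_fraction * rng.uniform(0.7, 1.3), 0, 1)
        s = turesky_score(float(c))
        if rng.random() < ordinal_noise_p:
            s += rng.choice([-1, 1])
        scores.append(int(np.clip(s, 0, 5)))
    return tuple(scores)  # type: ignore[return-value]


@dataclass
class SyntheticSurface:
    """Everything generated for one tooth surface of one subject."""

    subject_id: str
    tooth_id: str
    spec: SyntheticSpec
    mesh_t0: SurfaceMesh
    roi: ROIMask
    mesh_t4_clean: SurfaceMesh  # plaque added, before scanner corruption
    mesh_t4: SurfaceMesh  # as scanned (noise + pose)
    ground_truth: GroundTruth
    image: DisclosedImage
    truth_classes: np.ndarray
    tdp_sites: tuple[int, int, int]
    ddp_sites: tuple[int, int, int]


def generate_surface(spec: SyntheticSpec, subject_id: str = "S01", tooth_id: str = "11") -> SyntheticSurface:
    """Generate one complete synthetic surface from a spec (reproducible by seed)."""
    rng = np.random.default_rng(spec.seed)
    mesh_t0, roi = make_crown(spec)
    roi = ROIMask(tooth_id=tooth_id, vertex_ids=roi.vertex_ids, timepoint="T0")
    t4_clean, gt = add_plaque(mesh_t0, roi, spec, rng)
    t4_scanned, transform = corrupt_scan(t4_clean, spec, rng)
    gt.applied_transform = transform
    image, truth = render_disclosed_image(mesh_t0, gt, spec, rng)
    image.tooth_id = tooth_id
    surface_cov = gt.covered_area_fraction
    tdp = synth_site_scores(surface_cov, rng)
    ddp = synth_site_scores(surface_cov * gt.true_dark_fraction, rng)
    return SyntheticSurface(
        subject_id=subject_id,
        tooth_id=tooth_id,
        spec=spec,
        mesh_t0=mesh_t0,
        roi=roi,
        mesh_t4_clean=t4_clean,
        mesh_t4=t4_scanned,
        ground_truth=gt,
        image=image,
        truth_classes=truth,
        tdp_sites=tdp,
        ddp_sites=ddp,
    )


def generate_cohort(
    n_subjects: int = 15,
    teeth_per_subject: int = 8,
    seed: int = 0,
    base_spec: SyntheticSpec | None = None,
) -> list[SyntheticSurface]:
    """A full synthetic study: subjects x maxillary buccal surfaces.

    Coverage is drawn uniformly over 5-95% (the study saw 4-96% total
    coverage); the mature fraction grows once coverage exceeds one third,
    and mature plaque is twice as thick, reproducing the regime in which
    early growth is lateral spread and later growth vertical thickening.
    """
    from .io import MAXILLARY_ANALYSIS_TEETH

    base = base_spec or SyntheticSpec(edge_length=0.25)
    root = np.random.default_rng(seed)
    surfaces = []
    teeth = MAXILLARY_ANALYSIS_TEETH[:teeth_per_subject]
    for si in range(n_subjects):
        for tooth in teeth:
            cov = float(root.uniform(0.05, 0.95))
            maturity = float(np.clip((cov - 0.325) / 0.40, 0.0, 0.8))
            spec = replace(
                base,
                coverage_fraction=cov,
                maturity_fraction=maturity,
                max_thickness=float(root.uniform(0.08, 0.18)),
                scan_noise_sd=0.005,
                pose_rotation_deg=float(root.uniform(0.5, 3.0)),
                pose_translation_mm=float(root.uniform(0.2, 1.0)),
                seed=int(root.integers(2**31)),
            )
            surfaces.append(generate_surface(spec, subject_id=f"S{si + 1:02d}", tooth_id=tooth))
    return surfaces


def make_breakpoint_records(
    n: int = 150,
    seed: int = 0,
    breakpoint_pct: float = 32.5,
    slope_below: float = 0.01,
    slope_ratio: float = 2.0,
    noise_sd: float = 0.05,
) -> "np.recarray":
    """Record-level two-segment cohort: VPI piecewise-linear in coverage.

    Coverage spans 4-96%; below the breakpoint volume grows at
    ``slope_below`` mm^3 per coverage point, above at ``slope_ratio``
    times that, plus Gaussian noise. Used to validate breakpoint recovery.
    """
    rng = np.random.default_rng(seed)
    cov = rng.uniform(4, 96, size=n)
    slope_above = slope_ratio * slope_below
    vpi = slope_below * np.minimum(cov, breakpoint_pct) + slope_above * np.maximum(cov - breakpoint_pct, 0)
    vpi = vpi + rng.normal(0, noise_sd, size=n)
    out = np.recarray(n, dtype=[("plani_tot", float), ("vpi", float)])
    out.plani_tot = cov
    out.vpi = vpi
    return out
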