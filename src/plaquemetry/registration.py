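"""Rigid superimposition of sequential scans.

The day-4 (T4, plaque-bearing) scan is always moved into the baseline
(T0, clean) frame so that de-novo deposit appears as positive deviation
along the T0 outward normals. Alignment is two-stage:

1. :func:`pre_align` — coarse: centroids matched, principal axes matched,
   the four proper-rotation sign choices disambiguated by nearest-point RMS.
2. :func:`best_fit_roi` — fine: fraction-trimmed point-to-plane ICP with
   symmetric correspondences, capped at 1 mm. Trimming (keep the best
   ``trim_fraction`` of correspondences) lets the clean geometry anchor the
   fit even when part of the ROI carries a one-sided plaque offset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .core import SurfaceMesh, SurfaceQuery, ValidationError

log = logging.getLogger(__name__)

CORRESPONDENCE_CAP_MM = 1.0
MIN_CORRESPONDENCES = 50


@dataclass
class RigidTransform:
    """Proper rigid motion x -> R x + t (mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=np.float64)
        self.translation = np.asarray(self.translation, dtype=np.float64)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ValidationError("rotation must be 3x3, translation length 3")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-9):
            raise ValidationError("rotation not orthonormal")
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-9:
            raise ValidationError("rotation determinant must be +1")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return RigidTransform(self.rotation @ other.rotation, self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def as_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "RigidTransform":
        m = np.asarray(m, dtype=float)
        return cls(m[:3, :3], m[:3, 3])


@dataclass
class AlignmentReport:
    """Outcome of a best-fit superimposition, measured on the trimmed inlier set."""

    transform: RigidTransform
    mean_abs_distance: float
    sd_distance: float
    inlier_fraction: float
    iterations: int
    converged: bool = True

    def __post_init__(self) -> None:
        if self.mean_abs_distance < 0:
            raise ValidationError("mean_abs_distance must be >= 0")
        if not (0 < self.inlier_fraction <= 1):
            raise ValidationError("inlier_fraction must be in (0, 1]")


def _orthonormal_axes(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Centroid, eigenvalues and right-handed principal axes of a point cloud."""
    c = points.mean(axis=0)
    cov = np.cov((points - c).T)
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    if np.linalg.det(v) < 0:
        v[:, 2] *= -1
    return c, w, v


def pre_align(mesh_t4: SurfaceMesh, mesh_t0: SurfaceMesh, n_samples: int = 500) -> RigidTransform:
    """Coarse transform mapping the T4 mesh into the T0 frame.

    Centroids are aligned and principal axes matched; the four proper
    sign choices for the axes are disambiguated by the smallest RMS
    nearest-vertex distance after rotation. Degenerate principal axes
    (two equal covariance eigenvalues) fall back to centroid-only
    alignment with a warning.
    """
    if mesh_t0.n_vertices == 0 or mesh_t4.n_vertices == 0:
        raise ValidationError("cannot pre-align empty meshes")
    c4, w4, v4 = _orthonormal_axes(mesh_t4.vertices)
    c0, w0, v0 = _orthonormal_axes(mesh_t0.vertices)
    def _degenerate(w: np.ndarray) -> bool:
        return bool((np.abs(np.diff(np.sort(w))) < 1e-9 * max(w.max(), 1e-30)).any())

    if _degenerate(w0) or _degenerate(w4):
        log.warning("degenerate principal axes; falling back to centroid-only pre-alignment")
        return RigidTransform(np.eye(3), c0 - c4)

    rng = np.random.default_rng(0)
    idx = rng.choice(mesh_t4.n_vertices, size=min(n_samples, mesh_t4.n_vertices), replace=False)
    sample = mesh_t4.vertices[idx]
    tree = cKDTree(mesh_t0.vertices)

    best: RigidTransform | None = None
    best_rms = np.inf
    for sx, sy in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
        signs = np.array([sx, sy, sx * sy])  # keeps det(R) = +1
        r = v0 @ np.diag(signs) @ v4.T
        t = c0 - r @ c4
        cand = RigidTransform(r, t)
        d, _ = tree.query(cand.apply(sample))
        rms = float(np.sqrt(np.mean(d**2)))
        if rms < best_rms:
            best_rms, best = rms, cand
    assert best is not None
    return best


def _point_to_plane_step(src: np.ndarray, dst: np.ndarray, normals: np.ndarray) -> RigidTransform:
    """One linearized point-to-plane least-squares solve (small-angle)."""
    b = np.einsum("ij,ij->i", dst - src, normals)
    a = np.hstack([np.cross(src, normals), normals])
    x, *_ = np.linalg.lstsq(a, b, rcond=None)
    omega, t = x[:3], x[3:]
    theta = np.linalg.norm(omega)
    if theta < 1e-30:
        r = np.eye(3)
    else:
        k = omega / theta
        kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
        r = np.eye(3) + np.sin(theta) * kx + (1 - np.cos(theta)) * (kx @ kx)
    # re-orthonormalize against drift
    u, _, vt = np.linalg.svd(r)
    r = u @ vt
    if np.linalg.det(r) < 0:
        u[:, 2] *= -1
        r = u @ vt
    return RigidTransform(r, t)


def _correspondences(
    moved_t4_vertices: np.ndarray,
    t4_vertices: np.ndarray,
    q0: SurfaceQuery,
    t0_vertices: np.ndarray,
    t0_vertex_normals: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Symmetric correspondence set as (p in T4 frame, q in T0 frame, n in T0 frame).

    Forward: each moved T4 vertex to its nearest point on the T0 surface,
    with the T0 face normal. Backward: each T0 vertex to its nearest moved
    T4 vertex, with the T0 vertex normal. Pairs farther than the 1 mm cap
    are rejected. Returns (p, q, n, total_before_cap).
    """
    cp, fi, dist = q0.closest(moved_t4_vertices)
    keep_f = dist <= CORRESPONDENCE_CAP_MM
    face_normals = q0.mesh.face_normals()
    p_f = t4_vertices[keep_f]
    q_f = cp[keep_f]
    n_f = face_normals[fi[keep_f]]

    tree4 = cKDTree(moved_t4_vertices)
    d_b, j_b = tree4.query(t0_vertices)
    keep_b = d_b <= CORRESPONDENCE_CAP_MM
    p_b = t4_vertices[j_b[keep_b]]
    q_b = t0_vertices[keep_b]
    n_b = t0_vertex_normals[keep_b]

    total = len(moved_t4_vertices) + len(t0_vertices)
    return (
        np.vstack([p_f, p_b]),
        np.vstack([q_f, q_b]),
        np.vstack([n_f, n_b]),
        total,
    )


def best_fit_roi(
    roi_t4: SurfaceMesh,
    roi_t0: SurfaceMesh,
    init: RigidTransform | None = None,
    trim_fraction: float = 0.6,
    max_iterations: int = 100,
    tol_mm: float = 1e-6,
) -> AlignmentReport:
    """Trimmed symmetric point-to-plane ICP of a T4 ROI onto its T0 ROI.

    ``trim_fraction`` is the fraction of correspondences *kept* (those with
    the smallest absolute point-to-plane residuals); plaque-covered regions
    are one-sided positive offsets and end up in the discarded tail, so the
    clean T0 geometry anchors the fit. Iterates until the trimmed mean
    absolute distance changes by less than ``tol_mm`` or ``max_iterations``
    is reached; a non-converged run returns its best iterate flagged.
    """
    if not (0 < trim_fraction <= 1):
        raise ValidationError("trim_fraction must be in (0, 1]")
    if init is None:
        init = RigidTransform.identity()
    q0 = SurfaceQuery(roi_t0)
    t0_normals = roi_t0.vertex_normals()

    transform = init
    best_transform = init
    best_mad = np.inf
    prev_mad = np.inf
    mad = np.inf
    sd = 0.0
    inlier_fraction = 1.0
    converged = False
    it = 0

    anneal_iters = 10  # trim anneals 1.0 -> trim_fraction over the first iterations

    for it in range(1, max_iterations + 1):
        moved = transform.apply(roi_t4.vertices)
        p, q, n, total = _correspondences(moved, roi_t4.vertices, q0, roi_t0.vertices, t0_normals)
        if len(p) < MIN_CORRESPONDENCES:
            raise ValidationError(
                f"only {len(p)} correspondences under the {CORRESPONDENCE_CAP_MM} mm cap "
                f"(need >= {MIN_CORRESPONDENCES})"
            )
        moved_p = transform.apply(p)
        res = np.einsum("ij,ij->i", q - moved_p, n)
        # graduated trimming: hard trimming from the start can lock into a
        # mixed clean/deposit equilibrium; annealing the kept fraction lets
        # the fit settle on the majority (clean) mode first
        frac = 1.0 - (1.0 - trim_fraction) * min(1.0, it / anneal_iters)
        n_keep = max(MIN_CORRESPONDENCES, int(np.ceil(frac * len(res))))
        n_keep = min(n_keep, len(res))
        # deposit is a one-sided negative residual (T4 outside T0), so the
        # upper residual half is plaque-free: estimate the noise scale there
        # and reject correspondences far below the median before trimming —
        # otherwise thin deposit margins can balance the clean mode into a
        # biased equilibrium
        med = float(np.median(res))
        upper = res[res >= med] - med
        sigma = 1.4826 * float(np.median(upper)) if len(upper) > 10 else np.inf
        keep = res >= med - 3.0 * max(sigma, tol_mm)
        idx = np.nonzero(keep)[0]
        order = idx[np.argsort(np.abs(res[idx]))]
        inliers = order[: min(n_keep, len(order))]
        mad = float(np.mean(np.abs(res[inliers])))
        sd = float(np.std(res[inliers]))
        inlier_fraction = n_keep / total
        if it > anneal_iters:  # MADs at different trim levels are not comparable
            if mad < best_mad:
                best_mad, best_transform = mad, transform
            if abs(prev_mad - mad) < tol_mm:
                converged = True
                break
            prev_mad = mad
        step = _point_to_plane_step(moved_p[inliers], q[inliers], n[inliers])
        transform = step.compose(transform)

    if not converged:
        log.warning("ICP did not converge in %d iterations (trimmed MAD %.3g mm)", max_iterations, best_mad)
        transform = best_transform
        mad = best_mad
    return AlignmentReport(
        transform=transform,
        mean_abs_distance=mad,
        sd_distance=sd,
        inlier_fraction=float(np.clip(inlier_fraction, 1e-12, 1.0)),
        iterations=it,
        converged=converged,
    )
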