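"""Core mesh container and surface geometry primitives.

All coordinates are in millimetres throughout the package (intraoral
scanners export mm); there is no unit auto-detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


@dataclass
class SurfaceMesh:
    """Triangulated scan surface.

    Parameters
    ----------
    vertices : (n, 3) float array, mm
    faces : (m, 3) int array of vertex indices
    colors : optional (n, 3) uint8 per-vertex RGB
    """

    vertices: np.ndarray
    faces: np.ndarray
    colors: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValidationError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValidationError("faces must be (m, 3)")
        if not np.all(np.isfinite(self.vertices)):
            raise ValidationError("non-finite vertex coordinates")
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise ValidationError("face index out of range")
        if self.faces.size and self.faces.min() < 0:
            raise ValidationError("negative face index")

    # -- derived quantities ------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def triangles(self) -> np.ndarray:
        """(m, 3, 3) triangle corner coordinates."""
        return self.vertices[self.faces]

    def face_areas(self) -> np.ndarray:
        t = self.triangles()
        cross = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])
        return 0.5 * np.linalg.norm(cross, axis=1)

    def area(self) -> float:
        return float(self.face_areas().sum())

    def face_normals(self) -> np.ndarray:
        t = self.triangles()
        cross = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])
        norm = np.linalg.norm(cross, axis=1)
        norm[norm == 0] = 1.0
        return cross / norm[:, None]

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted average of incident face normals, unit length."""
        t = self.triangles()
        cross = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])  # 2*area*normal
        vn = np.zeros_like(self.vertices)
        for k in range(3):
            np.add.at(vn, self.faces[:, k], cross)
        norm = np.linalg.norm(vn, axis=1)
        norm[norm == 0] = 1.0
        return vn / norm[:, None]

    def vertex_areas(self) -> np.ndarray:
        """Barycentric-lumped vertex areas: one third of incident triangle areas.

        Sums exactly to the total surface area.
        """
        fa = self.face_areas()
        va = np.zeros(self.n_vertices)
        for k in range(3):
            np.add.at(va, self.faces[:, k], fa / 3.0)
        return va

    def submesh(self, vertex_ids: np.ndarray) -> tuple["SurfaceMesh", np.ndarray]:
        """Extract the submesh induced by a vertex subset.

        Keeps faces whose three corners all lie in ``vertex_ids``.
        Returns the submesh and the original indices of its vertices
        (position i of the map is the parent index of submesh vertex i).
        """
        vertex_ids = np.asarray(vertex_ids, dtype=np.int64)
        keep = np.zeros(self.n_vertices, dtype=bool)
        keep[vertex_ids] = True
        face_mask = keep[self.faces].all(axis=1)
        faces = self.faces[face_mask]
        used = np.unique(faces) if faces.size else np.array([], dtype=np.int64)
        remap = -np.ones(self.n_vertices, dtype=np.int64)
        remap[used] = np.arange(len(used))
        sub = SurfaceMesh(
            self.vertices[used],
            remap[faces],
            None if self.colors is None else self.colors[used],
        )
        return sub, used

    def vertex_adjacency(self) -> list[set[int]]:
        adj: list[set[int]] = [set() for _ in range(self.n_vertices)]
        for a, b, c in self.faces:
            adj[a].update((b, c))
            adj[b].update((a, c))
            adj[c].update((a, b))
        return adj

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "SurfaceMesh":
        v = self.vertices @ np.asarray(rotation).T + np.asarray(translation)
        return SurfaceMesh(v, self.faces.copy(), self.colors)


# -- point-to-triangle distance -------------------------------------------


def closest_point_on_triangles(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Closest point on each triangle to each query point.

    Vectorized Ericson-style region test.

    Parameters
    ----------
    points : (n, 3)
    tri : (n, 3, 3) one triangle per point

    Returns
    -------
    (n, 3) closest points.
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab = b - a
    ac = c - a
    ap = points - a

    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = points - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = points - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(points)
    done = np.zeros(len(points), dtype=bool)

    # vertex regions
    m = (d1 <= 0) & (d2 <= 0)
    out[m] = a[m]
    done |= m
    m = (~done) & (d3 >= 0) & (d4 <= d3)
    out[m] = b[m]
    done |= m
    m = (~done) & (d6 >= 0) & (d5 <= d6)
    out[m] = c[m]
    done |= m

    # edge AB
    vc = d1 * d4 - d3 * d2
    m = (~done) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    denom = d1[m] - d3[m]
    denom = np.where(denom == 0, 1.0, denom)
    v = d1[m] / denom
    out[m] = a[m] + v[:, None] * ab[m]
    done |= m

    # edge AC
    vb = d5 * d2 - d1 * d6
    m = (~done) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    denom = d2[m] - d6[m]
    denom = np.where(denom == 0, 1.0, denom)
    w = d2[m] / denom
    out[m] = a[m] + w[:, None] * ac[m]
    done |= m

    # edge BC
    va = d3 * d6 - d5 * d4
    m = (~done) & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    denom = (d4[m] - d3[m]) + (d5[m] - d6[m])
    denom = np.where(denom == 0, 1.0, denom)
    w = (d4[m] - d3[m]) / denom
    out[m] = b[m] + w[:, None] * (c[m] - b[m])
    done |= m

    # interior
    m = ~done
    denom = va[m] + vb[m] + vc[m]
    denom = np.where(denom == 0, 1.0, denom)
    v = vb[m] / denom
    w = vc[m] / denom
    out[m] = a[m] + v[:, None] * ab[m] + w[:, None] * ac[m]
    return out


class SurfaceQuery:
    """Nearest-point-on-surface queries against a triangulated mesh.

    Candidate triangles come from a k-d tree over triangle centroids
    (plus all triangles incident to the nearest vertices); the exact
    point-to-triangle distance then selects the minimizer. Exact for
    smooth meshes once the candidate set contains the true nearest
    triangle; ``k`` trades cost against robustness.
    """

    def __init__(self, mesh: SurfaceMesh, k: int = 24):
        if mesh.n_faces == 0:
            raise ValidationError("cannot query an empty mesh")
        self.mesh = mesh
        self.k = min(k, mesh.n_faces)
        self._centroids = mesh.triangles().mean(axis=1)
        self._tree = cKDTree(self._centroids)
        self._vtree = cKDTree(mesh.vertices)
        # faces incident to each vertex, padded to rectangular
        nv = mesh.n_vertices
        counts = np.zeros(nv, dtype=np.int64)
        for kk in range(3):
            np.add.at(counts, mesh.faces[:, kk], 1)
        max_deg = int(counts.max()) if nv else 0
        inc = -np.ones((nv, max_deg), dtype=np.int64)
        cursor = np.zeros(nv, dtype=np.int64)
        for fi, f in enumerate(mesh.faces):
            for v in f:
                inc[v, cursor[v]] = fi
                cursor[v] += 1
        self._incident = inc

    def closest(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (closest_points, face_indices, distances) for query points."""
        points = np.atleast_2d(np.asarray(points, dtype=np.float64))
        _, cand = self._tree.query(points, k=self.k)
        cand = np.asarray(cand).reshape(len(points), -1)
        _, nearest_v = self._vtree.query(points, k=1)
        inc = self._incident[np.atleast_1d(nearest_v)]
        cand = np.concatenate([cand, np.where(inc < 0, cand[:, :1], inc)], axis=1)

        n, kc = cand.shape
        tri = self.mesh.triangles()[cand.reshape(-1)]
        pts = np.repeat(points, kc, axis=0)
        cp = closest_point_on_triangles(pts, tri).reshape(n, kc, 3)
        d2 = np.sum((cp - points[:, None, :]) ** 2, axis=2)
        best = np.argmin(d2, axis=1)
        idx = np.arange(n)
        return (
            cp[idx, best],
            cand[idx, best],
            np.sqrt(d2[idx, best]),
        )


def closest_point_brute_force(points: np.ndarray, mesh: SurfaceMesh) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact nearest point by testing every triangle (test oracle; O(n*m))."""
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    tri = mesh.triangles()
    out_cp = np.empty_like(points)
    out_fi = np.empty(len(points), dtype=np.int64)
    out_d = np.empty(len(points))
    for i, p in enumerate(points):
        cp = closest_point_on_triangles(np.repeat(p[None], len(tri), axis=0), tri)
        d2 = np.sum((cp - p) ** 2, axis=1)
        j = int(np.argmin(d2))
        out_cp[i], out_fi[i], out_d[i] = cp[j], j, np.sqrt(d2[j])
    return out_cp, out_fi, out_d
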