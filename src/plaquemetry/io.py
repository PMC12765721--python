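"""Reading and writing scans, ROIs, images and score tables.

Mesh formats: PLY, STL, OBJ (ASCII and binary where the format has both),
delegated to :mod:`trimesh`. ROIs are JSON documents; TMQHPlI site scores
are long-format CSV. Units are millimetres everywhere.

ROI JSON schema (one document holds a list of ROIs)::

    {"rois": [
        {"tooth_id": "11", "timepoint": "T0", "vertex_ids": [0, 1, ...]},
        {"tooth_id": "12", "timepoint": "T4",
         "boundary_polyline": [5, 9, 13, ...],   # closed edge loop of vertex ids
         "seed_vertex": 42}                       # interior seed for flood fill
    ]}

A polyline ROI is converted to a vertex mask at load time by flood-filling
the mesh vertex graph from the seed without crossing the boundary loop.
"""

from __future__ import annotations

import json
import logging
import warnings
from collections import deque
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .core import SurfaceMesh, ValidationError

log = logging.getLogger(__name__)

#: Buccal surfaces used for analysis by default: maxillary premolars,
#: canines and incisors in FDI two-digit notation (first quadrant 14..11,
#: second quadrant 21..24).
MAXILLARY_ANALYSIS_TEETH = ("14", "13", "12", "11", "21", "22", "23", "24")

TIMEPOINTS = ("T0", "T4")
SITES = ("mesial", "central", "distal")
VARIANTS = ("TDP", "DDP")

MERGE_TOL_MM = 1e-6  # duplicate-vertex merge radius, far below the 0.01 mm detection limit


@dataclass
class ROIMask:
    """Vertex mask delineating one buccal tooth surface on one timepoint's mesh."""

    tooth_id: str
    vertex_ids: np.ndarray
    timepoint: str

    def __post_init__(self) -> None:
        self.vertex_ids = np.asarray(self.vertex_ids, dtype=np.int64)
        if self.timepoint not in TIMEPOINTS:
            raise ValidationError(f"unknown timepoint {self.timepoint!r}")
        if self.vertex_ids.size == 0:
            raise ValidationError("empty ROI mask")
        if len(np.unique(self.vertex_ids)) != len(self.vertex_ids):
            raise ValidationError("duplicate vertex ids in ROI mask")

    def validate_against(self, mesh: SurfaceMesh) -> None:
        if self.vertex_ids.max() >= mesh.n_vertices or self.vertex_ids.min() < 0:
            raise ValidationError("ROI vertex index out of range for mesh")
        sub, _ = mesh.submesh(self.vertex_ids)
        if sub.n_faces == 0:
            raise ValidationError("ROI induces no faces")
        if not _is_edge_connected(sub):
            raise ValidationError(f"ROI {self.tooth_id}@{self.timepoint} is not edge-connected")


@dataclass
class ScanPair:
    """One subject's T0 (clean) and T4 (plaque-bearing) scans with paired ROIs."""

    subject_id: str
    mesh_t0: SurfaceMesh
    mesh_t4: SurfaceMesh
    rois: dict[str, tuple[ROIMask, ROIMask]]  # tooth_id -> (roi@T0, roi@T4)

    def __post_init__(self) -> None:
        for tooth, (r0, r4) in self.rois.items():
            if r0.timepoint != "T0" or r4.timepoint != "T4":
                raise ValidationError(f"ROI pair for tooth {tooth} has wrong timepoints")
            if r0.tooth_id != tooth or r4.tooth_id != tooth:
                raise ValidationError("ROI tooth_id mismatch in pair")


def _is_edge_connected(mesh: SurfaceMesh) -> bool:
    if mesh.n_vertices == 0:
        return False
    used = np.unique(mesh.faces)
    if len(used) < mesh.n_vertices:  # isolated vertices
        return False
    adj = mesh.vertex_adjacency()
    seen = {int(used[0])}
    stack = [int(used[0])]
    while stack:
        v = stack.pop()
        for w in adj[v]:
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return len(seen) == mesh.n_vertices


# -- meshes ----------------------------------------------------------------


def load_mesh(path: str | Path, file_format: str | None = None) -> SurfaceMesh:
    """Load a PLY/STL/OBJ mesh and clean it.

    Cleanup merges duplicate vertices within 1e-6 mm and drops degenerate
    (zero-area) faces; both thresholds sit far below the 0.01 mm plaque
    detection limit so cleanup cannot create apparent plaque.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"mesh file not found: {path}")
    fmt = (file_format or path.suffix.lstrip(".")).lower()
    if fmt not in ("ply", "stl", "obj"):
        raise ValidationError(f"unsupported mesh format {fmt!r}")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tm = trimesh.load(str(path), file_type=fmt, force="mesh", process=False)
    except Exception as exc:  # noqa: BLE001 - normalize loader failures
        raise IOError(f"cannot read {path}: {exc}") from exc
    vertices = np.asarray(tm.vertices, dtype=np.float64)
    faces = np.asarray(tm.faces, dtype=np.int64)
    colors = None
    if hasattr(tm.visual, "vertex_colors") and tm.visual.kind == "vertex":
        colors = np.asarray(tm.visual.vertex_colors)[:, :3].astype(np.uint8)
    mesh = _clean(vertices, faces, colors)
    if mesh.n_faces == 0 or mesh.area() <= 0:
        raise ValidationError(f"mesh {path} empty after cleanup")
    return mesh


def save_mesh(mesh: SurfaceMesh, path: str | Path, scalars: np.ndarray | None = None) -> None:
    """Write a mesh as PLY/STL/OBJ (format from extension).

    ``scalars`` (per-vertex, PLY only) are stored as a grayscale vertex
    colour channel for quick inspection of thickness fields.
    """
    path = Path(path)
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    if mesh.colors is not None:
        tm.visual.vertex_colors = mesh.colors
    if scalars is not None and path.suffix.lower() == ".ply":
        s = np.asarray(scalars, dtype=float)
        rng = s.max() - s.min()
        g = np.zeros_like(s) if rng == 0 else (s - s.min()) / rng
        tm.visual.vertex_colors = np.column_stack([255 * g] * 3).astype(np.uint8)
    tm.export(str(path))


def _clean(vertices: np.ndarray, faces: np.ndarray, colors: np.ndarray | None) -> SurfaceMesh:
    # merge duplicates on a MERGE_TOL grid
    key = np.round(vertices / MERGE_TOL_MM).astype(np.int64)
    _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    vertices = vertices[first]
    colors = colors[first] if colors is not None else None
    faces = inverse[faces]
    # drop faces with repeated indices
    ok = (faces[:, 0] != faces[:, 1]) & (faces[:, 1] != faces[:, 2]) & (faces[:, 0] != faces[:, 2])
    dropped = int((~ok).sum())
    faces = faces[ok]
    mesh = SurfaceMesh(vertices, faces, colors)
    # drop zero-area faces
    areas = mesh.face_areas()
    zero = areas <= 1e-12
    if zero.any():
        dropped += int(zero.sum())
        mesh = SurfaceMesh(vertices, faces[~zero], colors)
    if dropped:
        log.warning("dropped %d degenerate face(s) during mesh cleanup", dropped)
    return mesh


# -- ROIs ------------------------------------------------------------------


def load_roi(path: str | Path, mesh: SurfaceMesh | None = None) -> list[ROIMask]:
    """Load ROI masks from JSON; polyline ROIs require ``mesh`` for flood fill."""
    path = Path(path)
    doc = json.loads(path.read_text())
    out: list[ROIMask] = []
    for entry in doc["rois"]:
        tooth = str(entry["tooth_id"])
        tp = entry.get("timepoint")
        if tp not in TIMEPOINTS:
            raise ValidationError(f"unknown timepoint {tp!r} for tooth {tooth}")
        if "vertex_ids" in entry:
            mask = ROIMask(tooth, np.asarray(entry["vertex_ids"], dtype=np.int64), tp)
        elif "boundary_polyline" in entry:
            if mesh is None:
                raise ValidationError("polyline ROI requires the mesh it refers to")
            ids = polyline_to_mask(
                mesh,
                np.asarray(entry["boundary_polyline"], dtype=np.int64),
                int(entry["seed_vertex"]),
            )
            mask = ROIMask(tooth, ids, tp)
        else:
            raise ValidationError(f"ROI for tooth {tooth} has neither vertex_ids nor boundary_polyline")
        if mesh is not None:
            mask.validate_against(mesh)
        out.append(mask)
    return out


def save_roi(masks: list[ROIMask], path: str | Path) -> None:
    doc = {
        "rois": [
            {
                "tooth_id": m.tooth_id,
                "timepoint": m.timepoint,
                "vertex_ids": [int(v) for v in m.vertex_ids],
            }
            for m in masks
        ]
    }
    Path(path).write_text(json.dumps(doc))


def polyline_to_mask(mesh: SurfaceMesh, polyline: np.ndarray, seed: int) -> np.ndarray:
    """Interior vertices of a closed boundary loop, by graph flood fill.

    The polyline must be a closed loop of mesh vertices in which each
    consecutive pair (and last-to-first) shares a mesh edge. The fill
    starts at ``seed`` and never crosses boundary vertices; the returned
    mask is interior plus boundary.
    """
    adj = mesh.vertex_adjacency()
    poly = [int(v) for v in polyline]
    if len(poly) < 3:
        raise ValidationError("boundary polyline needs at least 3 vertices")
    for a, b in zip(poly, poly[1:] + poly[:1]):
        if b not in adj[a]:
            raise ValidationError(f"polyline not closed: vertices {a} and {b} share no mesh edge")
    boundary = set(poly)
    if seed in boundary:
        raise ValidationError("seed vertex lies on the boundary polyline")
    seen = {seed}
    q = deque([seed])
    while q:
        v = q.popleft()
        for w in adj[v]:
            if w not in seen and w not in boundary:
                seen.add(w)
                q.append(w)
    if len(seen) + len(boundary) >= mesh.n_vertices:
        raise ValidationError("flood fill escaped the polyline (boundary does not enclose the seed)")
    return np.array(sorted(seen | boundary), dtype=np.int64)


# -- score tables ----------------------------------------------------------


def load_scores(path: str | Path) -> pd.DataFrame:
    """Load and validate a long-format TMQHPlI site-score CSV.

    Columns: subject_id, tooth_id, variant in {TDP, DDP}, site in
    {mesial, central, distal}, score in 0..5. Every (subject, tooth,
    variant) must have exactly the three sites. Sites where the dark
    (DDP) score exceeds the total (TDP) score are flagged with a warning
    — dark, mature plaque is by definition a subset of total plaque —
    but kept, since real scoring noise produces such records.
    """
    df = pd.read_csv(path, dtype={"subject_id": str, "tooth_id": str})
    required = {"subject_id", "tooth_id", "variant", "site", "score"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"scores CSV missing columns: {sorted(missing)}")
    if not df["variant"].isin(VARIANTS).all():
        raise ValidationError("variant must be TDP or DDP")
    if not df["site"].isin(SITES).all():
        raise ValidationError("site must be mesial/central/distal")
    if not df["score"].between(0, 5).all() or not (df["score"] == df["score"].astype(int)).all():
        raise ValidationError("scores must be integers in 0..5")
    df["score"] = df["score"].astype(int)
    counts = df.groupby(["subject_id", "tooth_id", "variant"])["site"].agg(["count", "nunique"])
    if not ((counts["count"] == 3) & (counts["nunique"] == 3)).all():
        raise ValidationError("each (subject, tooth, variant) needs exactly the 3 sites")
    wide = df.pivot_table(
        index=["subject_id", "tooth_id", "site"], columns="variant", values="score"
    )
    if {"TDP", "DDP"} <= set(wide.columns):
        bad = wide[wide["DDP"] > wide["TDP"]]
        for idx in bad.index:
            log.warning("DDP score exceeds TDP score at %s (dark plaque should be a subset of total)", idx)
    return df.reset_index(drop=True)
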