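"""Label volumes to triangulated bone surfaces and glenohumeral crops.

Meshes come from the classic marching-cubes algorithm on the binary class
mask (iso-level 0.5, one-voxel zero padding so objects touching the grid
border still close), with vertices in physical mm. The glenohumeral (GH)
region is isolated as a fixed-size crop centred at the midpoint of the
closest boundary-voxel pair between the humerus and the scapula.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import trimesh
from scipy.spatial import cKDTree
from skimage import measure

from .celunet import _class_boundary
from .volumes import LabelVolume, VoxelVolume

__all__ = [
    "SurfaceMesh",
    "GHRegion",
    "reconstruct_mesh",
    "extract_gh_region",
    "closest_boundary_pair",
    "save_stl",
    "load_stl",
]


@dataclass
class SurfaceMesh:
    """Triangulated surface in physical coordinates (mm)."""

    vertices: np.ndarray
    faces: np.ndarray
    class_id: int

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)

    @property
    def is_watertight(self) -> bool:
        return bool(self.as_trimesh().is_watertight)

    @property
    def euler_characteristic(self) -> int:
        m = self.as_trimesh()
        return int(len(m.vertices) - len(m.edges_unique) + len(m.faces))

    @property
    def volume_mm3(self) -> float:
        return float(abs(self.as_trimesh().volume))


@dataclass
class GHRegion:
    origin_voxel: tuple[int, int, int]
    size_voxels: tuple[int, int, int]
    image_crop: VoxelVolume
    labels_crop: LabelVolume | None = None


def reconstruct_mesh(
    labels: LabelVolume | np.ndarray,
    spacing: tuple[float, float, float] | None = None,
    class_id: int = 1,
    iso_level: float = 0.5,
) -> SurfaceMesh:
    """Marching-cubes surface of one class, vertices in mm, outward normals."""
    arr = labels.data if isinstance(labels, LabelVolume) else np.asarray(labels)
    if spacing is None:
        spacing = labels.spacing if isinstance(labels, LabelVolume) else (1.0, 1.0, 1.0)
    mask = arr == class_id
    if not mask.any():
        raise ValueError(f"class {class_id} absent from label volume")
    padded = np.pad(mask.astype(np.float64), 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=iso_level, spacing=spacing)
    verts = verts - np.asarray(spacing)  # undo the one-voxel pad
    return SurfaceMesh(vertices=verts, faces=faces, class_id=class_id)


def closest_boundary_pair(
    labels: LabelVolume | np.ndarray, class_a: int = 1, class_b: int = 2
) -> tuple[tuple[int, int, int], tuple[int, int, int], float]:
    """Closest pair of boundary voxels between two classes (voxel units).

    Ties are broken toward the lexicographically smallest (a, b) index pair.
    """
    arr = labels.data if isinstance(labels, LabelVolume) else np.asarray(labels)
    pts = {}
    for c in (class_a, class_b):
        mask = arr == c
        if not mask.any():
            raise ValueError(f"class {c} absent from label volume")
        pts[c] = np.argwhere(_class_boundary(mask))
    tree = cKDTree(pts[class_b])
    dists, idx = tree.query(pts[class_a])
    dmin = dists.min()
    cand_a = pts[class_a][dists <= dmin + 1e-9]
    best = None
    for a in cand_a:
        for j in tree.query_ball_point(a, dmin + 1e-9):
            b = pts[class_b][j]
            key = (tuple(a), tuple(b))
            if best is None or key < best:
                best = key
    a, b = best
    return tuple(int(v) for v in a), tuple(int(v) for v in b), float(dmin)


def extract_gh_region(
    labels: LabelVolume,
    image: VoxelVolume | None = None,
    crop_size_mm: float = 64.0,
) -> GHRegion:
    """Crop centred at the humerus-scapula closest-approach midpoint.

    The crop size is fixed in mm (so the classifier input is constant in
    physical extent), clamped to the parent grid.
    """
    a, b, _ = closest_boundary_pair(labels, 1, 2)
    center = tuple((np.asarray(a) + np.asarray(b)) // 2)
    spacing = np.asarray(labels.spacing)
    shape = np.asarray(labels.shape)
    size = np.minimum(np.rint(crop_size_mm / spacing).astype(int), shape)
    size = np.maximum(size, 1)
    origin = np.clip(np.asarray(center) - size // 2, 0, shape - size)
    sl = tuple(slice(o, o + s) for o, s in zip(origin, size))
    src = image.data if image is not None else labels.data.astype(np.float64)
    region = GHRegion(
        origin_voxel=tuple(int(o) for o in origin),
        size_voxels=tuple(int(s) for s in size),
        image_crop=VoxelVolume(src[sl], labels.spacing),
        labels_crop=LabelVolume(labels.data[sl], labels.spacing),
    )
    lab = region.labels_crop.data
    if not ((lab == 1).any() and (lab == 2).any()):
        raise ValueError("GH crop does not contain both bone classes")
    return region


def save_stl(mesh: SurfaceMesh, path: str | Path) -> None:
    mesh.as_trimesh().export(str(path), file_type="stl")


def load_stl(path: str | Path, class_id: int = 0) -> SurfaceMesh:
    m = trimesh.load(str(path), file_type="stl", process=False)
    return SurfaceMesh(vertices=np.asarray(m.vertices), faces=np.asarray(m.faces),
                       class_id=class_id)
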