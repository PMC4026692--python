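"""Reading, writing and validation of on-disk artifacts.

The pipeline's inputs are binary structure segmentations (NIfTI), surface
meshes in vertex correspondence (PLY/OBJ, correspondence implied by vertex
order), and a cohort table (CSV) carrying diagnostic labels and intracranial
volumes.  Everything is validated into small domain types at the boundary so
the numerical modules can assume well-formed data.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import nibabel as nib
import numpy as np
import pandas as pd
import trimesh

DEFAULT_CLASSES = ("NC", "AD", "FTD")

__all__ = [
    "BinaryMask",
    "SurfaceMesh",
    "CohortTable",
    "read_mask",
    "write_mask",
    "read_mesh",
    "write_mesh",
    "read_cohort",
    "DEFAULT_CLASSES",
]


@dataclass(frozen=True)
class BinaryMask:
    """A voxelized structure segmentation.

    Parameters
    ----------
    voxels
        3D uint8 array containing only 0/1; at least one foreground voxel.
    spacing
        Voxel edge lengths ``(dx, dy, dz)`` in mm, all strictly positive.
    origin
        World-space offset of voxel (0,0,0) in mm.  World coordinates are
        ``index * spacing + origin`` in the array's native axis order.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        if v.ndim != 3:
            raise ValueError(f"mask must be 3D, got {v.ndim}D")
        vals = np.unique(v)
        if not np.isin(vals, [0, 1]).all():
            raise ValueError("mask voxels must contain only 0/1")
        if v.sum() == 0:
            raise ValueError("empty segmentation")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        object.__setattr__(self, "voxels", v.astype(np.uint8))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def n_foreground(self) -> int:
        return int(self.voxels.sum())

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm³."""
        dx, dy, dz = self.spacing
        return dx * dy * dz


@dataclass(frozen=True)
class SurfaceMesh:
    """A triangle mesh; correspondence between meshes is carried by vertex order."""

    vertices: np.ndarray  # (n, 3) float, mm
    faces: np.ndarray  # (m, 3) int

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        f = np.asarray(self.faces, dtype=np.int64)
        if v.ndim != 2 or v.shape[1] != 3 or v.shape[0] < 4:
            raise ValueError("mesh needs an (n>=4, 3) vertex array")
        if f.ndim != 2 or f.shape[1] != 3:
            raise ValueError("faces must be triangle index triples")
        if f.size and (f.min() < 0 or f.max() >= len(v)):
            raise ValueError("face index out of range")
        if f.size and ((f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])).any():
            raise ValueError("degenerate (repeated-index) triangle")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted outward vertex normals (unit length)."""
        tm = trimesh.Trimesh(self.vertices, self.faces, process=False)
        n = np.asarray(tm.vertex_normals, dtype=float)
        return n / np.linalg.norm(n, axis=1, keepdims=True)


@dataclass
class CohortTable:
    """Subjects with diagnostic labels, ICV and per-structure file paths.

    ``table`` has columns ``subject_id``, ``group``, ``icv`` plus any number
    of path columns (one per structure/artifact).
    """

    table: pd.DataFrame
    class_names: tuple[str, ...] = DEFAULT_CLASSES

    def __post_init__(self) -> None:
        t = self.table
        for col in ("subject_id", "group", "icv"):
            if col not in t.columns:
                raise ValueError(f"cohort table missing required column {col!r}")
        if t["subject_id"].duplicated().any():
            dup = t.loc[t["subject_id"].duplicated(), "subject_id"].tolist()
            raise ValueError(f"duplicate subject_id(s): {dup}")
        unknown = set(t["group"]) - set(self.class_names)
        if unknown:
            raise ValueError(
                f"unknown group label(s) {sorted(unknown)}; allowed: {list(self.class_names)}"
            )
        if (t["icv"] <= 0).any():
            bad = t.loc[t["icv"] <= 0, "subject_id"].tolist()
            raise ValueError(f"nonpositive ICV for subject(s): {bad}")

    @property
    def subject_ids(self) -> list[str]:
        return self.table["subject_id"].tolist()

    @property
    def labels(self) -> pd.Series:
        return self.table.set_index("subject_id")["group"]

    def __len__(self) -> int:
        return len(self.table)


def read_mask(path: str | os.PathLike) -> BinaryMask:
    """Load a NIfTI segmentation and binarize it (any nonzero label = foreground)."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected a 3D image, got shape {data.shape}")
    voxels = (data != 0).astype(np.uint8)
    if voxels.sum() == 0:
        raise ValueError("empty segmentation")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(x) for x in img.affine[:3, 3])
    return BinaryMask(voxels=voxels, spacing=spacing, origin=origin)


def write_mask(mask: BinaryMask, path: str | os.PathLike) -> None:
    affine = np.diag(list(mask.spacing) + [1.0])
    affine[:3, 3] = mask.origin
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), affine)
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


def _check_triangle_faces(path: str) -> None:
    """Reject non-triangle faces in text formats before trimesh triangulates them."""
    lower = path.lower()
    if lower.endswith(".obj"):
        with open(path) as fh:
            for line in fh:
                if line.startswith("f ") and len(line.split()) - 1 != 3:
                    raise ValueError(f"non-triangle face in {path}")
    elif lower.endswith(".ply"):
        with open(path, "rb") as fh:
            header = fh.read(4096)
        if b"format ascii" in header:
            with open(path) as fh:
                lines = fh.read().splitlines()
            end = lines.index("end_header")
            n_vert = n_face = 0
            for ln in lines[:end]:
                parts = ln.split()
                if parts[:2] == ["element", "vertex"]:
                    n_vert = int(parts[2])
                elif parts[:2] == ["element", "face"]:
                    n_face = int(parts[2])
            for ln in lines[end + 1 + n_vert : end + 1 + n_vert + n_face]:
                if ln.split() and int(ln.split()[0]) != 3:
                    raise ValueError(f"non-triangle face in {path}")


def read_mesh(path: str | os.PathLike) -> SurfaceMesh:
    """Load a PLY or OBJ triangle mesh, preserving vertex order."""
    path = str(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    _check_triangle_faces(path)
    loaded = trimesh.load(path, process=False, force="mesh")
    vertices = np.asarray(loaded.vertices, dtype=float)
    faces = np.asarray(loaded.faces, dtype=np.int64)
    if len(vertices) == 0:
        raise ValueError(f"no vertices in {path}")
    return SurfaceMesh(vertices=vertices, faces=faces)


def write_mesh(mesh: SurfaceMesh, path: str | os.PathLike) -> None:
    tm = trimesh.Trimesh(mesh.vertices, mesh.faces, process=False)
    tm.export(str(path))


def read_cohort(
    path: str | os.PathLike, class_names: tuple[str, ...] = DEFAULT_CLASSES
) -> CohortTable:
    """Read and validate the cohort CSV (subject_id, group, icv, path columns)."""
    table = pd.read_csv(path)
    table["subject_id"] = table["subject_id"].astype(str)
    return CohortTable(table=table, class_names=class_names)
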