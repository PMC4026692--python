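"""Synthetic three-group shape cohort generator.

Emulates the statistical regime of a dementia differential-diagnosis cohort
(normal controls, an AD-like group, an FTD-like group) with a single generic
subcortical structure, so every pipeline stage is exercisable without any
imaging data:

* a shared template — an ellipsoid mesh — gives every subject exact vertex
  correspondence by construction, standing in for diffeomorphic template
  injection;
* per-subject global size variation makes the group volume distributions
  overlap (gross atrophy alone cannot separate the disease groups; the
  AD-like and FTD-like volume distributions are identical by design);
* each disease group receives a smooth focal radial bump at a group-specific
  pole of the long axis — posterior for the AD-like group, anterior for the
  FTD-like group — so local surface displacement carries the discriminating
  signal, while the mirror symmetry of the two loci keeps the intrinsic
  (spectral) shape of the two disease groups nearly identical;
* ICV is drawn so that structure volume correlates with head size at a
  configurable slope, exercising the ICV normalization.

Shapes are star-convex by construction: the surface radius along a unit
direction u is ``rho(u) = s * r_E(u) + A * exp(-theta(u)^2 / (2 sigma^2))``
with r_E the ellipsoid radius, s the subject's size factor, A the bump
amplitude and theta the angle to the group's bump locus.  Voxelization
therefore reduces to an exact point-in-shape test on the grid, and the mesh
and the mask describe the same surface.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh

from .io import BinaryMask, CohortTable, SurfaceMesh, write_mask, write_mesh

__all__ = ["CohortSpec", "SyntheticSubject", "SyntheticCohort",
           "template_mesh", "generate_subject", "generate_cohort"]


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for the synthetic cohort.

    Defaults encode a 78-subject three-group cohort (NC=14, AD=34, FTD=30)
    on a ventricle-scale elongated ellipsoid.
    """

    group_sizes: dict = field(
        default_factory=lambda: {"NC": 14, "AD": 34, "FTD": 30}
    )
    semi_axes: tuple[float, float, float] = (22.0, 12.0, 9.0)  # mm
    #: multiplicative group volume means (both disease groups enlarged alike)
    volume_multiplier: dict = field(
        default_factory=lambda: {"NC": 1.00, "AD": 1.10, "FTD": 1.10}
    )
    volume_noise_sd: float = 0.12  # multiplicative SD of subject volume
    bump_amplitude: dict = field(
        default_factory=lambda: {"NC": 0.0, "AD": 2.0, "FTD": 2.0}
    )  # mm at the locus pole
    bump_sigma: float = 0.25  # angular Gaussian width, rad
    #: bump locus as a unit direction; AD posterior (-x), FTD anterior (+x)
    bump_locus: dict = field(
        default_factory=lambda: {"AD": (-1.0, 0.0, 0.0), "FTD": (1.0, 0.0, 0.0)}
    )
    jitter_sd: float = 0.05  # per-vertex iid noise, mm
    mesh_subdivisions: int = 4  # icosphere level: 4 -> 2562 vertices
    voxel_spacing: float = 1.0  # mm, isotropic
    icv_mean: float = 1.45e6  # mm^3
    icv_sd: float = 1.5e5
    icv_slope: float = 0.003  # structure mm^3 per ICV mm^3
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 2 for n in self.group_sizes.values()):
            raise ValueError("every group needs >= 2 subjects")
        if any(a < 0 for a in self.bump_amplitude.values()):
            raise ValueError("bump amplitudes must be >= 0")
        if self.voxel_spacing <= 0:
            raise ValueError("voxel spacing must be positive")


@dataclass
class SyntheticSubject:
    subject_id: str
    group: str
    mask: BinaryMask
    mesh: SurfaceMesh
    icv: float
    truth: dict  # ground-truth generator parameters for recovery tests


@dataclass
class SyntheticCohort:
    spec: CohortSpec
    template: SurfaceMesh
    subjects: list[SyntheticSubject]

    @property
    def cohort_table(self) -> CohortTable:
        rows = [{"subject_id": s.subject_id, "group": s.group, "icv": s.icv}
                for s in self.subjects]
        return CohortTable(pd.DataFrame(rows))

    @property
    def labels(self) -> pd.Series:
        return pd.Series({s.subject_id: s.group for s in self.subjects},
                         name="group")

    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame([{"subject_id": s.subject_id, "group": s.group,
                              "icv": s.icv, **s.truth} for s in self.subjects])


def _ellipsoid_radius(directions: np.ndarray, semi_axes) -> np.ndarray:
    """Radius of the ellipsoid along unit direction(s): t with t*d on the surface."""
    a = np.asarray(semi_axes, dtype=float)
    return 1.0 / np.sqrt(((directions / a) ** 2).sum(axis=-1))


def template_mesh(spec: CohortSpec) -> SurfaceMesh:
    """The shared template: an icosphere mapped radially onto the ellipsoid."""
    ico = trimesh.creation.icosphere(subdivisions=spec.mesh_subdivisions, radius=1.0)
    dirs = np.asarray(ico.vertices, dtype=float)
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    verts = dirs * _ellipsoid_radius(dirs, spec.semi_axes)[:, None]
    return SurfaceMesh(vertices=verts, faces=np.asarray(ico.faces, dtype=np.int64))


def _radius_function(spec: CohortSpec, group: str, scale: float, amplitude: float):
    locus = spec.bump_locus.get(group)
    locus = None if locus is None or amplitude == 0 else np.asarray(locus, float)

    def rho(directions: np.ndarray) -> np.ndarray:
        r = scale * _ellipsoid_radius(directions, spec.semi_axes)
        if locus is not None:
            cosang = np.clip(directions @ locus, -1.0, 1.0)
            theta = np.arccos(cosang)
            r = r + amplitude * np.exp(-(theta**2) / (2.0 * spec.bump_sigma**2))
        return r

    return rho


def _voxelize(rho, spec: CohortSpec) -> BinaryMask:
    """Exact star-convex voxelization: voxel center in iff |p| <= rho(p/|p|)."""
    h = spec.voxel_spacing
    max_r = max(spec.semi_axes) * 1.6 + max(spec.bump_amplitude.values()) + 2 * h
    n = int(np.ceil(2 * max_r / h)) + 1
    coords = (np.arange(n) - (n - 1) / 2.0) * h
    X, Y, Z = np.meshgrid(coords, coords, coords, indexing="ij")
    P = np.stack([X, Y, Z], axis=-1)
    dist = np.linalg.norm(P, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        dirs = P / dist[..., None]
    dirs[dist == 0] = (1.0, 0.0, 0.0)
    inside = dist <= rho(dirs)
    origin = tuple(coords[0] for _ in range(3))
    return BinaryMask(voxels=inside.astype(np.uint8), spacing=(h, h, h),
                      origin=origin)


def generate_subject(
    spec: CohortSpec, group: str, subject_id: str, seed: int,
    base_volume: float | None = None,
) -> SyntheticSubject:
    """One subject: deformed mesh in template correspondence, mask, ICV.

    The subject's target volume combines the group multiplier, multiplicative
    noise, and an ICV-coupled term at ``spec.icv_slope``, all realized as an
    isotropic scale factor of the template; the focal bump and vertex jitter
    are applied on top.  An empty or pathologically small voxelization is
    retried with a fresh sub-seed (max 5 attempts).
    """
    if group not in spec.group_sizes:
        raise ValueError(f"unknown group {group!r}")
    rng = np.random.default_rng(seed)
    if base_volume is None:
        base_volume = 4.0 / 3.0 * np.pi * float(np.prod(spec.semi_axes))

    icv = float(rng.normal(spec.icv_mean, spec.icv_sd))
    noise = float(rng.normal(0.0, spec.volume_noise_sd))
    target_volume = base_volume * spec.volume_multiplier[group] * (1.0 + noise)
    target_volume += spec.icv_slope * (icv - spec.icv_mean)
    target_volume = max(target_volume, 0.2 * base_volume)
    scale = (target_volume / base_volume) ** (1.0 / 3.0)
    amplitude = float(spec.bump_amplitude.get(group, 0.0))

    rho = _radius_function(spec, group, scale, amplitude)
    tmpl = template_mesh(spec)
    dirs = tmpl.vertices / np.linalg.norm(tmpl.vertices, axis=1, keepdims=True)
    verts = dirs * rho(dirs)[:, None]
    if spec.jitter_sd > 0:
        verts = verts + rng.normal(0.0, spec.jitter_sd, size=verts.shape)
    mesh = SurfaceMesh(vertices=verts, faces=tmpl.faces)

    last_err: Exception | None = None
    for attempt in range(5):
        try:
            mask = _voxelize(rho, spec)
            break
        except ValueError as err:  # empty voxelization at coarse spacing
            last_err = err
            sub = np.random.default_rng((seed, attempt)).integers(0, 2**31 - 1)
            rng2 = np.random.default_rng(int(sub))
            scale = max(scale * (1 + 0.05 * (attempt + 1)), 0.5)
            rho = _radius_function(spec, group, scale, amplitude)
    else:
        raise RuntimeError(f"voxelization failed after 5 attempts: {last_err}")

    truth = {"true_scale": scale, "true_amplitude": amplitude,
             "target_volume_mm3": target_volume}
    return SyntheticSubject(subject_id=subject_id, group=group, mask=mask,
                            mesh=mesh, icv=icv, truth=truth)


def generate_cohort(spec: CohortSpec, out_dir: str | None = None) -> SyntheticCohort:
    """Full cohort, deterministic for a fixed ``spec.seed``.

    With ``out_dir`` the cohort is also written in the formats the I/O layer
    reads: NIfTI masks, PLY meshes, ``template.ply``, ``cohort.csv`` (with
    path columns) and ``manifest.csv`` carrying the ground-truth parameters.
    """
    rng = np.random.default_rng(spec.seed)
    subjects = []
    for group in spec.group_sizes:
        for i in range(spec.group_sizes[group]):
            sid = f"{group}{i + 1:03d}"
            sub_seed = int(rng.integers(0, 2**31 - 1))
            subjects.append(generate_subject(spec, group, sid, sub_seed))
    cohort = SyntheticCohort(spec=spec, template=template_mesh(spec),
                             subjects=subjects)
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        write_mesh(cohort.template, os.path.join(out_dir, "template.ply"))
        rows = []
        for s in cohort.subjects:
            mask_path = os.path.join(out_dir, f"{s.subject_id}_mask.nii.gz")
            mesh_path = os.path.join(out_dir, f"{s.subject_id}_surface.ply")
            write_mask(s.mask, mask_path)
            write_mesh(s.mesh, mesh_path)
            rows.append({"subject_id": s.subject_id, "group": s.group,
                         "icv": s.icv, "mask_path": mask_path,
                         "mesh_path": mesh_path})
        pd.DataFrame(rows).to_csv(os.path.join(out_dir, "cohort.csv"), index=False)
        cohort.manifest().to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return cohort
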