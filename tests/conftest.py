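import numpy as np
import pytest

from shapedx.io import BinaryMask, SurfaceMesh
from shapedx.synthetic import CohortSpec, generate_cohort


def ball_mask(radius_vox: float, spacing=(1.0, 1.0, 1.0), margin: int = 2) -> BinaryMask:
    """Digitized ball: voxel centers within radius_vox (in voxel units of axis 0)."""
    r_mm = radius_vox * spacing[0]
    ns = [int(np.ceil(2 * (r_mm / s + margin))) for s in spacing]
    grids = [(np.arange(n) - (n - 1) / 2.0) * s for n, s in zip(ns, spacing)]
    X, Y, Z = np.meshgrid(*grids, indexing="ij")
    inside = X**2 + Y**2 + Z**2 <= r_mm**2
    return BinaryMask(voxels=inside.astype(np.uint8), spacing=spacing)


def cube_mask(side_vox: int, spacing=(1.0, 1.0, 1.0)) -> BinaryMask:
    return BinaryMask(voxels=np.ones((side_vox,) * 3, dtype=np.uint8),
                      spacing=spacing)


def icosphere_mesh(subdivisions: int = 2, radius: float = 10.0) -> SurfaceMesh:
    import trimesh

    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return SurfaceMesh(vertices=np.asarray(ico.vertices, float),
                       faces=np.asarray(ico.faces, np.int64))


@pytest.fixture(scope="session")
def tiny_cohort():
    """Fast low-resolution cohort exercising every stage (2 subjects/group)."""
    spec = CohortSpec(
        group_sizes={"NC": 3, "AD": 3, "FTD": 3},
        mesh_subdivisions=2,
        voxel_spacing=2.0,
        seed=123,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def desk_cohort():
    """Default-condition cohort (78 subjects) at reduced mesh/grid resolution.

    Session-scoped: generated once and shared by the end-to-end and
    acceptance tests.
    """
    spec = CohortSpec(seed=20240, mesh_subdivisions=3, voxel_spacing=1.5)
    return generate_cohort(spec)
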