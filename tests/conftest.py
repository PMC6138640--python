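import numpy as np
import pytest

from nbaxis.geometry import Axis3D, Point3D, VoxelSpacing
from nbaxis.stack_io import VoxelGrid
from nbaxis.synthetic import (
    DEFAULT_SPACING,
    CycleTruth,
    NoiseModel,
    SceneTruth,
    sample_division_series,
)


def scene_with_axis(direction, spacing=DEFAULT_SPACING, volume_ratio=4.0, nb_radius=5.0):
    """A one-cycle scene whose division axis points along ``direction``."""
    u = np.asarray(direction, dtype=float)
    u = u / np.linalg.norm(u)
    gmc_r = nb_radius / volume_ratio ** (1.0 / 3.0)
    d = 0.8 * (nb_radius + gmc_r)
    centre = np.zeros(3)
    gmc = centre + d * u
    cyc = CycleTruth(
        true_axis=Axis3D.from_arrays(centre - nb_radius * u, gmc + gmc_r * u),
        gmc_centre=Point3D.from_array(gmc),
        gmc_radius=gmc_r,
        interphase_frame=0,
        rounding_frame=1,
        telophase_frame=2,
        apical_centrosome=Point3D.from_array(centre - 0.6 * nb_radius * u),
        basal_centrosome=Point3D.from_array(centre + 0.6 * nb_radius * u),
        deviation_drawn=None,
    )
    return SceneTruth(
        nb_centre=Point3D.from_array(centre),
        nb_radius=nb_radius,
        cycles=(cyc,),
        glia_coverage_fraction=0.79,
        glia_cap_axis=(0.0, 0.0, 1.0),
        spacing=spacing,
        noise=NoiseModel(),
        seed=0,
    )


@pytest.fixture(scope="session")
def control_scene():
    """A small control-condition lineage with anisotropic spacing."""
    return sample_division_series("control", 3, seed=42)


@pytest.fixture()
def iso_spacing():
    return VoxelSpacing(0.26, 0.26, 0.26)


def voxelized_ball(radius: float, spacing: VoxelSpacing, margin: float = 1.5) -> VoxelGrid:
    """Binary ball mask of the given physical radius, centred in the grid."""
    sp = spacing.as_array()
    half = radius + margin
    axes = [np.arange(int(2 * half / d) + 1) * d - half for d in sp]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij", sparse=True)
    return VoxelGrid(zz**2 + yy**2 + xx**2 <= radius**2, spacing)
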