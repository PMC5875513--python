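"""Deterministic generators for the built-in benchmark geometries."""

from __future__ import annotations

import numpy as np

from . import materials as mat
from .beamline import Aperture, Compensator
from .transport import Phantom

__all__ = ["make_water_tank", "make_stair_compensator", "make_slab_phantom"]


def make_water_tank(side: float = 40.0, voxel: float = 0.1, entry_z: float = 0.0) -> Phantom:
    """Homogeneous water block (default 40x40x40 cm at 1 mm voxels).

    ``voxel`` is in cm.  The entry face sits at ``entry_z``; laterally the
    tank is centred on the beam axis.
    """
    n = int(round(side / voxel))
    ids = np.zeros((n, n, n), dtype=np.uint8)
    return Phantom(
        origin=(-side / 2.0, -side / 2.0, entry_z),
        voxel_size=(voxel, voxel, voxel),
        material_ids=ids,
        material_names=("water",),
    )


def make_stair_compensator(
    pixel: float = 0.1,
    step_width: float = 6.0,
    thicknesses: tuple[float, float, float] = (2.7, 0.2, 5.2),
    z_position: float = -40.0,
) -> Compensator:
    """Three parallel sharp-edged Lucite steps, each 6 cm wide.

    Thickness depends only on x: 2.7 cm for x < -3, 0.2 cm for |x| < 3,
    5.2 cm for x > 3 (edges at +-3 cm off-axis); 18 cm square map.
    """
    half = 1.5 * step_width
    n = int(round(2 * half / pixel))
    x = -half + (np.arange(n) + 0.5) * pixel
    tmap = np.empty((n, n))
    col = np.where(x < -step_width / 2, thicknesses[0], np.where(x < step_width / 2, thicknesses[1], thicknesses[2]))
    tmap[:, :] = col[:, None]
    return Compensator(
        thickness_map=tmap,
        pixel_size=pixel,
        origin=(x[0], x[0]),
        material=mat.DEFAULT_MATERIALS["lucite"],
        z_position=z_position,
    )


def make_slab_phantom(
    side: float = 20.0,
    depth_extent: float = 20.0,
    voxel: float = 0.2,
    slab_depth: float = 4.0,
    slab_thickness: float = 2.0,
    entry_z: float = 0.0,
) -> tuple[Phantom, Aperture]:
    """Solid-water block with adjacent bone (x < 0) and lung (x >= 0) slabs.

    Slab depths/thicknesses are configurable (defaults declared arbitrary:
    2 cm slabs starting at 4 cm depth).  Returns the phantom and its
    companion 5 cm x 7 cm rectangular aperture.
    """
    nx = ny = int(round(side / voxel))
    nz = int(round(depth_extent / voxel))
    ids = np.zeros((nx, ny, nz), dtype=np.uint8)  # 0 = solid-water
    z0 = int(round(slab_depth / voxel))
    z1 = int(round((slab_depth + slab_thickness) / voxel))
    ids[: nx // 2, :, z0:z1] = 1  # bone
    ids[nx // 2 :, :, z0:z1] = 2  # lung
    phantom = Phantom(
        origin=(-side / 2.0, -side / 2.0, entry_z),
        voxel_size=(voxel, voxel, voxel),
        material_ids=ids,
        material_names=("solid-water", "bone", "lung"),
    )
    aperture = Aperture(shape="rectangle", width=5.0, height=7.0)
    return phantom, aperture
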