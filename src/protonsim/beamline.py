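"""Thin-plane beamline devices: lead foil, nozzle wall, aperture, compensator.

Every device acts at a plane: it degrades energy through the range law
(by the device's water-equivalent thickness), applies a Gaussian angular
kick with the Highland sigma, or terminates the proton.  Lateral
displacement inside the device slabs is ignored — the paper-style
simplification this engine is built around.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import materials as mat
from .transport import ProtonState, highland_sigma

__all__ = [
    "NozzleGeometry",
    "Aperture",
    "Compensator",
    "traverse_foil",
    "apply_aperture",
    "apply_compensator",
    "apply_nozzle_wall",
    "drift_to_plane",
]


@dataclass(frozen=True)
class NozzleGeometry:
    """Simplified cylindrical nozzle with a single lead foil inside.

    The foil sits midway between the source plane and the nozzle exit
    unless ``foil_z`` is given explicitly.
    """

    inner_radius: float = 13.0
    wall_thickness: float = 6.0
    exit_z: float = -40.0  # snout/aperture plane, cm from isocenter
    source_z: float = -230.0
    foil_thickness: float = 2.0  # mm lead
    foil_z: float | None = None

    def __post_init__(self) -> None:
        if self.inner_radius <= 0:
            raise ValueError("inner_radius must be > 0")
        if self.foil_thickness < 0:
            raise ValueError("foil_thickness must be >= 0")
        if self.foil_z is None:
            object.__setattr__(self, "foil_z", 0.5 * (self.source_z + self.exit_z))
        if not (self.source_z <= self.foil_z <= self.exit_z):
            raise ValueError("foil must lie between source plane and nozzle exit")


@dataclass(frozen=True)
class Aperture:
    """Perfect-absorber field-defining opening at a plane (closed opening:
    boundary points survive)."""

    shape: str  # "circle" | "rectangle" | "polygon"
    z_position: float = -40.0
    radius: float | None = None
    width: float | None = None
    height: float | None = None
    vertices: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.shape == "circle":
            if self.radius is None or self.radius <= 0:
                raise ValueError("circle aperture needs radius > 0")
        elif self.shape == "rectangle":
            if not (self.width and self.height) or self.width <= 0 or self.height <= 0:
                raise ValueError("rectangle aperture needs width, height > 0")
        elif self.shape == "polygon":
            v = np.asarray(self.vertices, dtype=float)
            if v.ndim != 2 or v.shape[0] < 3 or v.shape[1] != 2:
                raise ValueError("polygon aperture needs >= 3 (x, y) vertices")
            if _polygon_self_intersects(v):
                raise ValueError("polygon aperture must be simple (non-self-intersecting)")
            object.__setattr__(self, "vertices", v)
        else:
            raise ValueError(f"unknown aperture shape {self.shape!r}")

    def contains(self, x, y) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if self.shape == "circle":
            return x**2 + y**2 <= self.radius**2 + 1e-12
        if self.shape == "rectangle":
            return (np.abs(x) <= self.width / 2 + 1e-12) & (np.abs(y) <= self.height / 2 + 1e-12)
        return _points_in_polygon(x, y, self.vertices)


def _polygon_self_intersects(v: np.ndarray) -> bool:
    n = len(v)
    segs = [(v[i], v[(i + 1) % n]) for i in range(n)]

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    def intersects(p1, p2, p3, p4):
        d1, d2 = cross(p3, p4, p1), cross(p3, p4, p2)
        d3, d4 = cross(p1, p2, p3), cross(p1, p2, p4)
        return ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0))

    for i in range(n):
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue  # adjacent through wrap-around
            if intersects(*segs[i], *segs[j]):
                return True
    return False


def _points_in_polygon(x: np.ndarray, y: np.ndarray, verts: np.ndarray) -> np.ndarray:
    inside = np.zeros(np.broadcast(x, y).shape, dtype=bool)
    n = len(verts)
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        with np.errstate(divide="ignore", invalid="ignore"):
            crosses = ((y1 > y) != (y2 > y)) & (x < (x2 - x1) * (y - y1) / (y2 - y1) + x1)
        inside ^= crosses
    return inside


@dataclass
class Compensator:
    """Variable-thickness absorber: 2D thickness map over the field plane.

    Thickness is looked up nearest-pixel (sharp edges, no interpolation);
    points off the map see zero thickness.
    """

    thickness_map: np.ndarray  # (nx, ny) cm
    pixel_size: float  # cm
    origin: tuple[float, float] = (0.0, 0.0)  # centre of pixel (0, 0)
    material: mat.Material = field(default_factory=lambda: mat.DEFAULT_MATERIALS["lucite"])
    z_position: float = -40.0

    def __post_init__(self) -> None:
        self.thickness_map = np.asarray(self.thickness_map, dtype=float)
        if self.thickness_map.ndim != 2:
            raise ValueError("thickness_map must be 2D")
        if np.any(self.thickness_map < 0):
            raise ValueError("thicknesses must be >= 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel size must be > 0")

    def thickness_at(self, x, y) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        ix = np.rint((x - self.origin[0]) / self.pixel_size).astype(int)
        iy = np.rint((y - self.origin[1]) / self.pixel_size).astype(int)
        nx, ny = self.thickness_map.shape
        valid = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
        t = np.zeros_like(x, dtype=float)
        t[valid] = self.thickness_map[ix[valid], iy[valid]]
        return t

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["# pixel_size_cm", self.pixel_size])
            w.writerow(["# origin_cm", self.origin[0], self.origin[1]])
            w.writerow(["# material", self.material.name])
            for row in self.thickness_map:
                w.writerow([f"{v:.6g}" for v in row])

    @classmethod
    def from_csv(cls, path: str | Path, materials=None) -> "Compensator":
        materials = materials or mat.DEFAULT_MATERIALS
        rows = []
        meta = {}
        with open(path, newline="") as fh:
            for row in csv.reader(fh):
                if row and str(row[0]).startswith("#"):
                    meta[row[0].lstrip("# ")] = row[1:]
                elif row:
                    rows.append([float(v) for v in row])
        return cls(
            thickness_map=np.asarray(rows),
            pixel_size=float(meta["pixel_size_cm"][0]),
            origin=(float(meta["origin_cm"][0]), float(meta["origin_cm"][1])),
            material=materials[meta["material"][0]],
        )


# ---------------------------------------------------------------------------
# plane operators
# ---------------------------------------------------------------------------

def drift_to_plane(state: ProtonState, z: float) -> ProtonState:
    """Propagate alive protons in straight lines to the plane at ``z``.

    Protons moving away from the plane (dz <= 0) are terminated.
    """
    alive = state.alive
    dz = state.direction[:, 2]
    bad = alive & (dz <= 1e-9)
    state.alive = alive & ~bad
    sel = state.alive
    t = (z - state.position[sel, 2]) / dz[sel]
    state.position[sel] += state.direction[sel] * t[:, None]
    state.position[sel, 2] = z
    return state


def _degrade_and_scatter(
    state: ProtonState,
    wet_cm: np.ndarray,
    mass_thickness_gcm2: np.ndarray,
    x0_gcm2: float,
    rng: np.random.Generator,
    model: mat.RangeEnergyModel,
) -> ProtonState:
    sel = state.alive & (wet_cm > 0)
    if not np.any(sel):
        return state
    e = state.kinetic_energy[sel]
    residual = mat.range_from_energy(e, model) - wet_cm[sel]
    dead = residual <= 0
    e_new = np.where(dead, 0.0, mat.energy_from_range(np.clip(residual, 0, None), model))
    state.kinetic_energy[sel] = e_new
    ids = np.nonzero(sel)[0]
    state.alive[ids[dead]] = False

    live = ids[~dead]
    if live.size:
        e_mid = 0.5 * (e[~dead] + e_new[~dead])
        sig = highland_sigma(e_mid, mass_thickness_gcm2[sel][~dead], x0_gcm2)
        tx = sig * rng.standard_normal(live.size)
        ty = sig * rng.standard_normal(live.size)
        d = state.direction[live]
        # frame perpendicular to each direction
        helper = np.where(
            np.abs(d[:, 2:3]) < 0.9, np.array([[0.0, 0.0, 1.0]]), np.array([[1.0, 0.0, 0.0]])
        )
        u = np.cross(d, helper)
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        v = np.cross(d, u)
        d = d + tx[:, None] * u + ty[:, None] * v
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        state.direction[live] = d
    return state


def traverse_foil(
    state: ProtonState,
    foil_thickness_mm: float,
    rng: np.random.Generator,
    lead: mat.Material | None = None,
    model: mat.RangeEnergyModel = mat.DEFAULT_MODEL,
) -> ProtonState:
    """Lead-foil energy degradation (by its WET) plus Highland scattering."""
    if foil_thickness_mm < 0:
        raise ValueError("foil thickness must be >= 0")
    if foil_thickness_mm == 0:
        return state
    lead = lead or mat.DEFAULT_MATERIALS["lead"]
    t_cm = foil_thickness_mm / 10.0
    n = len(state)
    wet_arr = np.full(n, mat.wet(t_cm, lead))
    x_arr = np.full(n, t_cm * lead.mass_density)
    return _degrade_and_scatter(state, wet_arr, x_arr, lead.radiation_length, rng, model)


def apply_nozzle_wall(state: ProtonState, nozzle: NozzleGeometry) -> ProtonState:
    """Terminate protons outside the inner radius at the nozzle exit plane."""
    r2 = state.position[:, 0] ** 2 + state.position[:, 1] ** 2
    state.alive &= r2 <= nozzle.inner_radius**2
    return state


def apply_aperture(state: ProtonState, aperture: Aperture) -> ProtonState:
    """Perfect-absorber mask: protons outside the opening are terminated."""
    inside = aperture.contains(state.position[:, 0], state.position[:, 1])
    state.alive &= inside
    return state


def apply_compensator(
    state: ProtonState,
    compensator: Compensator,
    rng: np.random.Generator,
    model: mat.RangeEnergyModel = mat.DEFAULT_MODEL,
) -> ProtonState:
    """Range pullback by the local compensator WET, with Highland scattering."""
    t = compensator.thickness_at(state.position[:, 0], state.position[:, 1])
    wet_arr = t * compensator.material.relative_stopping_power
    x_arr = t * compensator.material.mass_density
    return _degrade_and_scatter(
        state, wet_arr, x_arr, compensator.material.radiation_length, rng, model
    )
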