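"""Condensed-history proton transport in a voxelized phantom.

A class II-style loop: each step is clamped at the nearest voxel
boundary (so no step crosses a material interface), energy loss follows
the water range law scaled by the local relative stopping power, with
Gaussian Bohr-like straggling per step; directions are deflected by the
Highland multiple-Coulomb-scattering sigma; primaries are removed by an
exponential nuclear attenuation stand-in depositing a fixed local
fraction of their remaining energy.  Dose is scored on a mesh that may
differ from the phantom grid (step-midpoint assignment), with per-voxel
sum and sum-of-squares per history for uncertainty estimation.

Coordinates: the beam travels +z, isocenter at the origin, source plane
at negative z.  Voxel indexing is half-open ``[o + i*d, o + (i+1)*d)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from numba import njit

from . import materials as mat

__all__ = [
    "ProtonState",
    "Phantom",
    "DoseGrid",
    "TransportPhysics",
    "highland_sigma",
    "step_length",
    "transport_in_phantom",
    "estimate_uncertainty",
]


@dataclass
class ProtonState:
    """Vectorized batch of proton states (arrays over particles)."""

    position: np.ndarray  # (n, 3) cm
    direction: np.ndarray  # (n, 3) unit vectors
    kinetic_energy: np.ndarray  # (n,) MeV
    statistical_weight: np.ndarray | None = None
    alive: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.position = np.atleast_2d(np.asarray(self.position, dtype=float))
        self.direction = np.atleast_2d(np.asarray(self.direction, dtype=float))
        self.kinetic_energy = np.atleast_1d(np.asarray(self.kinetic_energy, dtype=float))
        n = len(self.kinetic_energy)
        if self.statistical_weight is None:
            self.statistical_weight = np.ones(n)
        if self.alive is None:
            self.alive = np.ones(n, dtype=bool)
        self.statistical_weight = np.atleast_1d(np.asarray(self.statistical_weight, float))
        self.alive = np.atleast_1d(np.asarray(self.alive, bool))
        norms = np.linalg.norm(self.direction, axis=1)
        if np.any(np.abs(norms[self.alive] - 1.0) > 1e-9):
            raise ValueError("directions must be unit vectors")
        if np.any(self.kinetic_energy < 0):
            raise ValueError("kinetic energies must be >= 0")
        if np.any(self.statistical_weight <= 0):
            raise ValueError("statistical weights must be > 0")

    def __len__(self) -> int:
        return len(self.kinetic_energy)


@dataclass
class Phantom:
    """Voxel grid of materials with world placement.

    ``material_ids`` indexes into ``material_names`` which resolve in the
    material table.  ``density_override`` (g/cm^3) rescales both the
    stopping power and the scattering mass thickness voxel-by-voxel.
    """

    origin: tuple[float, float, float]
    voxel_size: tuple[float, float, float]
    material_ids: np.ndarray  # 3D uint8, shape (nx, ny, nz)
    material_names: tuple[str, ...] = ("water",)
    density_override: np.ndarray | None = None
    materials: Mapping[str, mat.Material] = field(default_factory=lambda: mat.DEFAULT_MATERIALS)

    def __post_init__(self) -> None:
        self.origin = tuple(float(v) for v in self.origin)
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")
        self.material_ids = np.ascontiguousarray(self.material_ids, dtype=np.uint8)
        if self.material_ids.ndim != 3:
            raise ValueError("material_ids must be a 3D grid")
        for name in self.material_names:
            if name not in self.materials:
                raise ValueError(f"material {name!r} not in the material table")
        if self.material_ids.max() >= len(self.material_names):
            raise ValueError("material id exceeds the name list")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.material_ids.shape

    def entry_z(self) -> float:
        return self.origin[2]

    def property_tables(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(rsp, rho, X0) per material id."""
        mats = [self.materials[n] for n in self.material_names]
        rsp = np.array([m.relative_stopping_power for m in mats])
        rho = np.array([m.mass_density for m in mats])
        x0 = np.array([m.radiation_length for m in mats])
        return rsp, rho, x0


@dataclass
class DoseGrid:
    """Accumulated energy-deposit mesh with per-history squared sums."""

    origin: tuple[float, float, float]
    voxel_size: tuple[float, float, float]
    shape: tuple[int, int, int]
    energy_deposit: np.ndarray | None = None
    energy_deposit_sq: np.ndarray | None = None
    histories: int = 0
    accounting: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.origin = tuple(float(v) for v in self.origin)
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        self.shape = tuple(int(v) for v in self.shape)
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")
        if self.energy_deposit is None:
            self.energy_deposit = np.zeros(self.shape)
        if self.energy_deposit_sq is None:
            self.energy_deposit_sq = np.zeros(self.shape)

    @classmethod
    def for_phantom(cls, phantom: Phantom, voxel_size=None) -> "DoseGrid":
        if voxel_size is None:
            return cls(phantom.origin, phantom.voxel_size, phantom.shape)
        voxel_size = tuple(float(v) for v in np.broadcast_to(voxel_size, 3))
        extent = [n * d for n, d in zip(phantom.shape, phantom.voxel_size)]
        shape = tuple(max(int(round(e / v)), 1) for e, v in zip(extent, voxel_size))
        return cls(phantom.origin, voxel_size, shape)

    def depth_coordinates(self) -> np.ndarray:
        return (np.arange(self.shape[2]) + 0.5) * self.voxel_size[2]

    def to_hdf5(self, path: str | Path, provenance: dict | None = None) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("energy_deposit", data=self.energy_deposit, compression="gzip")
            f.create_dataset("energy_deposit_sq", data=self.energy_deposit_sq, compression="gzip")
            f.attrs["origin"] = self.origin
            f.attrs["voxel_size"] = self.voxel_size
            f.attrs["histories"] = self.histories
            for k, v in self.accounting.items():
                f.attrs[f"accounting_{k}"] = v
            if provenance:
                import json

                f.attrs["provenance"] = json.dumps(provenance)

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "DoseGrid":
        import h5py

        with h5py.File(path, "r") as f:
            dep = f["energy_deposit"][...]
            sq = f["energy_deposit_sq"][...]
            grid = cls(
                tuple(f.attrs["origin"]),
                tuple(f.attrs["voxel_size"]),
                dep.shape,
                energy_deposit=dep,
                energy_deposit_sq=sq,
                histories=int(f.attrs["histories"]),
            )
            grid.accounting = {
                k[len("accounting_"):]: float(v)
                for k, v in f.attrs.items()
                if k.startswith("accounting_")
            }
        return grid


@dataclass(frozen=True)
class TransportPhysics:
    """Tunable physics stand-ins for the condensed-history loop."""

    max_step: float = 0.1  # cm
    range_fraction: float = 0.2
    energy_cutoff: float = 0.5  # MeV, deposit-on-kill
    straggling_coefficient: float = mat.BOHR_STRAGGLING_MEV2_PER_CM  # MeV^2/cm water
    nuclear_lambda: float = 0.012  # per cm water
    nuclear_local_fraction: float = 0.6


def highland_sigma(energy_mev, path_wet_gcm2, x0_gcm2):
    """Highland multiple-scattering sigma (radians), vectorized.

    ``14.1/(pv) * sqrt(x/X0) * (1 + (1/9) log10(x/X0))``; returns 0 for
    zero path and clamps the bracket at 0 for very thin slabs.
    """
    e = np.asarray(energy_mev, dtype=float)
    x = np.asarray(path_wet_gcm2, dtype=float)
    pv = (e**2 + 2.0 * e * mat.PROTON_MASS_MEV) / (e + mat.PROTON_MASS_MEV)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = x / x0_gcm2
        bracket = np.where(ratio > 0, 1.0 + np.log10(np.where(ratio > 0, ratio, 1.0)) / 9.0, 0.0)
        sig = np.where(
            ratio > 0,
            14.1 / pv * np.sqrt(np.where(ratio > 0, ratio, 0.0)) * np.maximum(bracket, 0.0),
            0.0,
        )
    return sig if sig.ndim else float(sig)


def step_length(
    state: ProtonState,
    phantom: Phantom,
    physics: TransportPhysics = TransportPhysics(),
    index: int = 0,
    model: mat.RangeEnergyModel = mat.DEFAULT_MODEL,
) -> float:
    """Step proposal for one particle: min(boundary, max_step, fraction*range).

    Mirrors the kernel's stepping policy; exposed for inspection/tests.
    """
    if not state.alive[index]:
        raise ValueError("state is not alive")
    pos = state.position[index]
    d = state.direction[index]
    rsp_tab, _, _ = phantom.property_tables()
    ii = [int(math.floor((pos[k] - phantom.origin[k]) / phantom.voxel_size[k])) for k in range(3)]
    for k in range(3):
        if not (0 <= ii[k] < phantom.shape[k]):
            raise ValueError("particle is outside the phantom")
    rsp = rsp_tab[phantom.material_ids[ii[0], ii[1], ii[2]]]
    if phantom.density_override is not None:
        _, rho_tab, _ = phantom.property_tables()
        rho_nom = rho_tab[phantom.material_ids[ii[0], ii[1], ii[2]]]
        rsp = rsp * phantom.density_override[ii[0], ii[1], ii[2]] / rho_nom
    geo_range = mat.range_from_energy(state.kinetic_energy[index], model) / rsp
    t_boundary = math.inf
    for k in range(3):
        if d[k] > 1e-12:
            t = (phantom.origin[k] + (ii[k] + 1) * phantom.voxel_size[k] - pos[k]) / d[k]
        elif d[k] < -1e-12:
            t = (phantom.origin[k] + ii[k] * phantom.voxel_size[k] - pos[k]) / d[k]
        else:
            continue
        t_boundary = min(t_boundary, t)
    step = min(physics.max_step, physics.range_fraction * geo_range, t_boundary)
    return max(step, 1e-5)


# ---------------------------------------------------------------------------
# numba kernel
# ---------------------------------------------------------------------------

@njit(cache=False)
def _highland_nb(e, x_gcm2, x0):
    if x_gcm2 <= 0.0:
        return 0.0
    pv = (e * e + 2.0 * e * 938.272) / (e + 938.272)
    ratio = x_gcm2 / x0
    bracket = 1.0 + math.log10(ratio) / 9.0
    if bracket < 0.0:
        bracket = 0.0
    return 14.1 / pv * math.sqrt(ratio) * bracket


@njit(cache=False)
def _kernel(
    pos,
    dirs,
    energy,
    alive,
    ph_origin,
    ph_voxel,
    ph_shape,
    mat_ids,  # flattened uint8 (C order of (nx,ny,nz))
    rsp_tab,
    rho_tab,
    x0_tab,
    dens_override,  # flattened float64 or length-0 when absent
    sc_origin,
    sc_voxel,
    sc_shape,
    dose,  # flattened float64
    dose_sq,
    alpha,
    pexp,
    e_cutoff,
    e_cap,
    max_step,
    range_frac,
    strag_coeff,
    lam_nuc,
    f_local,
    seed,
):
    np.random.seed(seed)
    n = energy.shape[0]
    nx, ny, nz = ph_shape[0], ph_shape[1], ph_shape[2]
    sx, sy, sz = sc_shape[0], sc_shape[1], sc_shape[2]
    has_override = dens_override.shape[0] > 0
    inv_p = 1.0 / pexp

    launched = 0.0
    deposited = 0.0
    escaped = 0.0
    nuclear_lost = 0.0
    n_exit = 0
    n_stopped = 0
    n_nuclear = 0
    n_missed = 0

    buf_cap = 8192
    buf_idx = np.empty(buf_cap, dtype=np.int64)
    buf_dep = np.empty(buf_cap, dtype=np.float64)

    for h in range(n):
        if not alive[h]:
            continue
        e = energy[h]
        launched += e
        x, y, z = pos[h, 0], pos[h, 1], pos[h, 2]
        dx, dy, dz = dirs[h, 0], dirs[h, 1], dirs[h, 2]

        # advance to the grid if starting outside (ray-box entry)
        t_in = 0.0
        t_out = 1e30
        ok = True
        for k in range(3):
            if k == 0:
                p0, dk = x, dx
            elif k == 1:
                p0, dk = y, dy
            else:
                p0, dk = z, dz
            lo = ph_origin[k]
            hi = ph_origin[k] + ph_shape[k] * ph_voxel[k]
            if abs(dk) < 1e-12:
                if p0 < lo or p0 >= hi:
                    ok = False
                    break
            else:
                t0 = (lo - p0) / dk
                t1 = (hi - p0) / dk
                if t0 > t1:
                    t0, t1 = t1, t0
                if t0 > t_in:
                    t_in = t0
                if t1 < t_out:
                    t_out = t1
        if not ok or t_in > t_out:
            escaped += e
            n_missed += 1
            continue
        if t_in > 0.0:
            x += dx * (t_in + 1e-7)
            y += dy * (t_in + 1e-7)
            z += dz * (t_in + 1e-7)

        nbuf = 0
        status_alive = True
        while status_alive:
            ix = int(math.floor((x - ph_origin[0]) / ph_voxel[0]))
            iy = int(math.floor((y - ph_origin[1]) / ph_voxel[1]))
            iz = int(math.floor((z - ph_origin[2]) / ph_voxel[2]))
            if ix < 0 or ix >= nx or iy < 0 or iy >= ny or iz < 0 or iz >= nz:
                escaped += e
                n_exit += 1
                break
            vox = (ix * ny + iy) * nz + iz
            mid_mat = mat_ids[vox]
            rsp = rsp_tab[mid_mat]
            rho = rho_tab[mid_mat]
            if has_override:
                scale = dens_override[vox] / rho
                rsp = rsp * scale
                rho = dens_override[vox]
            x0_loc = x0_tab[mid_mat]

            rw = alpha * e**pexp  # residual water range
            geo_range = rw / rsp

            # boundary distance
            tb = 1e30
            if dx > 1e-12:
                t = (ph_origin[0] + (ix + 1) * ph_voxel[0] - x) / dx
                if t < tb:
                    tb = t
            elif dx < -1e-12:
                t = (ph_origin[0] + ix * ph_voxel[0] - x) / dx
                if t < tb:
                    tb = t
            if dy > 1e-12:
                t = (ph_origin[1] + (iy + 1) * ph_voxel[1] - y) / dy
                if t < tb:
                    tb = t
            elif dy < -1e-12:
                t = (ph_origin[1] + iy * ph_voxel[1] - y) / dy
                if t < tb:
                    tb = t
            if dz > 1e-12:
                t = (ph_origin[2] + (iz + 1) * ph_voxel[2] - z) / dz
                if t < tb:
                    tb = t
            elif dz < -1e-12:
                t = (ph_origin[2] + iz * ph_voxel[2] - z) / dz
                if t < tb:
                    tb = t

            step = max_step
            if range_frac * geo_range < step:
                step = range_frac * geo_range
            crossing = False
            if tb < step:
                step = tb
                crossing = True
            if step < 1e-5:
                step = 1e-5
                crossing = True  # may nudge across; harmless
            if crossing:
                adv = step + 1e-7  # land just inside the next voxel
            else:
                adv = step

            step_wet = step * rsp
            # mean energy loss from the range law
            if step_wet >= rw:
                de_mean = e
            else:
                e_new = ((rw - step_wet) / alpha) ** inv_p
                de_mean = e - e_new
            de = de_mean
            if strag_coeff > 0.0 and de_mean < e:
                de += math.sqrt(strag_coeff * step_wet) * np.random.normal()
                if de < 0.0:
                    de = 0.0
                elif de > e:
                    de = e

            # score at the step midpoint
            mx = x + dx * step * 0.5
            my = y + dy * step * 0.5
            mz = z + dz * step * 0.5
            jx = int(math.floor((mx - sc_origin[0]) / sc_voxel[0]))
            jy = int(math.floor((my - sc_origin[1]) / sc_voxel[1]))
            jz = int(math.floor((mz - sc_origin[2]) / sc_voxel[2]))
            svox = -1
            if 0 <= jx < sx and 0 <= jy < sy and 0 <= jz < sz:
                svox = (jx * sy + jy) * sz + jz

            e_mid = e - 0.5 * de_mean
            if e_mid < e_cap:
                e_mid = e_cap

            # commit energy loss
            e -= de
            dep_here = de
            deposited += de

            stopping = False
            if e <= e_cutoff:
                dep_here += e
                deposited += e
                e = 0.0
                stopping = True
                n_stopped += 1

            if not stopping and lam_nuc > 0.0:
                p_rm = 1.0 - math.exp(-lam_nuc * step_wet)
                if np.random.random() < p_rm:
                    dep_here += f_local * e
                    deposited += f_local * e
                    nuclear_lost += (1.0 - f_local) * e
                    e = 0.0
                    stopping = True
                    n_nuclear += 1

            if svox >= 0 and dep_here > 0.0:
                if nbuf > 0 and buf_idx[nbuf - 1] == svox:
                    buf_dep[nbuf - 1] += dep_here
                else:
                    if nbuf < buf_cap:
                        buf_idx[nbuf] = svox
                        buf_dep[nbuf] = dep_here
                        nbuf += 1
                    else:  # overflow: merge into the last slot (rare)
                        buf_dep[nbuf - 1] += dep_here

            # move
            x += dx * adv
            y += dy * adv
            z += dz * adv

            if stopping:
                break

            # multiple Coulomb scattering
            sig = _highland_nb(e_mid, step * rho, x0_loc)
            if sig > 0.0:
                tx = sig * np.random.normal()
                ty = sig * np.random.normal()
                # orthonormal frame around (dx, dy, dz)
                if abs(dz) < 0.9:
                    ux, uy, uz = dy, -dx, 0.0
                else:
                    ux, uy, uz = 0.0, dz, -dy
                un = math.sqrt(ux * ux + uy * uy + uz * uz)
                ux, uy, uz = ux / un, uy / un, uz / un
                vx = dy * uz - dz * uy
                vy = dz * ux - dx * uz
                vz = dx * uy - dy * ux
                dx += tx * ux + ty * vx
                dy += tx * uy + ty * vy
                dz += tx * uz + ty * vz
                dn = math.sqrt(dx * dx + dy * dy + dz * dz)
                dx, dy, dz = dx / dn, dy / dn, dz / dn

        # flush per-history buffer (merge duplicate voxels for exact sq sums)
        if nbuf > 0:
            order = np.argsort(buf_idx[:nbuf])
            a = 0
            while a < nbuf:
                vi = buf_idx[order[a]]
                tot = buf_dep[order[a]]
                b = a + 1
                while b < nbuf and buf_idx[order[b]] == vi:
                    tot += buf_dep[order[b]]
                    b += 1
                dose[vi] += tot
                dose_sq[vi] += tot * tot
                a = b

    return launched, deposited, escaped, nuclear_lost, n_exit, n_stopped, n_nuclear, n_missed


def transport_in_phantom(
    states: ProtonState,
    phantom: Phantom,
    dose: DoseGrid | None = None,
    seed: int = 0,
    physics: TransportPhysics = TransportPhysics(),
    model: mat.RangeEnergyModel = mat.DEFAULT_MODEL,
) -> DoseGrid:
    """Transport a batch of protons, accumulating into ``dose``.

    ``dose`` defaults to a grid matching the phantom.  Repeated calls with
    the same grid accumulate (histories add up).  The kernel RNG is seeded
    with ``seed``; identical inputs give bit-identical results.
    """
    if dose is None:
        dose = DoseGrid.for_phantom(phantom)
    rsp_tab, rho_tab, x0_tab = phantom.property_tables()
    override = (
        np.ascontiguousarray(phantom.density_override, dtype=np.float64).ravel()
        if phantom.density_override is not None
        else np.empty(0, dtype=np.float64)
    )
    out = _kernel(
        np.ascontiguousarray(states.position, dtype=np.float64),
        np.ascontiguousarray(states.direction, dtype=np.float64),
        np.ascontiguousarray(states.kinetic_energy, dtype=np.float64),
        np.ascontiguousarray(states.alive),
        np.asarray(phantom.origin, dtype=np.float64),
        np.asarray(phantom.voxel_size, dtype=np.float64),
        np.asarray(phantom.shape, dtype=np.int64),
        phantom.material_ids.ravel(),
        rsp_tab,
        rho_tab,
        x0_tab,
        override,
        np.asarray(dose.origin, dtype=np.float64),
        np.asarray(dose.voxel_size, dtype=np.float64),
        np.asarray(dose.shape, dtype=np.int64),
        dose.energy_deposit.reshape(-1),
        dose.energy_deposit_sq.reshape(-1),
        model.alpha,
        model.p,
        physics.energy_cutoff,
        mat.LOW_ENERGY_CAP_MEV,
        physics.max_step,
        physics.range_fraction,
        physics.straggling_coefficient,
        physics.nuclear_lambda,
        physics.nuclear_local_fraction,
        int(seed) % (2**32),
    )
    launched, deposited, escaped, nuclear_lost, n_exit, n_stopped, n_nuclear, n_missed = out
    dose.histories += int(states.alive.sum())
    acc = dose.accounting
    for key, val in (
        ("launched_mev", launched),
        ("deposited_mev", deposited),
        ("escaped_mev", escaped),
        ("nuclear_nonlocal_mev", nuclear_lost),
        ("n_exited", n_exit),
        ("n_stopped", n_stopped),
        ("n_nuclear", n_nuclear),
        ("n_missed_grid", n_missed),
    ):
        acc[key] = acc.get(key, 0.0) + val
    return dose


def estimate_uncertainty(dose: DoseGrid, region_threshold: float = 0.5):
    """Mean relative standard error of the mean dose over the high-dose region.

    Per-voxel SEM from the per-history sum and sum-of-squares; the region
    is all voxels above ``region_threshold`` of the maximum deposit.
    Returns ``(region_value, per_voxel_array)``.
    """
    n = dose.histories
    if n < 2:
        raise ValueError("need at least 2 histories")
    dep = dose.energy_deposit
    if dep.max() <= 0:
        raise ValueError("dose grid is empty; cannot estimate uncertainty")
    mean = dep / n
    var = (dose.energy_deposit_sq / n - mean**2) * n / (n - 1)
    var = np.clip(var, 0.0, None)
    sem = np.sqrt(var / n)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(mean > 0, sem / mean, np.nan)
    mask = dep >= region_threshold * dep.max()
    if not mask.any():
        raise ValueError("no voxels in the requested region")
    return float(np.nanmean(rel[mask])), rel
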