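"""Dose-analysis surface: curve extraction, SOBP metrics, penumbra, gamma.

Conventions (configurable where noted):

* clinical range  = depth of the distal 90% dose level (``r90``);
* modulation      = distal r90 minus proximal r90;
* flatness        = half peak-to-peak of the plateau, as a percentage of
  the plateau mean, over ``[proximal r90 + margin, distal r90 - margin]``;
* the "2% or 2 mm" comparison is operationalized as the standard gamma
  index with global dose normalization and a 10% low-dose threshold.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "Curve1D",
    "SOBPMetrics",
    "depth_dose",
    "integrated_depth_dose",
    "lateral_profile",
    "distal_metrics",
    "penumbra_80_20",
    "gamma_pass_rate",
    "gamma_pass_rate_grid",
]


@dataclass(frozen=True)
class Curve1D:
    """A sampled 1D dose curve: strictly increasing coordinate (cm) vs value."""

    coordinate: np.ndarray
    value: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.coordinate, dtype=float)
        v = np.asarray(self.value, dtype=float)
        if c.ndim != 1 or v.shape != c.shape:
            raise ValueError("coordinate and value must be 1D arrays of equal length")
        if c.size < 2:
            raise ValueError("curve needs at least 2 points")
        if np.any(np.diff(c) <= 0):
            raise ValueError("coordinates must be strictly increasing")
        object.__setattr__(self, "coordinate", c)
        object.__setattr__(self, "value", v)

    def scaled(self, factor: float) -> "Curve1D":
        return Curve1D(self.coordinate, self.value * factor)

    def to_csv(self, path: str | Path, header: tuple[str, str] = ("coordinate_cm", "value")) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(header)
            w.writerows(zip(self.coordinate, self.value))

    @classmethod
    def from_csv(cls, path: str | Path) -> "Curve1D":
        data = np.genfromtxt(path, delimiter=",", skip_header=1)
        return cls(data[:, 0], data[:, 1])


@dataclass(frozen=True)
class SOBPMetrics:
    """Depth-dose figures of merit; distal crossings satisfy r90 <= r80 <= r20."""

    r90: float
    r80: float
    r20: float
    distal_falloff_80_20: float
    proximal_r90: float
    modulation: float
    flatness: float


# ---------------------------------------------------------------------------
# curve extraction from dose grids
# ---------------------------------------------------------------------------

def _slice_indices(grid, lo: float, hi: float, axis: int) -> slice:
    o = grid.origin[axis]
    d = grid.voxel_size[axis]
    n = grid.shape[axis]
    i0 = int(np.floor((lo - o) / d))
    i1 = int(np.ceil((hi - o) / d))
    if i0 < 0 or i1 > n or i0 >= i1:
        raise ValueError(
            f"requested region [{lo}, {hi}] cm exceeds grid extent "
            f"[{o}, {o + n * d}] on axis {axis}"
        )
    return slice(i0, i1)


def _normalize(depth: np.ndarray, dose: np.ndarray, mode: str) -> np.ndarray:
    if mode == "none" or dose.max() <= 0:
        return dose
    if mode == "max":
        return 100.0 * dose / dose.max()
    if mode == "plateau":
        # plateau mean between the proximal and distal 90% crossings of the
        # max-normalized curve, with a 0.5 cm guard on each side
        v = 100.0 * dose / dose.max()
        try:
            d90 = _distal_crossing(depth, v, 90.0)
            p90 = _proximal_crossing(depth, v, 90.0)
        except ValueError:
            return v
        lo, hi = p90 + 0.5, d90 - 0.5
        sel = (depth >= lo) & (depth <= hi)
        if sel.sum() < 2:
            return v
        return 100.0 * v / v[sel].mean()
    raise ValueError(f"unknown normalization {mode!r}")


def depth_dose(
    dose_grid,
    axis_region: tuple[float, float, float, float] = (-0.5, 0.5, -0.5, 0.5),
    normalize: str = "plateau",
    smooth_window: int | None = None,
) -> Curve1D:
    """Laterally averaged dose vs depth inside an axial box.

    ``axis_region`` is ``(x_lo, x_hi, y_lo, y_hi)`` in cm.  Depth is
    measured from the grid entry face (z origin).  Normalization:
    ``"plateau"`` (plateau mean = 100, SOBP convention), ``"max"``
    (max = 100, pristine convention) or ``"none"``.  ``smooth_window``
    applies a light Savitzky-Golay filter (odd window, order 2) before
    normalization, standard practice for noisy measured curves.
    """
    xs = _slice_indices(dose_grid, axis_region[0], axis_region[1], 0)
    ys = _slice_indices(dose_grid, axis_region[2], axis_region[3], 1)
    dep = dose_grid.energy_deposit[xs, ys, :].mean(axis=(0, 1))
    if smooth_window:
        from scipy.signal import savgol_filter

        dep = np.clip(savgol_filter(dep, smooth_window, 2), 0.0, None)
    depth = (np.arange(dose_grid.shape[2]) + 0.5) * dose_grid.voxel_size[2]
    return Curve1D(depth, _normalize(depth, dep, normalize))


def integrated_depth_dose(
    dose_grid, normalize: str = "plateau", smooth_window: int | None = None
) -> Curve1D:
    """Laterally *integrated* energy deposit per depth slice.

    Independent of lateral scatter; this is the quantity compared against
    the analytic depth-dose oracle.
    """
    dep = dose_grid.energy_deposit.sum(axis=(0, 1))
    if smooth_window:
        from scipy.signal import savgol_filter

        dep = np.clip(savgol_filter(dep, smooth_window, 2), 0.0, None)
    depth = (np.arange(dose_grid.shape[2]) + 0.5) * dose_grid.voxel_size[2]
    return Curve1D(depth, _normalize(depth, dep, normalize))


def lateral_profile(
    dose_grid,
    depth: float,
    direction: str = "x",
    averaging_halfwidth: float = 0.5,
    normalize: bool = True,
) -> Curve1D:
    """Dose vs off-axis position at ``depth`` (cm from entry face).

    Averaged over ``+-averaging_halfwidth`` cm in the other lateral axis
    and over the depth voxel; normalized to central-axis value = 100.
    """
    iz = int(np.floor(depth / dose_grid.voxel_size[2]))
    if iz < 0 or iz >= dose_grid.shape[2]:
        raise ValueError(f"depth {depth} cm is outside the dose grid")
    if direction not in ("x", "y"):
        raise ValueError("direction must be 'x' or 'y'")
    main, other = (0, 1) if direction == "x" else (1, 0)
    os_ = _slice_indices(dose_grid, -averaging_halfwidth, averaging_halfwidth, other)
    if direction == "x":
        block = dose_grid.energy_deposit[:, os_, iz]
        prof = block.mean(axis=1)
    else:
        block = dose_grid.energy_deposit[os_, :, iz]
        prof = block.mean(axis=0)
    pos = dose_grid.origin[main] + (np.arange(dose_grid.shape[main]) + 0.5) * dose_grid.voxel_size[main]
    if normalize:
        i0 = int(np.argmin(np.abs(pos)))
        centre = prof[max(i0 - 1, 0): i0 + 2].mean()
        if centre <= 0:
            raise ValueError("central-axis dose is zero; cannot normalize")
        prof = 100.0 * prof / centre
    return Curve1D(pos, prof)


# ---------------------------------------------------------------------------
# threshold crossings
# ---------------------------------------------------------------------------

def _interp_crossing(x0, v0, x1, v1, level):
    return x0 + (level - v0) * (x1 - x0) / (v1 - v0)


def _distal_crossing(coord: np.ndarray, value: np.ndarray, level: float) -> float:
    """Deepest downward crossing of ``level`` (scan from the distal end)."""
    above = np.nonzero(value >= level)[0]
    if above.size == 0:
        raise ValueError(f"curve never reaches the {level}% level")
    i = above[-1]
    if i == value.size - 1:
        raise ValueError(f"curve never falls below {level}% on the distal side")
    return _interp_crossing(coord[i], value[i], coord[i + 1], value[i + 1], level)


def _proximal_crossing(coord: np.ndarray, value: np.ndarray, level: float) -> float:
    """Upward crossing of ``level`` contiguous with the plateau: scan
    backward from the curve maximum to the first sample below the level.

    Robust when the entrance dose hovers near the threshold (large
    modulation/range ratios); pinned to the first sample when the curve
    stays at or above the level all the way to the surface.
    """
    if value.max() < level:
        raise ValueError(f"curve never reaches the {level}% level")
    ipk = int(np.argmax(value))
    below = np.nonzero(value[: ipk + 1] < level)[0]
    if below.size == 0:
        return float(coord[0])
    i = below[-1]
    return _interp_crossing(coord[i], value[i], coord[i + 1], value[i + 1], level)


def distal_metrics(curve: Curve1D, plateau_margin: float = 0.5) -> SOBPMetrics:
    """SOBP range/modulation/falloff/flatness from a depth-dose curve.

    The curve is internally renormalized so the plateau mean is 100
    (robust to noise spikes), then distal 90/80/20 and proximal 90
    crossings are located by linear interpolation.
    """
    depth = curve.coordinate
    v = np.asarray(curve.value, dtype=float)
    if v.max() <= 0:
        raise ValueError("curve has no positive dose")
    v = 100.0 * v / v.max()
    d90 = _distal_crossing(depth, v, 90.0)
    p90 = _proximal_crossing(depth, v, 90.0)
    lo, hi = p90 + plateau_margin, d90 - plateau_margin
    sel = (depth >= lo) & (depth <= hi)
    if sel.sum() >= 2:
        v = 100.0 * v / v[sel].mean()
        d90 = _distal_crossing(depth, v, 90.0)
        p90 = _proximal_crossing(depth, v, 90.0)
        lo, hi = p90 + plateau_margin, d90 - plateau_margin
        sel = (depth >= lo) & (depth <= hi)
    d80 = _distal_crossing(depth, v, 80.0)
    d20 = _distal_crossing(depth, v, 20.0)
    if sel.sum() >= 2:
        pl = v[sel]
        flat = 100.0 * 0.5 * (pl.max() - pl.min()) / pl.mean()
    else:
        flat = float("nan")
    return SOBPMetrics(
        r90=float(d90),
        r80=float(d80),
        r20=float(d20),
        distal_falloff_80_20=float(d20 - d80),
        proximal_r90=float(p90),
        modulation=float(d90 - p90),
        flatness=float(flat),
    )


def penumbra_80_20(profile: Curve1D) -> tuple[float, float]:
    """Left and right 80%-to-20% penumbra widths of a lateral profile.

    Thresholds are percentages of the profile maximum; crossings found by
    linear interpolation on the outer shoulders.
    """
    x = profile.coordinate
    v = 100.0 * np.asarray(profile.value, float) / profile.value.max()
    ipk = int(np.argmax(v))

    def shoulder(side: str, level: float) -> float:
        if side == "left":
            seg_x, seg_v = x[: ipk + 1], v[: ipk + 1]
            above = np.nonzero(seg_v >= level)[0]
            if above.size == 0 or above[0] == 0:
                raise ValueError(f"left shoulder never crosses {level}%")
            i = above[0]
            return _interp_crossing(seg_x[i - 1], seg_v[i - 1], seg_x[i], seg_v[i], level)
        seg_x, seg_v = x[ipk:], v[ipk:]
        above = np.nonzero(seg_v >= level)[0]
        if above[-1] == seg_v.size - 1:
            raise ValueError(f"right shoulder never crosses {level}%")
        i = above[-1]
        return _interp_crossing(seg_x[i], seg_v[i], seg_x[i + 1], seg_v[i + 1], level)

    left = abs(shoulder("left", 80.0) - shoulder("left", 20.0))
    right = abs(shoulder("right", 80.0) - shoulder("right", 20.0))
    return float(left), float(right)


# ---------------------------------------------------------------------------
# gamma index
# ---------------------------------------------------------------------------

def gamma_pass_rate(
    reference: Curve1D,
    evaluated: Curve1D,
    dose_tol: float = 2.0,
    dta_mm: float = 2.0,
    threshold: float = 10.0,
) -> float:
    """Global-normalization 1D gamma pass rate (percent).

    Dose differences are taken relative to the reference maximum;
    evaluated points where the reference (interpolated to the same
    coordinate) is below ``threshold`` percent of its max are excluded.
    The reference is resampled at dta/10 for a near-continuous DTA search.
    """
    ref_x, ref_v = reference.coordinate, np.asarray(reference.value, float)
    ev_x, ev_v = evaluated.coordinate, np.asarray(evaluated.value, float)
    lo = max(ref_x[0], ev_x[0])
    hi = min(ref_x[-1], ev_x[-1])
    if lo >= hi:
        raise ValueError("reference and evaluated curves do not overlap")
    dta_cm = dta_mm / 10.0
    fine_x = np.arange(ref_x[0], ref_x[-1] + dta_cm / 20.0, dta_cm / 10.0)
    fine_v = np.interp(fine_x, ref_x, ref_v)
    dmax = ref_v.max()
    if dmax <= 0:
        raise ValueError("reference has no positive dose")

    sel = (ev_x >= lo) & (ev_x <= hi)
    ev_x, ev_v = ev_x[sel], ev_v[sel]
    ref_at = np.interp(ev_x, ref_x, ref_v)
    keep = ref_at >= threshold / 100.0 * dmax
    if not np.any(keep):
        raise ValueError("no evaluated points above the low-dose threshold")
    ev_x, ev_v = ev_x[keep], ev_v[keep]

    dd = (ev_v[:, None] - fine_v[None, :]) / (dose_tol / 100.0 * dmax)
    dx = (ev_x[:, None] - fine_x[None, :]) / dta_cm
    gamma2 = np.min(dd * dd + dx * dx, axis=1)
    return float(100.0 * np.mean(gamma2 <= 1.0))


def gamma_pass_rate_grid(
    reference,
    evaluated,
    dose_tol: float = 2.0,
    dta_mm: float = 2.0,
    threshold: float = 10.0,
) -> float:
    """3D gamma pass rate between two dose grids with identical geometry.

    Brute-force DTA search over voxel shifts within ``2 * dta``.
    """
    if reference.shape != evaluated.shape or not np.allclose(
        reference.voxel_size, evaluated.voxel_size
    ) or not np.allclose(reference.origin, evaluated.origin):
        raise ValueError("grids must share geometry for the 3D gamma")
    ref = np.asarray(reference.energy_deposit, float)
    ev = np.asarray(evaluated.energy_deposit, float)
    dmax = ref.max()
    if dmax <= 0:
        raise ValueError("reference has no positive dose")
    dta_cm = dta_mm / 10.0
    vox = np.asarray(reference.voxel_size, float)
    reach = np.maximum((2 * dta_cm / vox).astype(int), 0)
    mask = ref >= threshold / 100.0 * dmax
    if not mask.any():
        raise ValueError("no voxels above the low-dose threshold")
    gamma2 = np.full(ref.shape, np.inf)
    for sx in range(-reach[0], reach[0] + 1):
        for sy in range(-reach[1], reach[1] + 1):
            for sz in range(-reach[2], reach[2] + 1):
                dist2 = ((sx * vox[0]) ** 2 + (sy * vox[1]) ** 2 + (sz * vox[2]) ** 2) / dta_cm**2
                if dist2 > 4.0 + 1e-12:
                    continue
                shifted = np.roll(ref, (sx, sy, sz), axis=(0, 1, 2))
                dd2 = ((ev - shifted) / (dose_tol / 100.0 * dmax)) ** 2
                np.minimum(gamma2, dd2 + dist2, out=gamma2)
    return float(100.0 * np.mean(gamma2[mask] <= 1.0))
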