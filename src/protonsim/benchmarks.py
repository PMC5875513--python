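"""Self-contained benchmark configurations used for acceptance checking.

Each function commissions/loads everything it needs, runs the simulation
and measures the reported quantity from scratch; nothing is cached or
looked up.  All randomness flows from the ``seed`` argument.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import materials as mat
from . import oracle
from . import source_model as sm
from .beamline import Aperture
from .fixtures import make_stair_compensator, make_water_tank
from .metrics import (
    Curve1D,
    SOBPMetrics,
    depth_dose,
    distal_metrics,
    gamma_pass_rate,
    integrated_depth_dose,
)
from .pipeline import commission_source_mc, measure_sobp, run_beam
from .transport import DoseGrid, ProtonState, transport_in_phantom

__all__ = ["sobp_water_benchmark", "stair_compensator_benchmark", "oracle_benchmark"]

#: analysis box (cm) for laterally averaged depth dose; the commissioning
#: fields are >= 25 cm wide so a 10 cm box is well inside the flat region
ANALYSIS_BOX = (-7.0, 7.0, -7.0, 7.0)
SMOOTH_WINDOW = 7


@dataclass
class SOBPBenchmark:
    source: sm.SourceModel
    curve: Curve1D
    metrics: SOBPMetrics
    histories: int
    region_uncertainty: float


def sobp_water_benchmark(
    nominal_range: float,
    nominal_modulation: float,
    seed: int,
    histories: int = 200_000,
    verify_histories: int = 150_000,
) -> SOBPBenchmark:
    """Commission a beam and measure its SOBP in the 40 cm water tank.

    1 mm axial scoring; depth dose laterally averaged over a 10x10 cm box
    inside the 25 cm diameter commissioning aperture.
    """
    source = commission_source_mc(
        nominal_range, nominal_modulation, seed=seed, verify_histories=verify_histories
    )
    tank = make_water_tank(side=40.0, voxel=1.0)
    aperture = Aperture(shape="circle", radius=12.5)
    result = run_beam(
        source,
        tank,
        histories=histories,
        seed=seed + 1,
        scoring_voxel=(0.4, 0.4, 0.1),
        aperture=aperture,
    )
    metrics, curve = measure_sobp(result.dose, ANALYSIS_BOX)
    from .transport import estimate_uncertainty

    region, _ = estimate_uncertainty(result.dose)
    return SOBPBenchmark(source, curve, metrics, histories, region)


@dataclass
class StairBenchmark:
    distal_edge_depth: float
    plane_minus_edge: float  # 11.7 cm plane to the distal edge
    histories: int


def stair_compensator_benchmark(
    seed: int,
    histories: int = 300_000,
    source: sm.SourceModel | None = None,
) -> StairBenchmark:
    """Fig-4 beam through the stair compensator; distal edge behind the
    5.2 cm Lucite step (ray box x in [4.8, 6.6], |y| <= 1.5).

    The SOBP behind that step is fully modulated (plateau reaches the
    surface), so the distal edge is located as the distal 90% crossing —
    the stable operationalization of "the Bragg peak" there.
    """
    if source is None:
        source = commission_source_mc(15.2, 10.0, seed=seed, verify_histories=150_000)
    tank = make_water_tank(side=40.0, voxel=1.0)
    aperture = Aperture(shape="circle", radius=6.5)
    compensator = make_stair_compensator()
    result = run_beam(
        source,
        tank,
        histories=histories,
        seed=seed + 2,
        scoring_voxel=(0.4, 0.4, 0.1),
        aperture=aperture,
        compensator=compensator,
    )
    curve = depth_dose(result.dose, (4.8, 6.6, -1.5, 1.5), smooth_window=SMOOTH_WINDOW)
    edge = distal_metrics(curve).r90
    return StairBenchmark(edge, 11.7 - edge, histories)


@dataclass
class OracleBenchmark:
    gamma: float
    mc_r90: float
    oracle_r90: float
    pristine_peak_depth: float
    pristine_csda_range: float
    histories: int


def oracle_benchmark(seed: int, histories: int = 200_000) -> OracleBenchmark:
    """Transport engine vs the analytic oracle in matched geometry.

    The oracle models a 1D CSDA beam in water, so the MC uses a foil-free
    near-parallel beam; the laterally integrated depth dose is compared
    with gamma(2%/2mm, 10% threshold), and a near-monoenergetic pencil
    beam checks the pristine-peak depth against the range-energy model.
    """
    source = sm.commission_source(8.0, 5.0, foil_thickness=0.0, angular_spread=0.05)
    tank = make_water_tank(side=40.0, voxel=1.0)
    result = run_beam(
        source, tank, histories=histories, seed=seed + 3, scoring_voxel=(0.5, 0.5, 0.1)
    )
    mc_curve = integrated_depth_dose(result.dose, smooth_window=SMOOTH_WINDOW)
    zsel = mc_curve.coordinate < 11.0
    mc = Curve1D(mc_curve.coordinate[zsel], mc_curve.value[zsel])
    ana = oracle.sobp_analytic(source.layers, mc.coordinate)
    plateau = (ana.coordinate > 3.5) & (ana.coordinate < 7.5)
    ref = Curve1D(ana.coordinate, 100.0 * ana.value / ana.value[plateau].mean())
    gamma = gamma_pass_rate(ref, mc, dose_tol=2.0, dta_mm=2.0, threshold=10.0)

    e0 = 102.7
    n = min(histories, 100_000)
    state = ProtonState(
        position=np.tile([0.0, 0.0, -1.0], (n, 1)),
        direction=np.tile([0.0, 0.0, 1.0], (n, 1)),
        kinetic_energy=np.full(n, e0),
    )
    dose = DoseGrid((-10.0, -10.0, 0.0), (0.5, 0.5, 0.1), (40, 40, 120))
    transport_in_phantom(state, tank, dose, seed=seed + 4)
    dd = dose.energy_deposit.sum(axis=(0, 1))
    peak = float(dose.depth_coordinates()[np.argmax(dd)])

    return OracleBenchmark(
        gamma=gamma,
        mc_r90=distal_metrics(mc).r90,
        oracle_r90=distal_metrics(ref).r90,
        pristine_peak_depth=peak,
        pristine_csda_range=mat.range_from_energy(e0),
        histories=histories,
    )
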