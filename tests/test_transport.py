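import numpy as np
import pytest

from protonsim import materials as mat
from protonsim.fixtures import make_water_tank
from protonsim.transport import (
    DoseGrid,
    Phantom,
    ProtonState,
    TransportPhysics,
    estimate_uncertainty,
    highland_sigma,
    step_length,
    transport_in_phantom,
)

from conftest import pencil_state


class TestHighland:
    def test_thin_slab_100mev(self):
        # 14.1/pv * sqrt(0.01) * (1 + log10(0.01)/9), pv = 190.37 MeV
        assert highland_sigma(100.0, 0.3608, 36.08) == pytest.approx(5.76e-3, rel=0.01)

    def test_2mm_lead_100mev(self):
        x = 0.2 * 11.35
        assert highland_sigma(100.0, x, 6.37) == pytest.approx(0.042, rel=0.01)

    def test_zero_path(self):
        assert highland_sigma(100.0, 0.0, 36.08) == 0.0

    def test_monotone_in_path(self):
        x = np.linspace(0.01, 10, 200)
        sig = highland_sigma(100.0, x, 36.08)
        assert np.all(np.diff(sig) > 0)

    def test_decreases_with_energy(self):
        assert highland_sigma(50.0, 1.0, 36.08) > highland_sigma(200.0, 1.0, 36.08)


class TestStepLength:
    def test_range_fraction_bound(self, small_tank):
        # residual range 0.05 cm water, fraction 0.2 -> step <= 0.01
        e = mat.energy_from_range(0.05)
        st = pencil_state(1, energy=e, z=-1.0)
        st.position[0] = [0.05, 0.05, 5.05]
        s = step_length(st, small_tank)
        assert s <= 0.0100001

    def test_max_step_mid_voxel(self, small_tank):
        st = pencil_state(1, energy=150.0)
        st.position[0] = [0.05, 0.05, 5.2]  # far from the next z boundary
        assert step_length(st, small_tank) == pytest.approx(0.1)

    def test_boundary_clamp(self, small_tank):
        st = pencil_state(1, energy=150.0)
        st.position[0] = [0.05, 0.05, 5.95]  # 0.05 cm from the z=6 boundary
        assert step_length(st, small_tank) == pytest.approx(0.05)

    def test_dead_state_raises(self, small_tank):
        st = pencil_state(1, energy=150.0)
        st.alive[0] = False
        with pytest.raises(ValueError):
            step_length(st, small_tank)


class TestTransport:
    def test_energy_conservation_closes(self, pencil_dose):
        acc = pencil_dose.accounting
        closure = (
            acc["launched_mev"]
            - acc["deposited_mev"]
            - acc["escaped_mev"]
            - acc["nuclear_nonlocal_mev"]
        )
        assert abs(closure) <= 1e-6 * acc["launched_mev"]

    def test_deposited_not_exceeding_launched(self, pencil_dose):
        acc = pencil_dose.accounting
        assert acc["deposited_mev"] <= acc["launched_mev"]

    def test_bragg_peak_depth(self, pencil_dose):
        dd = pencil_dose.energy_deposit.sum(axis=(0, 1))
        z = pencil_dose.depth_coordinates()
        peak = z[np.argmax(dd)]
        assert 7.8 <= peak <= 8.0

    def test_lateral_symmetry(self, small_tank):
        # symmetric broad source in homogeneous water -> symmetric profile
        rng = np.random.default_rng(21)
        n = 40_000
        x = rng.uniform(-2.0, 2.0, n // 2)
        st = ProtonState(
            position=np.column_stack(
                [np.concatenate([x, -x]), np.zeros(n), np.full(n, -1.0)]
            ),
            direction=np.tile([0.0, 0.0, 1.0], (n, 1)),
            kinetic_energy=np.full(n, 102.7),
        )
        dose = DoseGrid((-10, -10, 0), (0.5, 0.5, 0.5), (40, 40, 20))
        transport_in_phantom(st, small_tank, dose, seed=22)
        lateral = dose.energy_deposit.sum(axis=(1, 2))
        left, right = lateral[:20], lateral[20:][::-1]
        big = (left + right) > 0.02 * lateral.max()
        rel_asym = np.abs(left - right)[big] / (left + right)[big]
        assert np.all(rel_asym < 0.05)

    def test_seed_determinism_bitwise(self, small_tank):
        grids = []
        for _ in range(2):
            dose = DoseGrid((-10, -10, 0), (1.0, 1.0, 0.1), (20, 20, 110))
            transport_in_phantom(pencil_state(5000), small_tank, dose, seed=77)
            grids.append(dose)
        assert np.array_equal(grids[0].energy_deposit, grids[1].energy_deposit)
        assert np.array_equal(grids[0].energy_deposit_sq, grids[1].energy_deposit_sq)

    def test_different_seed_differs(self, small_tank):
        grids = []
        for seed in (1, 2):
            dose = DoseGrid((-10, -10, 0), (1.0, 1.0, 0.1), (20, 20, 110))
            transport_in_phantom(pencil_state(2000), small_tank, dose, seed=seed)
            grids.append(dose)
        assert not np.array_equal(grids[0].energy_deposit, grids[1].energy_deposit)

    def test_falloff_widens_with_energy_sigma(self, small_tank):
        from protonsim.metrics import Curve1D, distal_metrics

        widths = []
        rng = np.random.default_rng(0)
        for sigma in (0.2, 0.8, 1.6):
            n = 30_000
            st = pencil_state(n)
            st.kinetic_energy = st.kinetic_energy + sigma * rng.standard_normal(n)
            dose = DoseGrid((-10, -10, 0), (1.0, 1.0, 0.1), (20, 20, 110))
            transport_in_phantom(st, small_tank, dose, seed=5)
            dd = dose.energy_deposit.sum(axis=(0, 1))
            m = distal_metrics(Curve1D(dose.depth_coordinates(), dd))
            widths.append(m.distal_falloff_80_20)
        assert widths[0] < widths[1] < widths[2]

    def test_proton_exiting_grid_counted(self, small_tank):
        st = pencil_state(100, energy=250.0)  # range ~39 cm > 20 cm tank
        dose = DoseGrid((-10, -10, 0), (1.0, 1.0, 0.5), (20, 20, 40))
        transport_in_phantom(st, small_tank, dose, seed=1)
        assert dose.accounting["n_exited"] > 0
        assert dose.accounting["escaped_mev"] > 0

    def test_miss_grid_entirely(self, small_tank):
        st = pencil_state(10)
        st.position[:, 0] = 100.0  # far outside laterally
        dose = DoseGrid((-10, -10, 0), (1.0, 1.0, 0.5), (20, 20, 40))
        transport_in_phantom(st, small_tank, dose, seed=1)
        assert dose.accounting["n_missed_grid"] == 10
        assert dose.energy_deposit.sum() == 0.0

    def test_density_override_shortens_range(self):
        ids = np.zeros((10, 10, 60), dtype=np.uint8)
        dense = Phantom(
            origin=(-5, -5, 0),
            voxel_size=(1.0, 1.0, 0.5),
            material_ids=ids,
            material_names=("water",),
            density_override=np.full((10, 10, 60), 1.5),
        )
        plain = Phantom((-5, -5, 0), (1.0, 1.0, 0.5), ids.copy(), ("water",))
        peaks = []
        for ph in (plain, dense):
            dose = DoseGrid((-5, -5, 0), (1.0, 1.0, 0.1), (10, 10, 120))
            transport_in_phantom(pencil_state(5000, energy=120.0), ph, dose, seed=3)
            dd = dose.energy_deposit.sum(axis=(0, 1))
            peaks.append(dose.depth_coordinates()[np.argmax(dd)])
        assert peaks[1] == pytest.approx(peaks[0] / 1.5, rel=0.05)


class TestUncertainty:
    def test_hand_computed_sem(self):
        # single voxel, per-history deposits {1, 1, 2} MeV
        grid = DoseGrid((0, 0, 0), (1, 1, 1), (1, 1, 1))
        grid.energy_deposit[0, 0, 0] = 4.0
        grid.energy_deposit_sq[0, 0, 0] = 6.0
        grid.histories = 3
        region, per_voxel = estimate_uncertainty(grid)
        assert region == pytest.approx(0.25, rel=1e-9)

    def test_identical_deposits_zero_uncertainty(self):
        grid = DoseGrid((0, 0, 0), (1, 1, 1), (1, 1, 1))
        grid.energy_deposit[0, 0, 0] = 50.0  # 10 histories x 5 MeV
        grid.energy_deposit_sq[0, 0, 0] = 250.0
        grid.histories = 10
        region, _ = estimate_uncertainty(grid)
        assert region == pytest.approx(0.0, abs=1e-12)

    def test_sqrt_n_scaling(self, small_tank):
        # quadrupling histories halves the region uncertainty within 20%
        uncs = []
        for n in (5_000, 20_000):
            dose = DoseGrid((-10, -10, 0), (0.5, 0.5, 0.2), (40, 40, 55))
            transport_in_phantom(pencil_state(n), small_tank, dose, seed=8)
            region, _ = estimate_uncertainty(dose)
            uncs.append(region)
        assert uncs[0] / uncs[1] == pytest.approx(2.0, rel=0.2)

    def test_empty_region_raises(self):
        grid = DoseGrid((0, 0, 0), (1, 1, 1), (2, 2, 2))
        grid.histories = 5
        with pytest.raises(ValueError):
            estimate_uncertainty(grid)

    def test_single_history_raises(self):
        grid = DoseGrid((0, 0, 0), (1, 1, 1), (1, 1, 1))
        grid.energy_deposit[0, 0, 0] = 1.0
        grid.histories = 1
        with pytest.raises(ValueError):
            estimate_uncertainty(grid)


class TestDoseGridIO:
    def test_hdf5_roundtrip(self, pencil_dose, tmp_path):
        path = tmp_path / "dose.h5"
        pencil_dose.to_hdf5(path, provenance={"seed": 1234})
        back = DoseGrid.from_hdf5(path)
        np.testing.assert_array_equal(back.energy_deposit, pencil_dose.energy_deposit)
        assert back.histories == pencil_dose.histories
        assert back.accounting["launched_mev"] == pytest.approx(
            pencil_dose.accounting["launched_mev"]
        )

    def test_invalid_state_vectors_rejected(self):
        with pytest.raises(ValueError):
            ProtonState(
                position=np.zeros((2, 3)),
                direction=np.array([[0, 0, 2.0], [0, 0, 1.0]]),
                kinetic_energy=np.array([100.0, 100.0]),
            )
        with pytest.raises(ValueError):
            ProtonState(
                position=np.zeros((1, 3)),
                direction=np.array([[0, 0, 1.0]]),
                kinetic_energy=np.array([-5.0]),
            )
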