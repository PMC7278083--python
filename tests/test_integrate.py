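"""Runge-Kutta steppers, pilot controller and the parallel contract."""

import numpy as np
import pytest

import misoflux as mf
from misoflux.integrate import cash_karp_step, rk4_step


class _Scalar:
    """dy/dt = -y as a one-block cascade (for stepper unit checks)."""

    dim = 1
    n_blocks = 1

    def initial_state(self):
        return np.array([1.0])

    def rhs(self, x, t=0.0):
        return -x

    def block_rhs(self, i, x):
        return -x

    def block_parents(self, i):
        return []

    def block_indices(self, i):
        return np.arange(1)

    def row_labels(self):
        return [{"metabolite": "y", "emu_atoms": "1", "weight": 0}]


class _Constant:
    """dy/dt = c: both embedded orders are exact, error estimate 0."""

    dim = 1
    n_blocks = 1

    def rhs(self, x, t=0.0):
        return np.array([2.5])

    def block_rhs(self, i, x):
        return np.array([2.5])

    def block_parents(self, i):
        return []

    def block_indices(self, i):
        return np.arange(1)


class TestRK4Step:
    def test_scalar_decay_matches_rk4_polynomial(self):
        y1 = rk4_step(_Scalar(), np.array([1.0]), 0.0, 0.1)
        expect = 1 - 0.1 + 0.005 - 0.1**3 / 6 + 0.1**4 / 24
        assert abs(y1[0] - expect) < 1e-15

    def test_zero_derivative_leaves_state(self):
        model = mf.toy_model(labeled_fraction=0.0)
        targets = [mf.EMU("F", (1, 2, 3, 4))]
        net = mf.trace_emus(model, targets)
        _, part = mf.decompose(net, targets, lam=1)
        system = mf.assemble(part, net, model)
        x = system.initial_state()
        assert np.allclose(rk4_step(system, x, 0.0, 0.01), x, atol=1e-15)

    def test_fourth_order_convergence_on_single_pool(self):
        from conftest import single_pool_model

        v, c = 10.0, 5.0  # turnover 0.5 s: errors well above roundoff
        model = single_pool_model(v=v, c=c)
        targets = [mf.EMU("P", (1,))]
        net = mf.trace_emus(model, targets)
        _, part = mf.decompose(net, targets, lam=1)
        system = mf.assemble(part, net, model)
        m1 = [i for i, n in enumerate(system.nodes) if n.weight == 1][0]
        errs = []
        for h in (0.4, 0.2, 0.1):
            traj = mf.integrate_constant(system, h, 2.0)
            exact = 1.0 - np.exp(-(v / c) * traj.times[-1])
            errs.append(abs(traj.final()[m1] - exact))
        orders = [np.log2(errs[i] / errs[i + 1]) for i in range(2)]
        assert all(3.5 < p < 4.6 for p in orders)

    def test_nonfinite_state_aborts(self):
        class Bad(_Scalar):
            def rhs(self, x, t=0.0):
                return np.array([np.inf])

        with pytest.raises(FloatingPointError):
            rk4_step(Bad(), np.array([1.0]), 0.0, 0.1)


class TestCashKarpStep:
    def test_error_estimate_fifth_order(self):
        hs = [0.4, 0.2, 0.1]
        errs = []
        for h in hs:
            _, err = cash_karp_step(_Scalar(), np.array([1.0]), 0.0, h)
            errs.append(err[0])
        orders = [np.log2(errs[i] / errs[i + 1]) for i in range(2)]
        assert all(4.5 < p < 5.5 for p in orders)

    def test_constant_derivative_zero_error(self):
        y, err = cash_karp_step(_Constant(), np.array([0.0]), 0.0, 0.3)
        # both embedded orders are exact; only tableau roundoff survives
        assert abs(err[0]) < 1e-15
        assert abs(y[0] - 0.75) < 1e-15

    def test_rejection_shrinks_by_quarter_power(self):
        ctrl = mf.StepController()
        ratio = 16.0
        assert np.isclose(ctrl.next_h_reject(1.0, ratio), 0.9 * 16 ** (-0.25))


class TestConstantStep:
    def test_unlabeled_substrate_stays_unlabeled(self):
        model = mf.toy_model(labeled_fraction=0.0)
        targets = [mf.EMU("F", (1, 2, 3, 4))]
        net = mf.trace_emus(model, targets)
        _, part = mf.decompose(net, targets, lam=1)
        system = mf.assemble(part, net, model)
        traj = mf.integrate_constant(system, 0.05, 2.0)
        m0_rows = [i for i, n in enumerate(system.nodes) if n.weight == 0]
        assert np.allclose(traj.states[:, m0_rows], 1.0, atol=1e-12)

    def test_f_m4_rises_monotonically_toward_one(self, toy_system, toy_trajectory):
        m4 = toy_system.node_index[
            mf.MassIsotopomerNode(mf.EMU("F", (1, 2, 3, 4)), 4)
        ]
        vals = toy_trajectory.states[:, m4]
        assert np.all(np.diff(vals) >= -1e-12)
        assert vals[0] == 0.0 and vals[-1] > 0.4

    def test_mid_sums_conserved(self, toy_trajectory):
        report = mf.conservation_report(toy_trajectory)
        assert report.max_mid < 1e-9

    def test_final_partial_step(self, single_pool):
        _, system = single_pool
        traj = mf.integrate_constant(system, 0.3, 1.0)
        assert np.isclose(traj.times[-1], 1.0)
        assert np.isclose(traj.steps[-1], 0.1)


class TestPilotController:
    def test_toy_pilots_are_the_four_weight0_singletons(
        self, toy_partition, toy_system
    ):
        pilot = mf.pilot_controller(toy_partition, toy_system)
        names = {str(toy_system.nodes[i]) for i in pilot}
        assert names == {"B_12.m0", "C_12.m0", "E_12.m0", "F_1234.m0"}

    def test_single_metabolite_model_has_one_pilot(self, single_pool):
        model, system = single_pool
        pilot = mf.pilot_controller(system.partition, system)
        assert len(pilot) == 1

    def test_every_pruned_metabolite_covered(self, generated_cases):
        for model, targets, network, partition in generated_cases:
            system = mf.assemble(partition, network, model)
            pilot = mf.pilot_controller(partition, system)
            covered = {system.nodes[i].emu.metabolite for i in pilot}
            assert covered == set(system.met_rows)


class TestAdaptive:
    def test_tracks_dense_reference_with_fewer_steps(
        self, toy_system, toy_partition, toy_dense_reference
    ):
        pilot = mf.pilot_controller(toy_partition, toy_system)
        ctrl = mf.StepController(pilot=pilot)
        at = mf.integrate_adaptive(toy_system, ctrl, 10.0, h0=0.005)
        ref = toy_dense_reference.sample(at.times)
        assert np.abs(at.states - ref).max() <= 1e-5
        assert at.accepted < 10.0 / 0.005

    def test_tighter_tolerance_reduces_deviation(
        self, toy_system, toy_partition, toy_dense_reference
    ):
        pilot = mf.pilot_controller(toy_partition, toy_system)
        dense = toy_dense_reference

        def max_dev(scale):
            ctrl = mf.StepController(
                tol_scaling=1e-9 * scale, tol_addition=1e-7 * scale, pilot=pilot
            )
            at = mf.integrate_adaptive(toy_system, ctrl, 10.0, h0=0.005)
            return np.abs(at.states - dense.sample(at.times)).max()

        assert max_dev(0.01) < max_dev(1.0)

    def test_step_underflow_aborts(self):
        class Stiff(_Scalar):
            def rhs(self, x, t=0.0):
                return -1e12 * x

            def block_rhs(self, i, x):
                return -1e12 * x

        ctrl = mf.StepController(h_min=1e-6)
        with pytest.raises(RuntimeError, match="underflow"):
            mf.integrate_adaptive(Stiff(), ctrl, 1.0, h0=0.5, x0=[1.0])


class TestParallelContract:
    def test_single_worker_equals_serial(self, toy_system, toy_trajectory):
        par = mf.run_parallel(toy_system, 1, mode="constant", step=0.005, t_end=10.0)
        assert np.array_equal(par.states, toy_trajectory.states)

    @pytest.mark.parametrize("workers", [2, 4])
    def test_multiworker_bitwise_identical(
        self, toy_system, toy_trajectory, workers
    ):
        par = mf.run_parallel(
            toy_system, workers, mode="constant", step=0.005, t_end=10.0
        )
        assert np.array_equal(par.states, toy_trajectory.states)
        assert np.array_equal(par.times, toy_trajectory.times)

    @pytest.mark.parametrize("workers", [1, 2, 4])
    def test_adaptive_h_sequence_worker_independent(
        self, toy_system, toy_partition, workers
    ):
        pilot = mf.pilot_controller(toy_partition, toy_system)
        serial = mf.integrate_adaptive(
            toy_system, mf.StepController(pilot=pilot), 10.0, h0=0.005
        )
        par = mf.run_parallel(
            toy_system,
            workers,
            mode="adaptive",
            step=0.005,
            t_end=10.0,
            controller=mf.StepController(pilot=pilot),
        )
        assert np.array_equal(par.steps, serial.steps)
        assert np.array_equal(par.states, serial.states)

    def test_deadlock_watchdog_names_blocked_block(self, toy_system):
        from misoflux.integrate import RK4, _CascadeScheduler

        class LostDelivery(_CascadeScheduler):
            """Simulates a parent whose stage values are never delivered."""

            def _ready(self, task, done):
                if task == (0, 1):
                    return False
                return super()._ready(task, done)

        sched = LostDelivery(toy_system, 2)
        x = toy_system.initial_state()
        with pytest.raises(RuntimeError, match="deadlock.*block 0"):
            sched.stages(x, 0.0, 0.005, RK4)


class TestTrajectoryIO:
    def test_long_format_csv(self, tmp_path, single_pool):
        _, system = single_pool
        traj = mf.integrate_constant(system, 0.1, 1.0)
        path = tmp_path / "traj.csv"
        traj.write_csv(path)
        import pandas as pd

        df = pd.read_csv(path)
        assert set(df.columns) == {"time", "metabolite", "emu_atoms", "weight", "value"}
        assert len(df) == len(traj.times) * system.dim

    def test_hdf5_round_trip(self, tmp_path, single_pool):
        _, system = single_pool
        traj = mf.integrate_constant(system, 0.1, 1.0)
        path = tmp_path / "traj.h5"
        traj.write_hdf5(path)
        import h5py

        with h5py.File(path) as fh:
            assert np.array_equal(fh["states"][...], traj.states)
            assert np.array_equal(fh["times"][...], traj.times)
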