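"""Isotope balance right-hand sides: convolution, tensors, backends."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import misoflux as mf
from misoflux.ode_assembly import build_eliminating_matrix, build_transition_tensor

from conftest import make_generated


class TestConvolveMid:
    def test_unlabeled_times_unlabeled(self):
        assert np.allclose(mf.convolve_mid([1, 0], [1, 0]), [1, 0, 0])

    def test_binomial(self):
        assert np.allclose(
            mf.convolve_mid([0.5, 0.5], [0.5, 0.5]), [0.25, 0.5, 0.25]
        )

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        a=st.lists(st.floats(0, 1), min_size=3, max_size=3),
        b=st.lists(st.floats(0, 1), min_size=4, max_size=4),
    )
    def test_matches_double_loop_oracle(self, a, b):
        c = mf.convolve_mid(a, b)
        expected = np.zeros(len(a) + len(b) - 1)
        for u, au in enumerate(a):
            for v, bv in enumerate(b):
                expected[u + v] += au * bv
        assert np.allclose(c, expected, atol=1e-12)


class TestTransitionTensor:
    def test_unimolecular_is_weight_identity(self, toy_network):
        er = next(
            r for r in toy_network.reactions
            if len(r.reactant_emus) == 1 and str(r.product_emu) == "C_12"
        )
        entries = build_transition_tensor(er)
        assert entries == {(0, 0): 1, (1, 1): 1, (2, 2): 1}

    def test_bimolecular_weights_add(self, toy_model):
        net = mf.trace_emus(toy_model, [mf.EMU("D", (1, 2, 3, 4))])
        er = next(r for r in net.reactions if len(r.reactant_emus) == 2)
        entries = build_transition_tensor(er)
        assert entries[(1, 1, 2)] == 1
        assert (1, 1, 3) not in entries

    def test_exactly_one_product_per_reactant_tuple(self, toy_model):
        net = mf.trace_emus(toy_model, [mf.EMU("D", (1, 2, 3, 4))])
        er = next(r for r in net.reactions if len(r.reactant_emus) == 2)
        entries = build_transition_tensor(er)
        from itertools import product

        for tup in product(range(3), range(3)):
            hits = [j for (i1, i2, j) in entries if (i1, i2) == tup]
            assert hits == [sum(tup)]


class TestEliminatingMatrix:
    def test_all_consumed_gives_minus_identity(self, toy_model, toy_partition):
        # V_5 consumes C: on any block of C mass isotopomers E = -I
        v5 = toy_model.reaction("V_5")
        c_nodes = [
            s.members for s in toy_partition.sccs
            if s.members[0].emu.metabolite == "C"
        ]
        for members in c_nodes:
            E = build_eliminating_matrix(members, v5)
            assert np.array_equal(E, -np.eye(len(members)))

    def test_partial_consumption_diagonal(self, toy_model, toy_partition):
        part = mf.aggregate_lambda(toy_partition, 4)
        block = part.sccs[0].members  # weight-0 nodes of B, C, E, F
        v5 = toy_model.reaction("V_5")  # consumes C and E only
        E = build_eliminating_matrix(block, v5)
        expect = np.diag([
            -1.0 if n.emu.metabolite in ("C", "E") else 0.0 for n in block
        ])
        assert np.array_equal(E, expect)


class TestRhs:
    def test_unlabeled_substrate_is_fixed_point(self):
        model = mf.toy_model(labeled_fraction=0.0)
        targets = [mf.EMU("F", (1, 2, 3, 4))]
        net = mf.trace_emus(model, targets)
        _, part = mf.decompose(net, targets, lam=1)
        system = mf.assemble(part, net, model)
        assert np.allclose(system.rhs(system.initial_state()), 0.0, atol=1e-14)

    def test_first_reachable_nodes_gain_weight(self, toy_system):
        """With fully labeled A and an all-m0 state, positive derivative
        appears exactly on B m2 (one V_1 step from the input) and on the m0
        nodes' own losses."""
        x = toy_system.initial_state()
        dx = toy_system.rhs(x)
        gaining = {
            str(toy_system.nodes[i]) for i in np.nonzero(dx > 1e-12)[0]
        }
        assert gaining == {"B_12.m2"}

    def test_derivative_weight_sums_vanish(self, toy_system):
        """Flux balance makes per-EMU weight sums of the derivative zero."""
        rng = np.random.default_rng(42)
        rows = toy_system.emu_rows()
        for _ in range(100):
            x = rng.random(toy_system.dim)
            # normalize each EMU to sum 1
            for _, (w, ix) in rows.items():
                x[ix] /= x[ix].sum()
            dx = toy_system.rhs(x)
            for _, (w, ix) in rows.items():
                assert abs(dx[ix].sum()) < 1e-12

    def test_stationary_state_is_equilibrium(self, toy_system, toy_network):
        stat = mf.stationary_solution(toy_network)
        x = np.empty(toy_system.dim)
        for emu, (w, ix) in toy_system.emu_rows().items():
            x[ix] = stat[emu][w]
        assert np.abs(toy_system.rhs(x)).max() < 1e-12

    def test_single_pool_step_response(self, single_pool):
        model, system = single_pool
        traj = mf.integrate_constant(system, 0.005, 10.0)
        v, c = 10.0, 40.0
        m1_row = [i for i, n in enumerate(system.nodes) if n.weight == 1][0]
        expect = 1.0 - np.exp(-(v / c) * traj.times)
        assert np.abs(traj.states[:, m1_row] - expect).max() < 1e-12

    def test_missing_pool_size_names_metabolite(self, toy_network, toy_partition):
        model = mf.toy_model()
        del model.pool_sizes["E"]
        with pytest.raises(mf.ModelError, match="E"):
            mf.assemble(toy_partition, toy_network, model)


class TestBackendEquivalence:
    def test_toy_random_states(self, toy_system, toy_system_tensor):
        rng = np.random.default_rng(7)
        for _ in range(100):
            x = rng.random(toy_system.dim)
            dv = toy_system.rhs(x)
            dt = toy_system_tensor.rhs(x)
            assert np.abs(dv - dt).max() < 1e-12

    def test_generated_random_states(self, generated_cases):
        rng = np.random.default_rng(11)
        for model, targets, network, partition in generated_cases:
            sv = mf.assemble(partition, network, model, backend="vector")
            st_ = mf.assemble(partition, network, model, backend="tensor")
            for _ in range(100):
                x = rng.random(sv.dim)
                assert np.abs(sv.rhs(x) - st_.rhs(x)).max() < 1e-12


class TestLinearity:
    def test_affine_without_bimolecular_reactions(self):
        spec = mf.GeneratorSpec(
            n_metabolites=5, seed=3, bimolecular_fraction=0.0,
            pool_range=(10.0, 100.0),
        )
        model = mf.random_network(spec)
        targets = [mf.EMU(m, a) for m, a in model.measured_targets]
        net = mf.trace_emus(model, targets)
        _, part = mf.decompose(net, targets, lam=1)
        system = mf.assemble(part, net, model)
        rng = np.random.default_rng(0)
        x, y = rng.random(system.dim), rng.random(system.dim)
        a, b = 0.3, 0.7
        lhs = system.rhs(a * x + b * y)
        rhs_ = a * system.rhs(x) + b * system.rhs(y) + (1 - a - b) * system.rhs(
            np.zeros(system.dim)
        )
        assert np.abs(lhs - rhs_).max() < 1e-12

    def test_internal_matrices_stable(self, toy_system):
        for i in range(toy_system.n_blocks):
            eig = np.linalg.eigvals(toy_system.internal_matrix(i))
            assert np.all(eig.real < 0)


class TestAggregatedAssembly:
    def test_lambda_aggregation_preserves_dynamics(
        self, toy_network, toy_targets, toy_model, toy_system
    ):
        _, part10 = mf.decompose(toy_network, toy_targets, lam=10)
        agg = mf.assemble(part10, toy_network, toy_model)
        t_ref = mf.integrate_constant(toy_system, 0.01, 2.0)
        t_agg = mf.integrate_constant(agg, 0.01, 2.0)
        ix = [toy_system.node_index[n] for n in agg.nodes]
        assert np.abs(t_agg.states - t_ref.states[:, ix]).max() < 1e-13


def test_bundle_serialization_round_trip(tmp_path, toy_system):
    path = tmp_path / "system.json"
    toy_system.save_bundle(path)
    import json

    doc = json.loads(path.read_text())
    assert doc["backend"] == "vector"
    assert len(doc["nodes"]) == toy_system.dim
    assert len(doc["blocks"]) == toy_system.n_blocks
    assert doc["convolutions"]  # toy has bimolecular V_5
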