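import numpy as np
import pandas as pd
import pytest
from scipy import stats

from turingrmt import KGrid
from turingrmt.hill_models import (
    DEFAULT_BOUNDS,
    HillParams,
    Topology,
    example_topology,
    find_steady_states,
    jacobian,
    lhs_sample,
    load_topology,
    rhs,
    save_topology,
    screen_models,
)


def _params(n, rng, topo=None):
    K = rng.uniform(0.05, 1.0, (n, n))
    return HillParams(
        b=rng.uniform(0.01, 0.1, n),
        V=rng.uniform(0.5, 5.0, n),
        mu=rng.uniform(0.1, 1.0, n),
        K=K,
        n=np.full((n, n), 2.0),
    )


class TestTopology:
    def test_entries_validated(self):
        with pytest.raises(ValueError):
            Topology(np.array([[2, 0], [0, 0]]))

    def test_yaml_round_trip(self, tmp_path):
        topo = example_topology(3)
        path = tmp_path / "topo.yaml"
        save_topology(topo, path)
        back = load_topology(path)
        np.testing.assert_array_equal(back.adjacency, topo.adjacency)
        assert back.names == topo.names

    def test_packaged_topologies_load(self):
        from importlib import resources

        base = resources.files("turingrmt") / "data" / "topologies"
        for name in (
            "activator_inhibitor_2node.yaml",
            "three_node_immobile.yaml",
            "four_node_immobile.yaml",
        ):
            topo = load_topology(base / name)
            assert topo.n_nodes in (2, 3, 4)


class TestRhs:
    def test_unregulated_node_linear_decay(self):
        topo = Topology(np.zeros((1, 1), dtype=int))
        p = HillParams(b=[1.0], V=[1.0], mu=[0.5], K=[[1.0]], n=[[2.0]])
        assert rhs(topo, p, np.array([2.0]))[0] == pytest.approx(0.0)
        assert rhs(topo, p, np.array([1.0]))[0] == pytest.approx(0.5)

    def test_half_saturation(self):
        # one activator exactly at threshold: Hill factor 1/2
        topo = Topology([[0, 1], [0, 0]])
        p = HillParams(b=[0.1, 0.1], V=[2.0, 2.0], mu=[1.0, 1.0],
                       K=np.full((2, 2), 0.5), n=np.full((2, 2), 2.0))
        x = np.array([1.0, 0.5])
        f = rhs(topo, p, x)
        assert f[0] == pytest.approx(0.1 + 2.0 * 0.5 - 1.0)

    def test_activator_and_repressor_at_threshold(self):
        # both regulators half-saturated: production term V/4
        topo = Topology([[0, 1, -1], [0, 0, 0], [0, 0, 0]])
        p = HillParams(b=[0.1] * 3, V=[4.0] * 3, mu=[1.0] * 3,
                       K=np.full((3, 3), 0.5), n=np.full((3, 3), 2.0))
        x = np.array([1.0, 0.5, 0.5])
        assert rhs(topo, p, x)[0] == pytest.approx(0.1 + 1.0 - 1.0)

    def test_nonpositive_concentration_rejected(self):
        topo = example_topology(2)
        p = _params(2, np.random.default_rng(0))
        with pytest.raises(ValueError):
            rhs(topo, p, np.array([1.0, 0.0]))


class TestJacobian:
    def test_unregulated_diagonal_is_minus_mu(self):
        topo = Topology(np.zeros((1, 1), dtype=int))
        p = HillParams(b=[1.0], V=[1.0], mu=[0.5], K=[[1.0]], n=[[2.0]])
        assert jacobian(topo, p, np.array([3.0]))[0, 0] == pytest.approx(-0.5)

    def test_absent_edge_is_structural_zero(self, rng):
        topo = example_topology(3)
        p = _params(3, rng)
        J = jacobian(topo, p, rng.uniform(0.2, 2.0, 3))
        assert J[2, 1] == 0.0  # node 2 does not regulate node 3
        assert J[2, 2] == pytest.approx(-p.mu[2])

    def test_matches_finite_differences(self, rng):
        topo = example_topology(4)
        p = _params(4, rng)
        x = rng.uniform(0.1, 3.0, 4)
        J = jacobian(topo, p, x)
        h = 1e-6
        Jfd = np.zeros((4, 4))
        for j in range(4):
            dx = np.zeros(4)
            dx[j] = h * x[j]
            Jfd[:, j] = (rhs(topo, p, x + dx) - rhs(topo, p, x - dx)) / (2 * h * x[j])
        assert np.abs(J - Jfd).max() < 1e-5


class TestSteadyStates:
    def test_single_linear_node(self):
        topo = Topology(np.zeros((1, 1), dtype=int))
        p = HillParams(b=[1.0], V=[1.0], mu=[0.5], K=[[1.0]], n=[[2.0]])
        ss = find_steady_states(topo, p, seed=0)
        assert len(ss) == 1
        assert ss.states[0][0] == pytest.approx(2.0, abs=1e-9)
        assert max(ss.residuals) < 1e-9

    def test_duplicate_roots_merged(self):
        topo = Topology(np.zeros((2, 2), dtype=int))
        p = HillParams(b=[1.0, 2.0], V=[1.0, 1.0], mu=[0.5, 0.5],
                       K=np.ones((2, 2)), n=np.full((2, 2), 2.0))
        ss = find_steady_states(topo, p, n_guesses=10, seed=1)
        assert len(ss) == 1  # linear system: all guesses converge to one root
        assert ss.n_converged == 10

    def test_bistable_self_activator_against_scan(self):
        # brute-force 1-D sign-change scan is the root-count oracle
        topo = Topology([[1]])
        p = HillParams(b=[0.05], V=[1.0], mu=[1.0], K=[[0.5]], n=[[2.0]])
        xs = np.linspace(1e-4, 20.0, 400_001)
        f = 0.05 + xs**2 / (xs**2 + 0.25) - xs
        n_roots = int(np.sum(np.diff(np.sign(f)) != 0))
        ss = find_steady_states(topo, p, n_guesses=64, seed=2)
        assert len(ss) == n_roots

    def test_residuals_below_tolerance(self, rng):
        topo = example_topology(3)
        found = 0
        for seed in range(5):
            p = _params(3, np.random.default_rng(seed))
            ss = find_steady_states(topo, p, seed=seed)
            found += len(ss)
            assert all(r < 1e-9 for r in ss.residuals)
            assert all((s > 0).all() for s in ss.states)
        assert found > 0


class TestLHS:
    def test_one_sample_per_log_bin(self):
        batch = lhs_sample(n_samples=10, seed=0, topology=example_topology(2))
        lo, hi = DEFAULT_BOUNDS["V"]
        u = (np.log(batch.V[:, 0]) - np.log(lo)) / (np.log(hi) - np.log(lo))
        bins = np.floor(u * 10).astype(int)
        assert sorted(bins) == list(range(10))

    def test_bounds_respected(self):
        batch = lhs_sample(n_samples=200, seed=1, topology=example_topology(3))
        for name, arr in (("V", batch.V), ("b", batch.b), ("mu", batch.mu)):
            lo, hi = DEFAULT_BOUNDS[name]
            assert arr.min() >= lo and arr.max() <= hi
        assert (batch.n == 2.0).all()

    def test_marginal_matches_loguniform(self):
        batch = lhs_sample(n_samples=10_000, seed=2,
                           topology=example_topology(2))
        lo, hi = DEFAULT_BOUNDS["mu"]
        u = (np.log(batch.mu[:, 1]) - np.log(lo)) / (np.log(hi) - np.log(lo))
        assert stats.kstest(u, "uniform").statistic < 0.05

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            lhs_sample(bounds={**DEFAULT_BOUNDS, "V": (10.0, 0.1)},
                       n_samples=5)


class TestScreen:
    def test_empty_request_gives_empty_records(self):
        rec = screen_models(example_topology(2), n_samples=0, seed=0)
        assert len(rec) == 0
        assert list(rec.columns) == ["set_id", "state_id", "i", "j", "value",
                                     "klass"]

    def test_record_schema_and_structural_elements(self, coarse_grid, tmp_path):
        topo = example_topology(2)
        out = tmp_path / "rec.csv"
        rec = screen_models(topo, n_samples=400, seed=5, k_grid=coarse_grid,
                            out_path=out)
        assert out.exists()
        assert len(rec) > 0
        # per steady state: one record per structural element (4 for the
        # fully-connected 2-node topology incl. diagonal)
        per_state = rec.groupby(["set_id", "state_id"]).size()
        assert (per_state == 4).all()
        # degradation keeps the inhibitor self-element negative
        assert (rec[(rec.i == 1) & (rec.j == 1)]["value"] < 0).all()
        back = pd.read_csv(out)
        assert len(back) == len(rec)

    def test_multistable_sets_emit_multiple_states(self, coarse_grid):
        rec = screen_models(example_topology(2), n_samples=1500, seed=11,
                            k_grid=coarse_grid)
        states_per_set = rec.groupby("set_id")["state_id"].nunique()
        assert states_per_set.max() >= 2
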