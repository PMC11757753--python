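import numpy as np
import pytest

from turingrmt import (
    DiagonalMode,
    DiffusionSpec,
    EnsembleSpec,
    InstabilityClass,
    KGrid,
    classify,
    classify_batch,
    dispersion_relation,
    jacobian_at_k,
    sample_jacobians,
)
from turingrmt.dispersion import (
    CLASS_NAMES,
    DispersionResult,
    classify_batch_adaptive,
)


class TestKGrid:
    def test_default_grid_matches_protocol(self):
        g = KGrid()
        k = g.k_values
        assert k[0] == 0.0 and k[-1] == 10.0
        assert len(k) == 1001
        assert np.diff(k) == pytest.approx(0.01)

    def test_step_must_divide_range(self):
        with pytest.raises(ValueError):
            KGrid(k_max=10.0, step=0.3)


class TestJacobianAtK:
    def test_direct_arithmetic(self):
        j0 = np.array([[-1.0, 2.0], [-2.0, -1.0]])
        out = jacobian_at_k(j0, DiffusionSpec(1, 10), 1.0)
        np.testing.assert_array_equal(out, [[-2.0, 2.0], [-2.0, -11.0]])

    def test_k_zero_is_identity_operation(self, rng, diff):
        j0 = rng.normal(size=(4, 4))
        np.testing.assert_array_equal(jacobian_at_k(j0, diff, 0.0), j0)

    def test_immobile_nodes_untouched(self, diff):
        out = jacobian_at_k(-np.eye(3), diff, 2.0)
        np.testing.assert_array_equal(out, np.diag([-5.0, -41.0, -1.0]))

    def test_rejects_nonsquare(self, diff):
        with pytest.raises(ValueError):
            jacobian_at_k(np.zeros((2, 3)), diff, 1.0)


class TestDispersionRelation:
    def test_immobile_eigenvalue_dominates(self, diff):
        # -I with one immobile node: leading branch pinned at -1 for all k
        res = dispersion_relation(-np.eye(3), diff, KGrid(step=0.1))
        np.testing.assert_allclose(res.lead_real, -1.0, atol=1e-12)

    def test_two_fully_diffusing_nodes(self, diff):
        # -I with both nodes diffusing: leading branch -1 - k^2 * min(D)
        grid = KGrid(step=0.1)
        res = dispersion_relation(-np.eye(2), diff, grid)
        np.testing.assert_allclose(res.lead_real, -1.0 - grid.k_values**2,
                                   rtol=1e-12)

    def test_trace_identity_along_grid(self, rng, diff):
        # sum of eigenvalues of J(k) = -N - k^2 (D1 + D2) at every k
        spec = EnsembleSpec(n_nodes=8, sigma2=0.2)
        j0 = sample_jacobians(spec, 1, rng)[0]
        grid = KGrid(step=0.25)
        for k in grid.k_values:
            s = np.linalg.eigvals(jacobian_at_k(j0, diff, k)).sum().real
            ref = -8.0 - k**2 * 11.0
            assert s == pytest.approx(ref, rel=1e-8)


def _result(lead_real, lead_imag=None, k_max=10.0):
    lr = np.asarray(lead_real, dtype=float)
    li = np.zeros_like(lr) if lead_imag is None else np.asarray(lead_imag, float)
    k = np.linspace(0.0, k_max, len(lr))
    return DispersionResult(k_values=k, lead_real=lr, lead_imag=li)


class TestClassifyLogic:
    def test_unstable_without_diffusion(self):
        res = _result([0.5, -1.0, -1.0, -1.0])
        assert classify(res) is InstabilityClass.UNSTABLE_WITHOUT_DIFFUSION

    def test_marginal_k0_counts_as_unstable(self):
        res = _result([0.0, -1.0, -1.0])
        assert classify(res) is InstabilityClass.UNSTABLE_WITHOUT_DIFFUSION

    def test_stable_everywhere(self):
        res = _result([-0.5, -0.2, -0.3, -0.9])
        assert classify(res) is InstabilityClass.STABLE

    def test_turing_one_interior_peak(self):
        res = _result([-0.5, 0.4, 0.1, -0.9])
        assert classify(res) is InstabilityClass.TURING_I
        assert res.k_peak == res.k_values[1]

    def test_turing_two_positive_at_grid_end(self):
        res = _result([-0.5, 0.1, 0.3, 0.4])
        assert classify(res) is InstabilityClass.TURING_II

    def test_hopf_takes_precedence(self):
        res = _result([-0.5, 0.4, 0.1, -0.9], lead_imag=[0, 0.7, 0, 0])
        assert classify(res) is InstabilityClass.TURING_HOPF

    def test_nan_dispersion_flagged(self):
        from turingrmt.dispersion import FlaggedSampleError

        res = _result([-0.5, np.nan, 0.1, -0.9])
        with pytest.raises(FlaggedSampleError):
            classify(res)


class TestClassifyEnsembleProperties:
    def test_two_node_fixed_diagonal_never_turing(self, diff, coarse_grid):
        # determinant argument: N=2 with -1 diagonals admits no Turing class
        spec = EnsembleSpec(n_nodes=2, sigma2=0.5, seed=21)
        j = sample_jacobians(spec, 3000)
        codes, flagged = classify_batch(j, diff, coarse_grid)
        assert not flagged.any()
        names = {CLASS_NAMES[c] for c in codes}
        assert names <= {"stable", "unstable_without_diffusion"}

    def test_antisymmetric_never_turing(self, diff, coarse_grid):
        # eigenvalues of the antisymmetric part are purely imaginary; the -1
        # diagonal shifts them left, so no positive real part at any k
        for n in (3, 6, 10):
            spec = EnsembleSpec(n_nodes=n, sigma2=0.8,
                                diagonal_mode=DiagonalMode.ANTISYMMETRIC_FIXED,
                                seed=n)
            j = sample_jacobians(spec, 500)
            codes, _ = classify_batch(j, diff, coarse_grid)
            names = {CLASS_NAMES[c] for c in codes}
            assert names <= {"stable", "unstable_without_diffusion"}
            # in fact the symmetric part is negative definite: always stable
            assert names == {"stable"}

    def test_fixed_seed_three_node_turing_one(self, diff):
        # rejection-sample the first Turing-I matrix at fixed seed, then
        # confirm the class on a 10x denser grid
        spec = EnsembleSpec(n_nodes=3, sigma2=4.0 / 3.0, seed=2024)
        j = sample_jacobians(spec, 4000)
        codes, _ = classify_batch(j, diff, KGrid(step=0.01))
        hits = np.flatnonzero(codes == CLASS_NAMES.index("turing_I"))
        assert hits.size > 0
        j0 = j[hits[0]]
        res = dispersion_relation(j0, diff, KGrid(step=0.001))
        assert classify(res) is InstabilityClass.TURING_I
        assert res.lead_real[0] < 0
        assert res.lead_real.max() > 0
        assert res.lead_real[-1] < 0

    def test_classification_invariant_under_diffuser_swap(self, diff, coarse_grid):
        # relabeling the two diffusers while swapping (D1, D2) is a
        # permutation similarity: classes must agree sample by sample
        spec = EnsembleSpec(n_nodes=5, sigma2=0.45, seed=8)
        j = sample_jacobians(spec, 400)
        perm = np.array([1, 0, 2, 3, 4])
        j_swapped = j[:, perm][:, :, perm]
        codes_a, _ = classify_batch(j, diff, coarse_grid)
        codes_b, _ = classify_batch(j_swapped, diff.swapped(), coarse_grid)
        np.testing.assert_array_equal(codes_a, codes_b)

    def test_adaptive_matches_full_grid(self, diff):
        # the coarse-screen-plus-refine classifier must reproduce the
        # single-pass full-grid classification on a near-critical ensemble
        spec = EnsembleSpec(n_nodes=5, sigma2=0.34, seed=77)
        j = sample_jacobians(spec, 600)
        grid = KGrid(step=0.01)
        full, _ = classify_batch(j, diff, grid)
        adaptive, _ = classify_batch_adaptive(j, diff, grid)
        np.testing.assert_array_equal(full, adaptive)

    def test_immobile_block_is_large_k_asymptote(self, rng, diff):
        from turingrmt.dispersion import immobile_block_lead_real

        spec = EnsembleSpec(n_nodes=6, sigma2=0.3)
        for j0 in sample_jacobians(spec, 20, rng):
            res = dispersion_relation(j0, diff, KGrid(step=0.5))
            limit = immobile_block_lead_real(j0)
            assert res.lead_real[-1] == pytest.approx(limit, abs=0.02)
        assert immobile_block_lead_real(-np.eye(2)) == -np.inf

    def test_grid_refinement_stability(self, diff):
        # halving the k step changes the class of at most 1% of samples
        spec = EnsembleSpec(n_nodes=5, sigma2=1.05**2 / 5, seed=31)
        j = sample_jacobians(spec, 1000)
        c1, _ = classify_batch(j, diff, KGrid(step=0.1))
        c2, _ = classify_batch(j, diff, KGrid(step=0.05))
        assert (c1 != c2).mean() <= 0.01
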