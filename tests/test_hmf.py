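"""HMF basis identities, projections, and network identification."""

import numpy as np
import pandas as pd
import pytest

from organet import hmf
from organet.design import toy_design
from organet.synthetic import (TrajectorySet, generate_ground_truth_network,
                               make_normalized_dataset, simulate_trajectories)


class TestBasis:
    @pytest.mark.parametrize("M,N", [(1, 2), (4, 2), (8, 3), (12, 5)])
    def test_boundary_identities(self, M, N):
        basis = hmf.hmf_basis(M=M, N=N, T=16.0, n_grid=513)
        assert np.max(np.abs(basis.phi[:, 0])) < 1e-10
        assert np.max(np.abs(basis.phi[:, -1])) < 1e-10
        assert np.max(np.abs(basis.dphi[:, 0])) < 1e-10
        assert np.max(np.abs(basis.dphi[:, -1])) < 1e-10

    def test_analytic_derivative_matches_finite_difference(self):
        basis = hmf.hmf_basis(M=6, N=3, T=16.0, n_grid=4097)
        h = basis.t[1] - basis.t[0]
        p = basis.phi
        # fourth-order central stencil on interior points
        num = (p[:, :-4] - 8 * p[:, 1:-3] + 8 * p[:, 3:-1] - p[:, 4:]) / (12 * h)
        assert np.max(np.abs(num - basis.dphi[:, 2:-2])) < 1e-6

    def test_order_below_two_rejected(self):
        with pytest.raises(ValueError, match="N must be >= 2"):
            hmf.hmf_basis(M=4, N=1, T=16.0)


class TestProjection:
    def test_zero_signal_zero_moments(self):
        basis = hmf.hmf_basis(M=5, N=3, T=16.0, n_grid=257)
        m, dm = hmf.project(basis, np.zeros((3, 257)))
        assert np.all(m == 0) and np.all(dm == 0)

    def test_exponential_integration_by_parts(self):
        """For E = e^{0.1 t}, dE/dt = 0.1 E, so the derivative moments
        must equal 0.1 x the moments."""
        basis = hmf.hmf_basis(M=8, N=3, T=16.0, n_grid=257)
        E = np.exp(0.1 * basis.t)[None, :]
        m, dm = hmf.project(basis, E)
        assert np.max(np.abs(dm - 0.1 * m)) < 1e-4

    def test_spectral_path_agrees_with_trapezoid(self):
        basis = hmf.hmf_basis(M=8, N=3, T=16.0, n_grid=257)
        rng = np.random.default_rng(0)
        # smooth signal: random low-order polynomial + slow exponential
        E = np.vstack([np.polyval(rng.standard_normal(4), basis.t / 16.0)
                       + np.exp(-0.1 * basis.t) for _ in range(4)])
        m1, dm1 = hmf.project(basis, E, method="trapezoid")
        m2, dm2 = hmf.project(basis, E, method="hartley")
        assert np.max(np.abs(m1 - m2)) / np.max(np.abs(m1)) < 1e-6
        assert np.max(np.abs(dm1 - dm2)) / np.max(np.abs(dm1)) < 1e-6

    def test_grid_mismatch_raises(self):
        basis = hmf.hmf_basis(M=4, N=2, T=16.0, n_grid=257)
        dense = hmf.DenseTrajectories(t=np.linspace(0, 8, 129),
                                      values=np.zeros((1, 129)),
                                      labels=[("o", "g")])
        with pytest.raises(ValueError, match="grid mismatch"):
            hmf.project(basis, dense)


class TestScalingAndInterpolation:
    def test_minmax_by_hand(self):
        idx = pd.MultiIndex.from_tuples([("o", "g")])
        traj = TrajectorySet(times=np.array([8.0, 10, 12, 16, 24]),
                             values=pd.DataFrame(
                                 [[2.0, 4.0, 6.0, 8.0, 10.0]], index=idx))
        scaled, params = hmf.minmax_scale(traj)
        assert np.allclose(scaled.values.iloc[0], [0, 0.25, 0.5, 0.75, 1.0])
        assert params.iloc[0]["min"] == 2.0 and params.iloc[0]["max"] == 10.0

    def test_constant_node_flagged_at_half(self):
        idx = pd.MultiIndex.from_tuples([("o", "g")])
        traj = TrajectorySet(times=np.array([8.0, 12.0, 16.0]),
                             values=pd.DataFrame([[3.0, 3.0, 3.0]], index=idx))
        scaled, params = hmf.minmax_scale(traj)
        assert np.allclose(scaled.values.iloc[0], 0.5)
        assert bool(params.iloc[0]["constant"])

    def test_monotone_input_stays_monotone(self):
        idx = pd.MultiIndex.from_tuples([("o", "g")])
        traj = TrajectorySet(times=np.array([8.0, 10, 12, 16, 24]),
                             values=pd.DataFrame(
                                 [[1.0, 1.5, 2.0, 5.0, 9.0]], index=idx))
        scaled, _ = hmf.minmax_scale(traj)
        assert (np.diff(scaled.values.iloc[0]) > 0).all()

    def test_spline_reproduces_linear_data(self):
        idx = pd.MultiIndex.from_tuples([("o", "g")])
        times = np.array([8.0, 10, 12, 16, 24])
        traj = TrajectorySet(times=times,
                             values=pd.DataFrame([0.05 * (times - 8.0)],
                                                 index=idx))
        dense = hmf.interpolate_dense(traj, n_grid=101, clip=None)
        assert np.max(np.abs(dense.values[0] - 0.05 * dense.t)) < 1e-10

    def test_endpoints_equal_input(self):
        idx = pd.MultiIndex.from_tuples([("o", "g")])
        traj = TrajectorySet(times=np.array([8.0, 10, 12, 16, 24]),
                             values=pd.DataFrame([[0.1, 0.9, 0.3, 0.6, 0.2]],
                                                 index=idx))
        dense = hmf.interpolate_dense(traj, n_grid=65)
        assert dense.values[0, 0] == pytest.approx(0.1, abs=1e-12)
        assert dense.values[0, -1] == pytest.approx(0.2, abs=1e-12)


class TestRegression:
    def test_scalar_exponential_rate_recovered(self):
        basis = hmf.hmf_basis(M=8, N=3, T=16.0, n_grid=257)
        E = np.exp(0.1 * basis.t)[None, :]
        m, dm = hmf.project(basis, E)
        sys = hmf.assemble_regression(m, dm, target=0, labels=[("o", "g")])
        k, *_ = np.linalg.lstsq(sys.A, sys.b, rcond=None)
        assert abs(k[0] - 0.1) < 1e-3

    def test_duplicated_regulator_detected_by_rank(self):
        basis = hmf.hmf_basis(M=8, N=3, T=16.0, n_grid=257)
        E = np.exp(0.1 * basis.t)
        values = np.vstack([E, E])                # identical columns
        m, dm = hmf.project(basis, values)
        sys = hmf.assemble_regression(m, dm, target=0)
        assert sys.rank < sys.A.shape[1]

    def test_underdetermined_flag_in_study_regime(self):
        basis = hmf.hmf_basis(M=8, N=3, T=16.0, n_grid=257)
        values = np.random.default_rng(0).random((15, 257))
        m, dm = hmf.project(basis, values)
        sys = hmf.assemble_regression(m, dm, target=0)
        assert sys.underdetermined


class TestElasticNet:
    def _system(self, seed=0, M=12, p=6):
        rng = np.random.default_rng(seed)
        A = rng.standard_normal((M, p))
        k = np.zeros(p)
        k[[1, 4]] = [0.5, -0.8]
        return A, A @ k, k

    def test_huge_penalty_shrinks_to_zero(self):
        A, b, _ = self._system()
        w = hmf.solve_elastic_net(A, b, alpha=1e6, l1_ratio=0.5)
        assert np.all(w == 0)

    def test_zero_penalty_matches_normal_equations(self):
        A, b, _ = self._system(seed=3)
        b = b + 0.01 * np.random.default_rng(4).standard_normal(len(b))
        w = hmf.solve_elastic_net(A, b, alpha=0.0, l1_ratio=0.0)
        w_ne = np.linalg.solve(A.T @ A, A.T @ b)   # independent oracle
        assert np.max(np.abs(w - w_ne)) < 1e-6

    def test_all_zero_design_returns_zero_row(self):
        w = hmf.solve_elastic_net(np.zeros((5, 3)), np.ones(5), 0.1)
        assert np.all(w == 0)

    def test_penalty_grid_must_be_nonempty(self):
        A, b, _ = self._system()
        sys = hmf.RegressionSystem(A=A, b=b, target=0)
        with pytest.raises(ValueError, match="non-empty"):
            hmf.fit_elastic_net(sys, penalty_grid=[])


class TestNetworkFit:
    def test_three_node_support_recovered_from_dense_data(self, dense_grid):
        d = toy_design(n_organs=1, n_genes=3)
        net = generate_ground_truth_network(d, density=0.34, seed=2)
        E0 = np.array([1.0, 0.5, 0.8])
        traj = simulate_trajectories(net, dense_grid, E0)
        dense = hmf.DenseTrajectories(t=dense_grid - 8.0,
                                      values=traj.values.to_numpy(),
                                      labels=list(net.node_labels))
        basis = hmf.hmf_basis(M=12, N=3, T=16.0, n_grid=dense_grid.size)
        im = hmf.fit_network(dense, basis, dense_grid - 8.0,
                             traj.values.to_numpy())
        K = im.K.to_numpy()
        for r, c in net.true_edges:
            assert K[r, c] != 0
            assert np.sign(K[r, c]) == np.sign(net.K[r, c])

    def test_noise_free_multi_experiment_recovery_within_tolerance(
            self, design15, truth15, dense_grid):
        """With several independent initial states the stacked system is
        well posed: support is recovered and true-edge coefficients match
        within 5% of the coefficient scale."""
        rng = np.random.default_rng(1)
        denses, evals = [], []
        for _ in range(8):
            E0 = rng.uniform(0.2, 1.0, 15)
            V = simulate_trajectories(truth15, dense_grid, E0
                                      ).values.to_numpy()
            denses.append(hmf.DenseTrajectories(t=dense_grid - 8.0, values=V,
                                                labels=truth15.node_labels))
            evals.append(V)
        basis = hmf.hmf_basis(M=12, N=3, T=16.0, n_grid=dense_grid.size)
        grid = np.concatenate([[0.0], hmf.default_penalty_grid()])
        im = hmf.fit_network(denses, basis, dense_grid - 8.0, evals,
                             penalty_grid=grid)
        K = im.K.to_numpy()
        for r, c in truth15.true_edges:
            assert K[r, c] != 0
            assert np.sign(K[r, c]) == np.sign(truth15.K[r, c])
        maxerr = max(abs(K[r, c] - truth15.K[r, c])
                     for r, c in truth15.true_edges)
        assert maxerr < 0.05 * 0.2

    def test_identical_strains_give_identical_networks(self, design15,
                                                       truth15):
        norm, meta = make_normalized_dataset(design15, truth15, noise_sd=0.05,
                                             seed=3)
        # copy SHR data onto WKY columns so both strains see the same data
        shr_cols = meta.index[meta["strain"] == "SHR"]
        wky_cols = meta.index[meta["strain"] == "WKY"]
        norm[wky_cols] = norm[shr_cols].to_numpy()
        im1 = hmf.estimate_network(norm, meta, "SHR")
        im2 = hmf.estimate_network(norm, meta, "WKY")
        assert np.array_equal(im1.K.to_numpy(), im2.K.to_numpy())

    def test_node_permutation_equivariance(self, design15, truth15):
        """Permuting gene order permutes K rows/columns correspondingly.

        Checked with the exact zero-penalty solver: the coordinate
        descent used at nonzero penalties visits columns in order and on
        near-degenerate designs may settle on different solutions."""
        cfg = hmf.HmfConfig(penalty_grid=(0.0,))
        norm, meta = make_normalized_dataset(design15, truth15, noise_sd=0.02,
                                             seed=4)
        im1 = hmf.estimate_network(norm, meta, "SHR", cfg)
        perm = norm.iloc[::-1]                   # reverse gene order
        im2 = hmf.estimate_network(perm, meta, "SHR", cfg)
        pairs = list(im1.K.index)
        for ra in pairs[:4]:
            for rb in pairs[:4]:
                a = im1.K.loc[ra, rb]
                b = im2.K.loc[ra, rb]
                assert a == pytest.approx(b, rel=1e-6, abs=1e-9)

    def test_recovery_degrades_with_noise_on_average(self, design15):
        """Mean null-exceedance of true-edge coefficients declines as
        replicate noise grows (weak monotonicity over seeds)."""
        noise_levels = [0.0, 0.05, 0.1, 0.2]
        means = []
        for noise in noise_levels:
            pcts = []
            for seed in range(8):
                truth = generate_ground_truth_network(design15, density=0.05,
                                                      seed=300 + seed)
                norm, meta = make_normalized_dataset(design15, truth,
                                                     noise_sd=noise,
                                                     seed=seed)
                im = hmf.estimate_network(norm, meta, "SHR")
                K = im.K.to_numpy()
                null = np.array([abs(K[r, c]) for r in range(15)
                                 for c in range(15)
                                 if r != c and truth.K[r, c] == 0])
                med = np.median([abs(K[r, c]) for r, c in truth.true_edges])
                pcts.append(float(np.mean(null < med)))
            means.append(np.mean(pcts))
        assert means[0] >= means[-1]
        assert np.mean(means[:2]) >= np.mean(means[2:])


class TestSimulateFittedModel:
    def test_zero_matrix_constant_trajectories(self):
        K = np.zeros((3, 3))
        traj = hmf.simulate_fitted_model(K, np.array([0.2, 0.5, 0.9]),
                                         n_out=21)
        assert np.allclose(traj.values.to_numpy(),
                           np.array([[0.2], [0.5], [0.9]]))

    def test_initial_condition_exact_at_first_age(self):
        K = np.array([[0.05]])
        traj = hmf.simulate_fitted_model(K, np.array([0.3]), n_out=17)
        assert traj.values.iloc[0, 0] == 0.3
        assert traj.times[0] == 8.0

    def test_scalar_fit_reproduces_exponential(self):
        basis = hmf.hmf_basis(M=8, N=3, T=16.0, n_grid=257)
        E = np.exp(0.1 * basis.t)[None, :]
        m, dm = hmf.project(basis, E)
        k, *_ = np.linalg.lstsq(m, dm[:, 0], rcond=None)
        traj = hmf.simulate_fitted_model(np.array([[k[0]]]), np.array([1.0]),
                                         n_out=161)
        want = np.exp(0.1 * (traj.times - 8.0))
        assert np.max(np.abs(traj.values.to_numpy()[0] - want)) < 1e-2
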