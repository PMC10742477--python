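"""Metaplex diffusion: conservation, positivity, consensus, diagnostics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import smx
from smx.dynamics import parse_simplex_label, simplex_label


@pytest.fixture(scope="module")
def standard_run(metaplex_n5, two_triangle):
    K = two_triangle
    ic = {K.find_by_labels([1]): 1.0,
          K.find_by_labels([1, 2]): 1.0,
          K.find_by_labels([1, 2, 3]): 1.0}
    u0 = smx.initial_condition(metaplex_n5, ("table", ic))
    cfg = smx.DiffusionConfig(dt=0.01, n_steps=20_000, store_every=100,
                              steady_tol=1e-12)
    return u0, smx.integrate(metaplex_n5, u0, cfg)


class TestInitialCondition:
    def test_delta_spreads_uniform_density(self, metaplex_n5):
        M = metaplex_n5
        u0 = smx.initial_condition(M, ("delta", (2, (0, 1, 2)), 1.0))
        k = M.domain_index((0, 1, 2))
        sl = M.dof_slice(k)
        np.testing.assert_allclose(u0[sl], u0[sl][0])
        assert abs(float(M.D @ u0) - 1.0) < 1e-12
        assert np.count_nonzero(u0) == M.domains[k].n_nodes

    def test_degree_ic_on_k3(self):
        M = smx.build_metaplex(smx.k3_complex(), nodes_per_edge=3)
        u0 = smx.initial_condition(M, "degree")
        totals = [float(M.D[M.dof_slice(k)] @ u0[M.dof_slice(k)])
                  for k in range(M.n_domains)]
        assert totals[:3] == [2.0, 2.0, 2.0]  # every K3 vertex has degree 2
        assert max(totals[3:]) == 0.0

    def test_uniform_random_total_mass_bookkeeping(self, metaplex_n5):
        u0 = smx.initial_condition(metaplex_n5, ("uniform_random", 11))
        per_domain = [float(metaplex_n5.D[metaplex_n5.dof_slice(k)]
                            @ u0[metaplex_n5.dof_slice(k)])
                      for k in range(metaplex_n5.n_domains)]
        assert all(0 <= m <= 1 for m in per_domain)
        assert abs(float(metaplex_n5.D @ u0) - sum(per_domain)) < 1e-10

    def test_table_accepts_string_labels(self, metaplex_n5):
        u0 = smx.initial_condition(metaplex_n5, ("table", {"1:0-1": 2.0}))
        assert abs(float(metaplex_n5.D @ u0) - 2.0) < 1e-12

    def test_unknown_simplex_rejected(self, metaplex_n5):
        with pytest.raises(KeyError):
            smx.initial_condition(metaplex_n5, ("delta", (1, (0, 4)), 1.0))


class TestIntegrate:
    def test_conservation_and_positivity(self, standard_run):
        _, traj = standard_run
        assert traj.mass_drift < 1e-8
        assert traj.global_min >= -1e-10

    def test_consensus_of_all_totals(self, standard_run, metaplex_n5):
        u0, traj = standard_run
        cv = smx.consensus_value(u0, metaplex_n5)
        assert abs(cv - 3.0 / 13.0) < 1e-12
        assert np.abs(traj.totals[:, -1] - cv).max() < 1e-6
        assert np.abs(traj.states[:, -1] - cv).max() < 1e-6

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_positivity_for_random_nonnegative_ics(self, seed):
        M = smx.build_metaplex(smx.k3_complex(), nodes_per_edge=4)
        rng = np.random.default_rng(seed)
        u0 = rng.uniform(size=M.n_dofs)
        traj = smx.integrate(M, u0, smx.DiffusionConfig(dt=0.05, n_steps=60))
        assert traj.global_min >= -1e-10
        assert traj.mass_drift < 1e-10

    def test_isolated_domain_relaxes_to_uniform_own_mass(self):
        dom = smx.discretize_simplex(1, 6).with_simplex((0, 1))
        M = smx.MetaplexSystem([dom], [])
        u0 = np.zeros(6)
        u0[0] = 3.0 / M.D[0]  # mass 3 at the left end
        traj = smx.integrate(M, u0, smx.DiffusionConfig(dt=0.05, n_steps=2000,
                                                        steady_tol=1e-13))
        np.testing.assert_allclose(traj.states[:, -1], 3.0, atol=1e-8)

    def test_schemes_agree_with_expected_orders(self, metaplex_n5):
        # Richardson: implicit Euler halves its error with dt, CN quarters it
        u0 = smx.initial_condition(metaplex_n5, ("uniform_random", 5))
        ref = smx.integrate(metaplex_n5, u0, smx.DiffusionConfig(
            dt=1.0 / 2048, n_steps=2048, scheme="crank_nicolson")).states[:, -1]
        ratios = {}
        for scheme in ("implicit_euler", "crank_nicolson"):
            errs = [np.abs(smx.integrate(metaplex_n5, u0, smx.DiffusionConfig(
                dt=1.0 / n, n_steps=n, scheme=scheme)).states[:, -1] - ref).max()
                for n in (32, 64)]
            ratios[scheme] = errs[0] / errs[1]
        assert 1.7 < ratios["implicit_euler"] < 2.3
        assert 3.5 < ratios["crank_nicolson"] < 4.5

    def test_steady_state_matches_nullspace_projection(self, two_triangle):
        import scipy.linalg as sla

        M = smx.build_metaplex(two_triangle, nodes_per_edge=3)
        u0 = smx.initial_condition(M, ("table", {(0, (0,)): 1.0,
                                                 (1, (0, 1)): 1.0,
                                                 (2, (0, 1, 2)): 1.0}))
        traj = smx.integrate(M, u0, smx.DiffusionConfig(
            dt=0.05, n_steps=30_000, steady_tol=1e-12, store_every=500))
        ns = sla.null_space(M.S.toarray())
        assert ns.shape[1] == 1
        v = ns[:, 0]
        proj = v * ((v @ (M.D * u0)) / (v @ (M.D * v)))
        assert np.abs(traj.states[:, -1] - proj).max() < 1e-8


class TestObservables:
    def test_totals_start_from_ic_masses_and_stay_constant_in_sum(
            self, standard_run, metaplex_n5):
        _, traj = standard_run
        t0 = dict(zip(traj.simplex_ids, traj.totals[:, 0]))
        assert abs(t0[(0, (0,))] - 1.0) < 1e-12
        assert abs(t0[(1, (0, 1))] - 1.0) < 1e-12
        assert abs(t0[(2, (0, 1, 2))] - 1.0) < 1e-12
        sums = traj.totals.sum(axis=0)
        assert np.abs(sums - sums[0]).max() < 1e-8

    def test_consensus_value_special_cases(self, metaplex_n5):
        assert smx.consensus_value(np.zeros(metaplex_n5.n_dofs), metaplex_n5) == 0.0
        v = 0.7
        np.testing.assert_allclose(
            smx.consensus_value(np.full(metaplex_n5.n_dofs, v), metaplex_n5), v)

    def test_return_probability_limit(self, metaplex_n5):
        u0 = smx.initial_condition(metaplex_n5, ("delta", (2, (0, 1, 2)), 1.0))
        traj = smx.integrate(metaplex_n5, u0, smx.DiffusionConfig(
            dt=0.01, n_steps=6000, store_every=50, steady_tol=1e-12))
        rp = smx.return_probability(traj, metaplex_n5, (2, (0, 1, 2)))
        assert rp[0] == 1.0
        assert abs(rp[-1] - 1.0 / 13.0) < 1e-6
        assert rp[-1] > 0

    def test_return_probability_needs_seeded_mass(self, standard_run, metaplex_n5):
        _, traj = standard_run
        with pytest.raises(ValueError, match="no initial mass"):
            smx.return_probability(traj, metaplex_n5, (2, (2, 3, 4)))

    def test_simplex_label_round_trip(self):
        assert parse_simplex_label(simplex_label(2, (0, 1, 4))) == (2, (0, 1, 4))
        with pytest.raises(ValueError):
            parse_simplex_label("2:0-1")


class TestDetectHoles:
    def test_far_triangle_flagged_early(self, metaplex_n5):
        u0 = smx.initial_condition(metaplex_n5, ("delta", (2, (0, 1, 2)), 1.0))
        traj = smx.integrate(metaplex_n5, u0,
                             smx.DiffusionConfig(dt=0.01, n_steps=100))
        rep = smx.detect_holes(traj, metaplex_n5, theta=0.1, t_eval=0.3)
        assert rep.holes == [(2, (2, 3, 4))]
        assert set(rep.table["simplex"]) == {"2:0-1-2", "2:2-3-4"}
        assert np.isfinite(rep.table["interior_boundary_ratio"]).all()

    def test_consensus_state_and_zero_theta_flag_nothing(self, standard_run,
                                                         metaplex_n5):
        _, traj = standard_run
        assert smx.detect_holes(traj, metaplex_n5, theta=0.9,
                                t_eval=traj.times[-1]).holes == []
        assert smx.detect_holes(traj, metaplex_n5, theta=0.0).holes == []

    def test_theta_validation(self, standard_run, metaplex_n5):
        _, traj = standard_run
        with pytest.raises(ValueError):
            smx.detect_holes(traj, metaplex_n5, theta=1.5)


@pytest.fixture(scope="module")
def report(two_triangle, metaplex_n5):
    rng = np.random.default_rng(2)
    table = {(m, s): float(rng.uniform(0.2, 1.0))
             for m, s in two_triangle.iter_simplices()}
    cfg = smx.DiffusionConfig(dt=0.01, n_steps=9000, store_every=30)
    return smx.compare_models(two_triangle, metaplex_n5, table, cfg)


class TestCompareModels:
    def test_metaplex_conservative_hodge_not(self, report):
        assert report.metaplex.mass_drift < 1e-8
        assert report.hodge.mass_drift > 0.1
        assert report.metaplex.min_value >= -1e-10

    def test_consensus_only_for_metaplex(self, report):
        assert report.metaplex.consensus_distance < 1e-4
        assert report.hodge.consensus_distance > 0.05

    def test_metaplex_converges_slower_on_shared_grid(self, report):
        np.testing.assert_array_equal(report.hodge.times, report.metaplex.times)
        assert report.hodge.convergence_time is not None
        assert report.metaplex.convergence_time is not None
        assert report.metaplex.convergence_time > report.hodge.convergence_time
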