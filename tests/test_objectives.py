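"""Objective scores: control coefficients, co-responses, function,
homeostasis/robustness and turnover time."""

import numpy as np
import pytest

import feaspace as fs
from feaspace.objectives import EPS_DIV

from conftest import toy_steady_state_closed_form


class TestControlCoefficients:
    def test_summation_theorems_at_reference(self, toy):
        C = fs.control_coefficients(toy, np.ones(3))
        np.testing.assert_allclose(C.C_J.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(C.C_x.sum(axis=1), 0.0, atol=1e-9)

    def test_fd_step_halving_converged(self, toy):
        Ca = fs.control_coefficients(toy, np.ones(3), fd_step=1e-3, method="fd")
        Cb = fs.control_coefficients(toy, np.ones(3), fd_step=1e-4, method="fd")
        assert np.max(np.abs(Ca.C_J - Cb.C_J)) < 1e-4
        assert np.max(np.abs(Ca.C_x - Cb.C_x)) < 1e-4

    def test_fd_agrees_with_analytic(self, toy):
        rng = np.random.default_rng(1)
        r = rng.uniform(0.5, 1.5, 3)
        Ca = fs.control_coefficients(toy, r, method="analytic")
        Cf = fs.control_coefficients(toy, r, method="fd", fd_step=1e-4)
        assert np.max(np.abs(Ca.C_J - Cf.C_J)) < 1e-6
        assert np.max(np.abs(Ca.C_x - Cf.C_x)) < 1e-5


class TestCoResponse:
    def _C(self, toy, CJ_row, Cx_row):
        C_J = np.zeros((3, 3))
        C_x = np.zeros((2, 3))
        C_J[2] = CJ_row
        C_x[0] = Cx_row
        return fs.ControlCoefficientSet(C_J=C_J, C_x=C_x, model=toy)

    def test_zero_numerator(self, toy):
        C = self._C(toy, [0.5, 0, 0], [0.0, 0, 0])
        assert fs.co_response(C, ("x", "M1"), ("J", "R3"), "R1") == 0.0

    def test_equal_coefficients_give_one(self, toy):
        C = self._C(toy, [0.3, 0, 0], [0.3, 0, 0])
        assert fs.co_response(C, ("x", "M1"), ("J", "R3"), "R1") == pytest.approx(1.0)

    def test_vanishing_denominator_is_signed_infinity(self, toy):
        C = self._C(toy, [0.0, 0, 0], [-0.3, 0, 0])
        assert fs.co_response(C, ("x", "M1"), ("J", "R3"), "R1") == -np.inf
        C00 = self._C(toy, [0.0, 0, 0], [0.0, 0, 0])
        assert np.isnan(fs.co_response(C00, ("x", "M1"), ("J", "R3"), "R1"))

    def test_matches_independent_finite_difference_ratio(self, toy):
        """Definition-level oracle: O^{M1,J}_{e1} equals the ratio of
        independently computed steady-state sensitivities."""
        h = 1e-6
        rp = np.array([1.0 + h, 1.0, 1.0])
        rm = np.array([1.0 - h, 1.0, 1.0])
        sp = fs.linlog_steady_state(toy, rp)
        sm = fs.linlog_steady_state(toy, rm)
        num = np.log(sp.x_ss[0] / sm.x_ss[0])
        den = np.log(sp.J_ss[2] / sm.J_ss[2])
        C = fs.control_coefficients(toy, np.ones(3))
        O = fs.co_response(C, ("x", "M1"), ("J", "R3"), "R1")
        assert O == pytest.approx(num / den, rel=1e-5)


class TestFiniteChangeCoresponse:
    def test_uniform_scaling_gives_zero(self, toy):
        st_ = fs.linlog_steady_state(toy, 1.7 * np.ones(3))
        O = fs.finite_change_coresponse(toy.reference, st_, toy)
        np.testing.assert_allclose(O, 0.0, atol=1e-10)

    def test_identity_transition_is_zero_by_convention(self, toy):
        st_ = fs.linlog_steady_state(toy, np.ones(3))
        O = fs.finite_change_coresponse(toy.reference, st_, toy)
        np.testing.assert_array_equal(O, np.zeros(2))

    def test_closed_form_transition(self, toy):
        r = np.array([2.0, 1.0, 1.0])
        st_ = fs.linlog_steady_state(toy, r)
        O = fs.finite_change_coresponse(toy.reference, st_, toy)
        x_exp, J_exp = toy_steady_state_closed_form(r)
        expected = np.log(x_exp) / np.log(J_exp[2])
        np.testing.assert_allclose(O, expected, rtol=1e-10)

    def test_unchanged_flux_moved_metabolites_divergent(self, toy):
        """Varying only the M2-consuming enzyme leaves the flux untouched
        but moves M2: the transition is perfectly robust, not homeostatic."""
        st_ = fs.linlog_steady_state(toy, np.array([1.0, 1.0, 2.0]))
        O = fs.finite_change_coresponse(toy.reference, st_, toy)
        assert O[0] == 0.0           # M1 did not move
        assert np.isinf(O[1])        # M2 moved at constant flux

    def test_local_limit_matches_derivative_coresponse(self, toy):
        """Shrinking the perturbation towards the reference, the finite-change
        co-response converges to the local (derivative) co-response."""
        C = fs.control_coefficients(toy, np.ones(3))
        target = np.array([fs.co_response(C, ("x", sp), ("J", "R3"), "R1")
                           for sp in toy.internal_species])
        errs = []
        for h in (1e-2, 1e-3):
            st_ = fs.linlog_steady_state(toy, np.array([1.0 + h, 1.0, 1.0]))
            O = fs.finite_change_coresponse(toy.reference, st_, toy)
            errs.append(np.max(np.abs(O - target)))
        assert errs[1] < errs[0]
        assert errs[1] < 1e-2


class TestFunctionScore:
    def test_argmax_scores_one(self):
        F, ok = fs.function_score(2.0, 2.0, theta_flux=0.0)
        assert F == 1.0 and ok

    def test_quartile_cutoff(self):
        F, ok = fs.function_score(1.4, 2.0, theta_flux=0.25)
        assert F == pytest.approx(0.7) and not ok
        _, ok2 = fs.function_score(1.6, 2.0, theta_flux=0.25)
        assert ok2

    def test_nonpositive_max_undefined(self):
        F, ok = fs.function_score(0.5, 0.0)
        assert np.isnan(F) and not ok

    def test_flux_optimum_lies_on_equal_upstream_enzymes(self, toy):
        """Grid-search oracle under the enzyme budget: the pathway flux is
        the harmonic mean of the two upstream enzymes, so the optimum has
        r1 = r2 (equal cost); the flux is invariant to the drain enzyme."""
        grid = np.linspace(0.1, 2.0, 39)
        best, best_r = -1.0, None
        for r1 in grid:
            for r2 in grid:
                r3 = 1.0
                if abs((r1 + r2 + r3) / 3 - 1) > 0.5:
                    continue
                J = 2 * r1 * r2 / (r1 + r2)
                if J > best:
                    best, best_r = J, (r1, r2, r3)
        assert abs(best_r[0] - best_r[1]) < 1e-9
        # cross-check the oracle against the model solver at the optimum
        st_ = fs.linlog_steady_state(toy, np.array(best_r))
        assert st_.J_ss[2] == pytest.approx(best, rel=1e-10)


class TestHomeostasisRobustness:
    def test_arithmetic_aggregate(self):
        H, ok = fs.homeostasis_score(np.array([0.2, -0.3]), theta_homeo=0.6)
        assert H == pytest.approx(0.5) and ok

    def test_duality_same_value_opposite_reading(self):
        O = np.array([0.2, -0.3])
        H, _ = fs.homeostasis_score(O)
        R, ok = fs.robustness_score(O, theta_robust=0.4)
        assert R == H and ok

    def test_divergent_marker_propagates(self):
        O = np.array([np.inf, 0.1])
        H, hok = fs.homeostasis_score(O)
        R, rok = fs.robustness_score(O)
        assert np.isinf(H) and not hok
        assert np.isinf(R) and rok

    def test_uniform_scaling_not_robust(self, toy):
        st_ = fs.linlog_steady_state(toy, 1.5 * np.ones(3))
        O = fs.finite_change_coresponse(toy.reference, st_, toy)
        R, ok = fs.robustness_score(O, theta_robust=0.5)
        assert R == 0.0 and not ok

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            fs.homeostasis_score(np.array([0.1]), subset_idx=np.array([], dtype=int))

    def test_homeostatic_states_concentrate_on_diagonal(self, mapped_set,
                                                        viability, scores):
        """Maintaining the state requires the enzymes to move in concert:
        homeostasis-feasible samples sit much closer to the r1=r2=r3
        diagonal (relative spread) than the viable set at large."""
        R = mapped_set.R
        mean = R.mean(axis=1)
        rel = np.linalg.norm(R - mean[:, None], axis=1) / np.maximum(mean, 1e-9)
        viable = fs.viable_mask(viability)
        feas = scores["feasible_homeo"].to_numpy() & viable
        assert feas.sum() >= 3
        assert rel[feas].mean() < 0.5 * rel[viable].mean()


class TestTurnoverTime:
    def test_definition(self, toy):
        st_ = fs.SteadyState(np.array([0.5, 1.0]), np.array([1.0, 1.0, 1.0]),
                             converged=True, stable=True, residual=0.0)
        assert fs.turnover_time(st_, toy, "M1") == pytest.approx(0.5)

    def test_halves_when_consumption_doubles(self, toy):
        st1 = fs.SteadyState(np.array([0.5, 1.0]), np.array([1.0, 1.0, 1.0]),
                             True, True, 0.0)
        st2 = fs.SteadyState(np.array([0.5, 1.0]), np.array([2.0, 2.0, 2.0]),
                             True, True, 0.0)
        assert fs.turnover_time(st2, toy, "M1") == fs.turnover_time(st1, toy, "M1") / 2

    def test_boosted_drain_enzyme_speeds_up_m2(self, toy):
        """A stronger end-of-pathway 'brake' lowers the M2 pool and with it
        the turnover time."""
        ref_tau = fs.turnover_time(fs.linlog_steady_state(toy, np.ones(3)),
                                   toy, "M2")
        fast_tau = fs.turnover_time(
            fs.linlog_steady_state(toy, np.array([1.0, 1.0, 2.0])), toy, "M2")
        assert fast_tau < ref_tau

    def test_zero_consumption_is_infinite(self, toy):
        st_ = fs.SteadyState(np.array([1.0, 1.0]), np.array([0.0, 0.0, 0.0]),
                             True, True, 0.0)
        assert np.isinf(fs.turnover_time(st_, toy, "M2"))


class TestClassifyAndCombine:
    def test_loose_cutoffs_make_every_viable_state_feasible(self, mapped_set,
                                                            viability):
        cfg = fs.ObjectiveConfig(theta_flux=1.0, theta_robust=0.0,
                                 theta_homeo=np.inf, theta_tau=np.inf)
        sc = fs.classify_and_combine(
            fs.score_objectives(mapped_set, viability, cfg), cfg)
        viable = fs.viable_mask(viability)
        assert np.array_equal(sc["feasible_all"].to_numpy(), viable)

    def test_disjoint_labels_empty_conjunction(self, scores):
        df = scores.copy()
        df["feasible_function"] = ~df["feasible_homeo"]
        df["feasible_responsive"] = True
        out = fs.classify_and_combine(df)
        assert int((out["feasible_function"] & out["feasible_homeo"]).sum()) == 0

    def test_all_feasible_set_is_small(self, scores):
        """With the default (field-standard) cut-offs the three objectives
        overlap on only a small corner of the viable space."""
        n_viable = int(scores["viable"].sum())
        n_all = int(scores["feasible_all"].sum())
        assert n_all < 0.10 * n_viable

    def test_local_mode_runs_and_flags_reference_neighbourhood(self, toy):
        cfg = fs.SamplingConfig(n_samples=20, seed=9, lo=0.5, hi=1.5)
        ss = fs.map_to_physiology(fs.sample_enzyme_levels(cfg, toy), toy)
        recs = fs.apply_all_constraints(ss)
        sc = fs.score_objectives(ss, recs, fs.ObjectiveConfig(mode="local"))
        assert len(sc) == 20
        # every viable sample received a defined worst-case local score
        assert sc.loc[sc["viable"], "H"].notna().all()
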