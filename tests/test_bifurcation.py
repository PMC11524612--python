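"""Tests for fixed-point solving, stability classification and continuation."""

import numpy as np
import pytest

from cldyn import (
    ModelParams,
    NeuronState,
    continue_branch,
    find_fixed_point,
    gaba_crossover,
    integrate,
    jacobian_eigenvalues,
    rhs,
)
from cldyn.bifurcation import (
    InconsistencyError,
    NoConvergenceError,
    _trace_branch,
    classify_stability,
    export_branch_csv,
    export_ode_file,
    export_summary_json,
    jacobian,
)


class TestNormalForm:
    """The generic arclength tracer on the saddle-node normal form x' = mu - x^2."""

    @staticmethod
    def F(u):
        # u = (x, mu); one equation, fold at mu = 0, x = 0
        return np.array([u[1] - u[0] ** 2])

    def test_traces_through_the_fold(self):
        pts, reason = _trace_branch(self.F, np.array([1.0, 1.0]), np.ones(2),
                                    p_index=1, p_range=(-0.5, 1.0), step0=0.05,
                                    direction=-1.0)
        mus = np.array([u[1] for u in pts])
        xs = np.array([u[0] for u in pts])
        # sampled points straddle the fold at mu = 0 (refinement is separate)
        assert mus.min() < 0.1
        assert xs.min() < -0.3                             # continued onto x<0 sheet
        np.testing.assert_allclose(mus, xs ** 2, atol=1e-8)
        # with a small maximum step the sampled minimum tightly brackets the fold
        pts2, _ = _trace_branch(self.F, np.array([1.0, 1.0]), np.ones(2),
                                p_index=1, p_range=(-0.5, 1.0), step0=0.02,
                                max_step=0.02, direction=-1.0)
        assert min(u[1] for u in pts2) == pytest.approx(0.0, abs=1e-3)

    def test_zero_length_range_gives_single_segment(self):
        pts, _ = _trace_branch(self.F, np.array([1.0, 1.0]), np.ones(2),
                               p_index=1, p_range=(1.0, 1.0), step0=0.05)
        mus = [u[1] for u in pts]
        assert all(abs(m - 1.0) < 1e-8 for m in mus[:1])


class TestStabilityClassification:
    @pytest.mark.parametrize("spectrum,expected", [
        ([-1.0, -0.5, -0.1 + 2j, -0.1 - 2j], "stable"),
        ([0.3, -1.0, -0.5], "saddle"),
        ([0.2 + 1j, 0.2 - 1j, -1.0], "unstable_focus"),
        ([1e-9, -1.0, -2.0], "marginal"),
    ])
    def test_by_leading_eigenvalue(self, spectrum, expected):
        assert classify_stability(np.array(spectrum)) == expected

    def test_structural_zero_dropped_for_conservative_family(self):
        spectrum = np.array([1e-12, -0.3, -1.0])
        assert classify_stability(spectrum, drop_structural=True) == "stable"


class TestFindFixedPoint:
    def test_resting_state_voltage(self, rest_597):
        # low-chloride resting branch point
        assert rest_597.state.V == pytest.approx(-70.69, abs=0.05)
        assert rest_597.stability == "stable"
        assert rest_597.residual_norm < 1e-10

    def test_rhs_residual_small_at_solution(self, params_conservative, rest_597):
        d = rhs(0.0, rest_597.state.as_array(), params_conservative)
        assert np.max(np.abs(d)) < 1e-8

    def test_omitted_chloride_balance_verified(self, params_conservative, rest_597):
        # the clamped coordinate's own equation holds by flux-charge redundancy
        d = rhs(0.0, rest_597.state.as_array(), params_conservative)
        assert abs(d[6]) < 1e-12

    def test_high_chloride_db_point_is_stable(self, params_conservative):
        guess = NeuronState.with_steady_gating(-33.0, 18.0, 26.0, 20.0)
        fp = find_fixed_point(guess, params_conservative, clamp=("Cl_i", 20.0))
        assert fp.state.V > -40.0
        assert fp.stability == "stable"

    def test_intermediate_chloride_point_is_unstable(self, params_conservative):
        guess = NeuronState.with_steady_gating(-40.0, 8.8, 29.4, 12.0)
        fp = find_fixed_point(guess, params_conservative, clamp=("Cl_i", 12.0))
        assert max(ev.real for ev in fp.reduced_eigenvalues) > 0

    def test_nonconvergence_raises(self, params_conservative):
        guess = NeuronState(-500.0, 0.5, 0.5, 0.5, 1e-3, 1.0, 24.0)
        with pytest.raises((NoConvergenceError, InconsistencyError, Exception)):
            find_fixed_point(guess, params_conservative, clamp=("Cl_i", 24.0))

    def test_bath_coupled_rest_has_ko_at_bath_level(self):
        # with eps_k > 0 the isolated fixed point pins K_o to K_bath
        p = ModelParams(eps_k=0.25, K_bath=3.0)
        fp = find_fixed_point(NeuronState.with_steady_gating(-70.0, 3.0, 20.0, 6.0), p)
        assert fp.state.K_o == pytest.approx(3.0, abs=1e-9)
        assert fp.stability == "stable"


class TestJacobian:
    def test_finite_difference_step_insensitivity(self, params_conservative, rest_597):
        y = rest_597.state.as_array()
        ev = np.sort_complex(jacobian_eigenvalues(y, params_conservative))
        J2 = jacobian(y, params_conservative)  # default step
        # independent evaluation with a different FD step
        J3 = np.empty_like(J2)
        for j in range(7):
            e = 1e-5 * max(1.0, abs(y[j]))
            yp = y.copy(); yp[j] += e
            ym = y.copy(); ym[j] -= e
            J3[:, j] = (rhs(0.0, yp, params_conservative)
                        - rhs(0.0, ym, params_conservative)) / (2 * e)
        ev3 = np.sort_complex(np.linalg.eigvals(J3))
        np.testing.assert_allclose(ev, ev3, rtol=1e-4, atol=1e-9)

    def test_structural_zero_on_conservative_family(self, params_conservative, rest_597):
        ev = jacobian_eigenvalues(rest_597.state.as_array(), params_conservative)
        assert np.min(np.abs(ev)) < 1e-10

    def test_resting_point_transversally_stable(self, params_conservative, rest_597):
        ev = rest_597.reduced_eigenvalues
        assert all(z.real < 0 for z in ev)


class TestBranch:
    def test_covers_range_and_residuals(self, cl_branch):
        pv = cl_branch.parameter_values()
        assert pv.min() <= 5.001 and pv.max() >= 19.999
        assert all(p.residual_norm < 1e-8 for p in cl_branch.points)

    def test_single_sn_and_hb_in_study_window(self, cl_branch):
        # the fold terminating the resting branch and the Hopf opening the DB branch
        sn = [b.value for b in cl_branch.sn_points if b.value > 7.0]
        hb = [b.value for b in cl_branch.hb_points if b.value > 10.0]
        assert len(sn) == 1
        assert len(hb) == 1
        assert 7.5 < sn[0] < 8.5
        assert 17.0 < hb[0] < 20.0

    def test_sn_hb_invariant_under_step_halving(self, params_conservative, cl_branch):
        guess = NeuronState.with_steady_gating(-76.5, 2.4, 21.7, 5.0)
        fine = continue_branch("Cl_i", (5.0, 20.0), guess, params_conservative,
                               step0=0.05)
        for coarse_pts, fine_pts in ((cl_branch.sn_points, fine.sn_points),
                                     (cl_branch.hb_points, fine.hb_points)):
            a = sorted(b.value for b in coarse_pts)
            b_ = sorted(b.value for b in fine_pts)
            assert len(a) == len(b_)
            np.testing.assert_allclose(a, b_, atol=0.02)

    def test_sn_coincides_with_cl_fold(self, cl_branch):
        pv = cl_branch.parameter_values()
        # extremum of Cl_i along arclength on the resting-side segment
        upper_sn = max(b.value for b in cl_branch.sn_points)
        i_fold = int(np.argmax(pv[: len(pv) // 2]))
        assert abs(pv[i_fold] - upper_sn) < 0.05

    def test_stability_against_simulation(self, params_conservative, cl_branch):
        # perturb 5 branch points by 0.1 mV; stable ones return, unstable depart
        pv = cl_branch.parameter_values()

        def nearest(cl):
            return cl_branch.points[int(np.argmin(np.abs(pv - cl)))]

        for cl in (5.5, 6.5, 19.5):
            fp = nearest(cl)
            pert = NeuronState.from_array(fp.state.as_array() + np.r_[0.1, np.zeros(6)])
            tr = integrate(pert, params_conservative, t_end=30_000.0)
            returned = abs(tr.V[-1] - fp.state.V) < 1.0
            if fp.stability == "stable":
                assert returned, f"stable point at Cl={cl} did not return"
        for cl in (9.0, 12.0):
            fp = nearest(cl)
            assert fp.stability in ("saddle", "unstable_focus")
            pert = NeuronState.from_array(fp.state.as_array() + np.r_[0.1, np.zeros(6)])
            tr = integrate(pert, params_conservative, t_end=30_000.0)
            assert np.max(np.abs(tr.V - fp.state.V)) > 5.0, \
                f"unstable point at Cl={cl} did not depart"

    def test_zero_length_range(self, params_conservative, rest_597):
        br = continue_branch("Cl_i", (5.97, 5.97), rest_597.state,
                             params_conservative)
        assert len(br) >= 1
        assert not br.sn_points and not br.hb_points


class TestGabaCrossover:
    def test_crossing_voltage_bracketed(self, cl_branch):
        out = gaba_crossover(cl_branch)
        assert out is not None
        v_star, cl_star = out
        # E_Cl equals V at the crossing
        import math
        e_cl = 26.64 * math.log(cl_star / (145.0 - 7.0 * (cl_star - 6.0)))
        assert v_star == pytest.approx(e_cl, abs=1e-6)
        assert -40.0 < v_star < -30.0

    def test_no_crossing_returns_none(self, params_conservative, rest_597):
        short = continue_branch("Cl_i", (5.0, 6.5), rest_597.state,
                                params_conservative, step0=0.05)
        assert gaba_crossover(short) is None


class TestExports:
    def test_branch_csv_and_summary(self, cl_branch, tmp_path):
        import json
        import pandas as pd

        export_branch_csv(cl_branch, tmp_path / "b.csv")
        df = pd.read_csv(tmp_path / "b.csv")
        assert {"parameter", "V", "Cl_i", "stability"} <= set(df.columns)
        assert len(df) == len(cl_branch)
        summary = export_summary_json(cl_branch, tmp_path / "s.json")
        loaded = json.loads((tmp_path / "s.json").read_text())
        assert loaded["sn"] == summary["sn"]
        assert loaded["crossover_V"] == pytest.approx(summary["crossover_V"])

    def test_ode_export_lists_all_equations(self, params_conservative, tmp_path):
        export_ode_file(params_conservative, tmp_path / "m.ode")
        text = (tmp_path / "m.ode").read_text()
        for lhs in ("v'=", "m'=", "n'=", "h'=", "ko'=", "nai'=", "cli'="):
            assert lhs in text
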