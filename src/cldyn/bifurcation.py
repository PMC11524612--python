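"""Stationary analysis: fixed points, stability, continuation, SN/HB detection.

With potassium diffusion disabled and no bicarbonate-carrying GABA input the
model conserves Q = [Na⁺]ᵢ − [K⁺]ₒ/s − [Cl⁻]ᵢ − (γC/τ)·V (s is the K_o flux
scale), so its stationary set is a one-parameter family rather than isolated
points.  The family is traced by clamping one coordinate (conventionally
[Cl⁻]ᵢ, the slow variable of interest) and solving the remaining equations;
the clamped coordinate's own balance is then satisfied automatically by the
flux–charge redundancy and is verified, not assumed.  With bath coupling
active (eps_k > 0) fixed points are isolated and the natural continuation
parameter is the GABA step conductance.

Stability is read from Jacobian eigenvalues: the full 7×7 spectrum carries a
structural zero along the family in the conservative case; transverse
stability (and SN/HB detection on clamped branches) uses the reduced
spectrum with the clamped coordinate held fixed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.optimize import brentq, root

from . import model
from .model import DomainViolationError, ModelParams, NeuronState, STATE_NAMES

__all__ = [
    "FixedPoint", "Branch", "BifurcationPoint",
    "find_fixed_point", "jacobian", "jacobian_eigenvalues", "classify_stability",
    "continue_branch", "detect_bifurcations", "gaba_crossover",
    "export_branch_csv", "export_summary_json", "export_ode_file",
]

#: Residual scale applied to the ion equations inside Newton solves, so all
#: equation rows are O(1) for comparable convergence control.
_ION_SCALE = 1e3
#: Typical magnitudes used to scale arclength steps per coordinate.
_COORD_SCALE = {"V": 25.0, "m": 1.0, "n": 1.0, "h": 1.0,
                "K_o": 5.0, "Na_i": 5.0, "Cl_i": 5.0, "g_gaba": 0.25}

_EIG_TOL = 1e-6


class NoConvergenceError(RuntimeError):
    """Newton/continuation corrector failed to converge."""


class InconsistencyError(RuntimeError):
    """The omitted (clamped-coordinate) balance residual failed verification."""


@dataclass
class FixedPoint:
    """A stationary solution with its spectrum and stability class."""

    state: NeuronState
    params: ModelParams
    g_gaba: float
    eigenvalues: np.ndarray          # full 7×7 spectrum, sorted by Re descending
    reduced_eigenvalues: np.ndarray  # spectrum with the clamped coordinate held
    stability: str                   # stable | saddle | unstable_focus | marginal
    residual_norm: float
    clamp: Optional[str] = None

    @property
    def V(self) -> float:
        return self.state.V

    @property
    def Cl_i(self) -> float:
        return self.state.Cl_i

    def parameter_value(self, name: str) -> float:
        if name == "g_gaba":
            return self.g_gaba
        return getattr(self.state, name)


@dataclass
class BifurcationPoint:
    kind: str                 # "SN" | "HB"
    parameter: str
    value: float
    state: NeuronState


@dataclass
class Branch:
    """Ordered continuation branch with detected bifurcations."""

    parameter: str
    points: list[FixedPoint]
    sn_points: list[BifurcationPoint] = field(default_factory=list)
    hb_points: list[BifurcationPoint] = field(default_factory=list)
    truncated_reason: Optional[str] = None

    def parameter_values(self) -> np.ndarray:
        return np.array([p.parameter_value(self.parameter) for p in self.points])

    def __len__(self) -> int:
        return len(self.points)


# ---------------------------------------------------------------------------
# Core solves
# ---------------------------------------------------------------------------

def _rhs_vec(y: np.ndarray, params: ModelParams, g: float) -> np.ndarray:
    return model.rhs(0.0, y, params, g)


def _scaled_residual(y: np.ndarray, params: ModelParams, g: float,
                     rows: Sequence[int]) -> np.ndarray:
    try:
        d = _rhs_vec(y, params, g)
    except DomainViolationError:
        return np.full(len(rows), 1e6)
    out = d[list(rows)].copy()
    for k, r in enumerate(rows):
        if r >= 4:
            out[k] *= _ION_SCALE
        elif 1 <= r <= 3:
            out[k] *= 10.0
    return out


def is_conservative(params: ModelParams, g_gaba: float) -> bool:
    """True when the flux–charge redundancy makes fixed points a family."""
    return params.eps_k == 0.0 and (g_gaba == 0.0 or params.r_hco3 == 0.0)


def find_fixed_point(guess: NeuronState, params: ModelParams, *,
                     clamp: Optional[tuple[str, float]] = None,
                     g_gaba: float = 0.0, tol: float = 1e-12,
                     verify_tol: float = 1e-6) -> FixedPoint:
    """Solve for a stationary solution, optionally with one coordinate clamped.

    ``clamp`` is ``(name, value)`` where name is a state coordinate (usually
    ``"Cl_i"``, or ``"V"`` near a fold) — its own balance equation is dropped
    from the solve; in the conservative regime the dropped residual is then
    checked against ``verify_tol`` (flux–charge redundancy), raising
    :class:`InconsistencyError` if it fails.  With ``clamp=None`` all seven
    equations are solved (isolated fixed points, e.g. with bath coupling).
    """
    y0 = guess.as_array()
    if clamp is None:
        rows = list(range(7))
        free = list(range(7))
    else:
        name, value = clamp
        idx = STATE_NAMES.index(name)
        y0[idx] = value
        rows = [r for r in range(7) if r != idx]
        free = rows

    def F(x):
        y = y0.copy()
        y[free] = x
        return _scaled_residual(y, params, g_gaba, rows)

    sol = root(F, y0[free], method="hybr", tol=tol)
    if not sol.success:
        raise NoConvergenceError(f"fixed-point solve failed: {sol.message}")
    y = y0.copy()
    y[free] = sol.x
    resid = _rhs_vec(y, params, g_gaba)
    residual_norm = float(np.max(np.abs(resid[rows])))
    if clamp is not None and is_conservative(params, g_gaba):
        omitted = float(abs(resid[STATE_NAMES.index(clamp[0])]))
        if omitted > verify_tol:
            raise InconsistencyError(
                f"omitted {clamp[0]} balance residual {omitted:.3g} exceeds "
                f"{verify_tol:.3g}; the clamping assumption broke")
    state = NeuronState.from_array(y)
    ev_full = jacobian_eigenvalues(y, params, g_gaba)
    ev_red = (_eigs(jacobian(y, params, g_gaba, drop=STATE_NAMES.index(clamp[0])))
              if clamp is not None else ev_full)
    stability = classify_stability(
        ev_red if clamp is not None else ev_full,
        drop_structural=(clamp is None and is_conservative(params, g_gaba)))
    return FixedPoint(state=state, params=params, g_gaba=g_gaba,
                      eigenvalues=ev_full, reduced_eigenvalues=ev_red,
                      stability=stability, residual_norm=residual_norm,
                      clamp=clamp[0] if clamp else None)


def jacobian(y: np.ndarray, params: ModelParams, g_gaba: float = 0.0,
             drop: Optional[int] = None) -> np.ndarray:
    """Jacobian of the right-hand side by central finite differences.

    ``drop`` removes one coordinate's row and column (the clamped-coordinate
    reduced Jacobian).  Step 1e-6, scaled per variable.
    """
    idx = [i for i in range(7) if i != drop]
    J = np.empty((len(idx), len(idx)))
    for col, j in enumerate(idx):
        e = 1e-6 * max(1.0, abs(y[j]))
        yp = y.copy(); yp[j] += e
        ym = y.copy(); ym[j] -= e
        dp = _rhs_vec(yp, params, g_gaba)
        dm = _rhs_vec(ym, params, g_gaba)
        J[:, col] = (dp[idx] - dm[idx]) / (2.0 * e)
    return J


def _eigs(J: np.ndarray) -> np.ndarray:
    ev = np.linalg.eigvals(J)
    return ev[np.argsort(-ev.real)]


def jacobian_eigenvalues(y: np.ndarray, params: ModelParams,
                         g_gaba: float = 0.0) -> np.ndarray:
    """Eigenvalues of the full 7×7 Jacobian, sorted by real part (descending)."""
    return _eigs(jacobian(y, params, g_gaba))


def classify_stability(eigenvalues: np.ndarray, *, drop_structural: bool = False,
                       tol: float = _EIG_TOL) -> str:
    """Classify a spectrum as stable / saddle / unstable_focus / marginal.

    ``drop_structural`` removes the eigenvalue of smallest magnitude first
    (the zero mode along a conservative fixed-point family).
    """
    ev = np.asarray(eigenvalues)
    if drop_structural and len(ev):
        ev = np.delete(ev, int(np.argmin(np.abs(ev))))
    lead = ev[np.argmax(ev.real)]
    if abs(lead.real) < tol:
        return "marginal"
    if lead.real < 0:
        return "stable"
    return "unstable_focus" if abs(lead.imag) > tol else "saddle"


# ---------------------------------------------------------------------------
# Generic pseudo-arclength continuation
# ---------------------------------------------------------------------------

def _trace_branch(F: Callable[[np.ndarray], np.ndarray], u0: np.ndarray,
                  scales: np.ndarray, p_index: int, p_range: tuple[float, float],
                  *, step0: float = 0.2, min_step: float = 1e-5,
                  max_step: float = 0.5, max_points: int = 4000,
                  direction: float = 1.0) -> tuple[list[np.ndarray], Optional[str]]:
    """Pseudo-arclength continuation of F(u) = 0 (n equations, n+1 unknowns).

    ``u`` stacks the free coordinates and the parameter at ``p_index``;
    ``scales`` normalizes each coordinate for the arclength metric.  Returns
    the accepted points and, if the trace stopped early, the reason.
    """
    n = len(u0) - 1
    lo, hi = p_range

    def corrector(pred, tangent, ds):
        def G(u):
            r = F(u)
            arc = np.dot((u - pred) / scales, tangent)
            return np.r_[r, arc]
        sol = root(G, pred, method="hybr", tol=1e-12)
        return sol

    def tangent_at(u, prev_tan):
        # null vector of dF/du, oriented along prev_tan
        J = np.empty((n, n + 1))
        for j in range(n + 1):
            e = 1e-7 * max(1.0, abs(u[j]))
            up = u.copy(); up[j] += e
            um = u.copy(); um[j] -= e
            J[:, j] = (F(up) - F(um)) / (2.0 * e)
        # scale columns, solve for null space
        Js = J * scales[None, :]
        _, _, vh = np.linalg.svd(Js)
        t = vh[-1]
        if prev_tan is not None and np.dot(t, prev_tan) < 0:
            t = -t
        return t / np.linalg.norm(t)

    # converge the starting point with p clamped
    def F_clamped(x, pval):
        u = np.empty(n + 1)
        u[:p_index] = x[:p_index]
        u[p_index] = pval
        u[p_index + 1:] = x[p_index:]
        return F(u)

    x0 = np.delete(u0, p_index)
    sol = root(lambda x: F_clamped(x, u0[p_index]), x0, method="hybr", tol=1e-12)
    if not sol.success:
        raise NoConvergenceError("continuation seed did not converge")
    u = np.insert(sol.x, p_index, u0[p_index])

    pts = [u.copy()]
    tan = tangent_at(u, None)
    if tan[p_index] * direction < 0:
        tan = -tan
    ds = step0
    fails = 0
    while len(pts) < max_points:
        pred = u + ds * tan * scales
        sol = corrector(pred, tan, ds)
        ok = sol.success and np.max(np.abs(F(sol.x))) < 1e-8
        if not ok:
            ds *= 0.5
            fails += 1
            if ds < min_step or fails > 60:
                return pts, "corrector failed repeatedly"
            continue
        fails = 0
        u_new = sol.x
        if not (lo - 1e-9 <= u_new[p_index] <= hi + 1e-9):
            # land exactly on the boundary with a clamped solve
            pb = float(np.clip(u_new[p_index], lo, hi))
            solb = root(lambda x: F_clamped(x, pb), np.delete(u_new, p_index),
                        method="hybr", tol=1e-12)
            if solb.success:
                pts.append(np.insert(solb.x, p_index, pb))
            return pts, None
        tan_new = tangent_at(u_new, tan)
        u = u_new
        tan = tan_new
        pts.append(u.copy())
        ds = min(max_step, ds * 1.3)
    return pts, "max_points reached"


# ---------------------------------------------------------------------------
# Model-facing continuation
# ---------------------------------------------------------------------------

def _branch_setup(param_name: str, params: ModelParams, g_gaba: float):
    """Return (F, pack, unpack, p_index, scales, rows) for a continuation run."""
    if param_name == "g_gaba":
        # all 7 state equations active; parameter is the held conductance
        rows = list(range(7))

        def F(u):
            return _scaled_residual(u[:7], params, u[7], rows)

        scales = np.array([_COORD_SCALE[n] for n in STATE_NAMES] + [_COORD_SCALE["g_gaba"]])
        return F, 7, scales, rows
    if param_name in STATE_NAMES:
        idx = STATE_NAMES.index(param_name)
        rows = [r for r in range(7) if r != idx]

        def F(u):
            y = np.empty(7)
            others = [i for i in range(7) if i != idx]
            y[others] = u[:6]
            y[idx] = u[6]
            return _scaled_residual(y, params, g_gaba, rows)

        scales = np.array([_COORD_SCALE[n] for n in STATE_NAMES if n != param_name]
                          + [_COORD_SCALE[param_name]])
        return F, 6, scales, rows
    raise ValueError(f"unknown continuation parameter {param_name!r}")


def _u_to_point(u: np.ndarray, param_name: str, params: ModelParams,
                g_gaba: float) -> FixedPoint:
    if param_name == "g_gaba":
        y = u[:7].copy()
        g = float(u[7])
        clamp_idx = None
    else:
        idx = STATE_NAMES.index(param_name)
        y = np.empty(7)
        others = [i for i in range(7) if i != idx]
        y[others] = u[:6]
        y[idx] = float(u[6])
        g = g_gaba
        clamp_idx = idx
    resid = _rhs_vec(y, params, g)
    rows = [r for r in range(7) if r != clamp_idx] if clamp_idx is not None else range(7)
    ev_full = jacobian_eigenvalues(y, params, g)
    ev_red = (_eigs(jacobian(y, params, g, drop=clamp_idx))
              if clamp_idx is not None else ev_full)
    stability = classify_stability(
        ev_red if clamp_idx is not None else ev_full,
        drop_structural=(clamp_idx is None and is_conservative(params, g)))
    return FixedPoint(state=NeuronState.from_array(y), params=params, g_gaba=g,
                      eigenvalues=ev_full, reduced_eigenvalues=ev_red,
                      stability=stability,
                      residual_norm=float(np.max(np.abs(resid[list(rows)]))),
                      clamp=param_name if clamp_idx is not None else None)


def continue_branch(param_name: str, p_range: tuple[float, float],
                    initial_guess: NeuronState, params: ModelParams, *,
                    g_gaba: float = 0.0, step0: float = 0.2,
                    max_points: int = 4000, direction: float = 1.0,
                    detect: bool = True) -> Branch:
    """Trace the fixed-point branch in ``param_name`` over ``p_range``.

    ``param_name`` is a clamped state coordinate (``"Cl_i"`` for the
    conservative family) or ``"g_gaba"`` (isolated fixed points under a held
    GABA step, e.g. with bath coupling).  Pseudo-arclength continuation
    handles folds; every accepted point satisfies the active equations to
    1e-8 (scaled).  Bifurcations are refined if ``detect``.
    """
    F, n, scales, rows = _branch_setup(param_name, params, g_gaba)
    y0 = initial_guess.as_array()
    if param_name == "g_gaba":
        u0 = np.r_[y0, g_gaba]
        p_index = 7
    else:
        idx = STATE_NAMES.index(param_name)
        start = float(np.clip(y0[idx], *p_range))
        u0 = np.r_[np.delete(y0, idx), start]
        p_index = 6
    try:
        pts, reason = _trace_branch(F, u0, scales, p_index, p_range,
                                    step0=step0, max_points=max_points,
                                    direction=direction)
    except DomainViolationError as exc:
        raise NoConvergenceError(f"branch left the validity region: {exc}") from exc
    points = [_u_to_point(u, param_name, params, g_gaba) for u in pts]
    branch = Branch(parameter=param_name, points=points, truncated_reason=reason)
    if detect and len(points) >= 3:
        detect_bifurcations(branch)
    return branch


# ---------------------------------------------------------------------------
# Bifurcation detection and refinement
# ---------------------------------------------------------------------------

def _local_solver(branch: Branch):
    """Factory: solve the branch equations with a chosen coordinate clamped,
    warm-started from a nearby branch point; parameter is among the unknowns."""
    params = branch.points[0].params
    param = branch.parameter

    def solve_at(coord: str, value: float, near: FixedPoint):
        y0 = near.state.as_array()
        g0 = near.g_gaba
        ci = STATE_NAMES.index(coord)
        if param == "g_gaba":
            rows = list(range(7))
            free = [i for i in range(7) if i != ci]

            def F(x):
                y = y0.copy()
                y[ci] = value
                y[free] = x[:6]
                return _scaled_residual(y, params, x[6], rows)

            sol = root(F, np.r_[y0[free], g0], method="hybr", tol=1e-12)
            if not sol.success:
                raise NoConvergenceError(f"local solve at {coord}={value} failed")
            y = y0.copy()
            y[ci] = value
            y[free] = sol.x[:6]
            return y, float(sol.x[6])
        pi = STATE_NAMES.index(param)
        rows = [r for r in range(7) if r != pi]
        free = [i for i in range(7) if i not in (ci, pi)]

        def F(x):
            y = y0.copy()
            y[ci] = value
            y[free] = x[:5]
            y[pi] = x[5]
            return _scaled_residual(y, params, g0, rows)

        sol = root(F, np.r_[y0[free], y0[pi]], method="hybr", tol=1e-12)
        if not sol.success:
            raise NoConvergenceError(f"local solve at {coord}={value} failed")
        y = y0.copy()
        y[ci] = value
        y[free] = sol.x[:5]
        y[pi] = sol.x[5]
        return y, g0

    return solve_at


def _param_of(branch: Branch, y: np.ndarray, g: float) -> float:
    if branch.parameter == "g_gaba":
        return g
    return float(y[STATE_NAMES.index(branch.parameter)])


def _crossing_eig(branch: Branch, y: np.ndarray, g: float) -> float:
    """Max real part over the complex pairs of the branch-relevant spectrum."""
    params = branch.points[0].params
    if branch.parameter == "g_gaba":
        ev = jacobian_eigenvalues(y, params, g)
    else:
        ev = _eigs(jacobian(y, params, g, drop=STATE_NAMES.index(branch.parameter)))
    cplx = ev[np.abs(ev.imag) > 1e-8]
    if len(cplx) == 0:
        real = ev[np.abs(ev.imag) <= 1e-8]
        return float(real.real.max()) if len(real) else -1.0
    return float(cplx.real.max())


def detect_bifurcations(branch: Branch, *, tol: float = 5e-3) -> Branch:
    """Locate and refine SN (folds in the parameter) and HB (complex-pair
    crossings) along the branch; results are stored on the branch in order.

    Folds are refined by bracketing the zero of dp/dξ where ξ is the local
    coordinate with the largest tangent component; Hopf points by bisection
    on the sign of the leading complex-pair real part, with fresh local
    solves.  Both to ``tol`` in the parameter.
    """
    branch.sn_points = []
    branch.hb_points = []
    if len(branch.points) < 3:
        return branch
    solve_at = _local_solver(branch)
    pv = branch.parameter_values()
    dp = np.diff(pv)

    # --- folds ---
    for i in range(1, len(dp)):
        if dp[i - 1] * dp[i] < 0 and abs(dp[i - 1]) > 1e-12:
            near = branch.points[i]
            coord = _fold_local_coordinate(branch, i)
            if coord is None:
                continue
            try:
                val, y, g = _refine_fold(branch, i, coord, solve_at, tol)
            except (NoConvergenceError, DomainViolationError):
                val, y, g = pv[i], near.state.as_array(), near.g_gaba
            branch.sn_points.append(BifurcationPoint(
                kind="SN", parameter=branch.parameter, value=val,
                state=NeuronState.from_array(y)))

    # --- Hopf crossings ---
    res = [_crossing_eig(branch, p.state.as_array(), p.g_gaba) for p in branch.points]
    for i in range(1, len(res)):
        if res[i - 1] * res[i] < 0:
            try:
                val, y, g = _refine_hopf(branch, i, solve_at, tol)
            except (NoConvergenceError, DomainViolationError):
                val = 0.5 * (pv[i - 1] + pv[i])
                y, g = branch.points[i].state.as_array(), branch.points[i].g_gaba
            branch.hb_points.append(BifurcationPoint(
                kind="HB", parameter=branch.parameter, value=val,
                state=NeuronState.from_array(y)))
    return branch


def _fold_local_coordinate(branch: Branch, i: int) -> Optional[str]:
    """Coordinate varying most strongly (relative to scale) across the fold."""
    a = branch.points[i - 1].state.as_array()
    b = branch.points[min(i + 1, len(branch.points) - 1)].state.as_array()
    diffs = np.abs(b - a) / np.array([_COORD_SCALE[n] for n in STATE_NAMES])
    if branch.parameter != "g_gaba":
        diffs[STATE_NAMES.index(branch.parameter)] = 0.0
    order = np.argsort(-diffs)
    for j in order:
        if diffs[j] > 0:
            return STATE_NAMES[j]
    return None


def _refine_fold(branch, i, coord, solve_at, tol):
    near = branch.points[i]
    ci = STATE_NAMES.index(coord)
    xa = branch.points[i - 1].state.as_array()[ci]
    xb = branch.points[min(i + 1, len(branch.points) - 1)].state.as_array()[ci]
    h = 1e-4 * _COORD_SCALE[coord]

    def dP(x):
        yp, gp = solve_at(coord, x + h, near)
        ym, gm = solve_at(coord, x - h, near)
        return _param_of(branch, yp, gp) - _param_of(branch, ym, gm)

    fa, fb = dP(xa), dP(xb)
    if fa * fb > 0:
        raise NoConvergenceError("fold derivative does not change sign")
    # map parameter tolerance to coordinate tolerance crudely via secant slope
    xtol = min(abs(xb - xa) * 1e-3 + 1e-9, 1e-4 * _COORD_SCALE[coord])
    x_star = brentq(dP, min(xa, xb), max(xa, xb), xtol=xtol)
    y, g = solve_at(coord, x_star, near)
    return _param_of(branch, y, g), y, g


def _refine_hopf(branch, i, solve_at, tol):
    a, b = branch.points[i - 1], branch.points[i]
    pv_a = a.parameter_value(branch.parameter)
    pv_b = b.parameter_value(branch.parameter)
    # choose a local coordinate monotone across the interval (fall back to V)
    coord = _fold_local_coordinate(branch, i) or "V"
    ci = STATE_NAMES.index(coord)
    xa, xb = a.state.as_array()[ci], b.state.as_array()[ci]
    if xa == xb:
        return 0.5 * (pv_a + pv_b), b.state.as_array(), b.g_gaba
    near = b

    def f(x):
        y, g = solve_at(coord, x, near)
        return _crossing_eig(branch, y, g)

    x_star = brentq(f, min(xa, xb), max(xa, xb),
                    xtol=abs(xb - xa) * 1e-6 + 1e-12, maxiter=200)
    y, g = solve_at(coord, x_star, near)
    return _param_of(branch, y, g), y, g


def gaba_crossover(branch: Branch) -> Optional[tuple[float, float]]:
    """Voltage (and parameter value) where the branch voltage crosses E_Cl.

    Along the branch, E_Cl([Cl⁻]ᵢ) rises while the fixed-point voltage falls
    toward it; the crossing marks where a pure-chloride GABA conductance
    switches from inhibitory (V > E_Cl) to depolarizing.  Returns
    ``(V_star, parameter_at_crossing)`` or None when the branch does not
    cross.  The bracketing interval is refined by a local re-solve.
    """
    params = branch.points[0].params

    def h_of(fp: FixedPoint) -> float:
        _, _, E_Cl = model.reversal_potentials(fp.state, params)
        return fp.state.V - E_Cl

    hs = [h_of(p) for p in branch.points]
    solve_at = _local_solver(branch)
    for i in range(1, len(hs)):
        if hs[i - 1] * hs[i] < 0:
            a, b = branch.points[i - 1], branch.points[i]
            xa, xb = a.state.V, b.state.V

            def f(Vc):
                y, g = solve_at("V", Vc, b)
                st = NeuronState.from_array(y)
                _, _, E_Cl = model.reversal_potentials(st, params)
                return Vc - E_Cl

            try:
                v_star = brentq(f, min(xa, xb), max(xa, xb), xtol=1e-8)
                y, g = solve_at("V", v_star, b)
            except (ValueError, NoConvergenceError):
                w = hs[i - 1] / (hs[i - 1] - hs[i])
                v_star = xa + w * (xb - xa)
                y, g = b.state.as_array(), b.g_gaba
            return float(v_star), _param_of(branch, y, g)
    return None


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------

def export_branch_csv(branch: Branch, path) -> None:
    import pandas as pd

    rows = []
    for p in branch.points:
        lead = p.reduced_eigenvalues[0]
        rows.append({
            "parameter": p.parameter_value(branch.parameter),
            "V": p.state.V, "Cl_i": p.state.Cl_i, "Na_i": p.state.Na_i,
            "K_o": p.state.K_o, "lead_re": lead.real, "lead_im": lead.imag,
            "stability": p.stability,
        })
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def export_summary_json(branch: Branch, path=None) -> dict:
    cross = gaba_crossover(branch)
    summary = {
        "parameter": branch.parameter,
        "n_points": len(branch.points),
        "sn": [b.value for b in branch.sn_points],
        "hb": [b.value for b in branch.hb_points],
        "crossover_V": None if cross is None else cross[0],
        "truncated_reason": branch.truncated_reason,
    }
    if path is not None:
        with open(path, "w") as fh:
            json.dump(summary, fh, indent=2)
    return summary


def export_ode_file(params: ModelParams, path) -> None:
    """Write the model as an XPPAUT-compatible .ode file (for cross-checking)."""
    s = params.ko_flux_scale
    text = f"""# chloride-potassium single-compartment neuron model
par ggaba=0
par epsk={params.eps_k}, kbath={params.K_bath}
par gna={params.gNa}, gk={params.gK}, gnal={params.gNaL}, gkl={params.gKL}, gcll={params.gClL}
par gamma={params.gamma}, rho={params.rho}, ukcc2={params.U_kcc2}, unkcc1={params.U_nkcc1}
par beta={params.beta}, ehco3={params.E_hco3}, rhco3={params.r_hco3}, tau={params.tau_ion}
par koscale={s}
ki=100-nai+cli
nao=135-beta*(nai-20)
clo=145-beta*(cli-6)
ena=26.64*ln(nao/nai)
ek=26.64*ln(ko/ki)
ecl=26.64*ln(cli/clo)
am=0.32*(v+54)/(1-exp(-(v+54)/4))
bm=0.28*(v+27)/(exp((v+27)/5)-1)
ah=0.128*exp(-(v+50)/18)
bh=4/(1+exp(-(v+27)/5))
an=0.032*(v+52)/(1-exp(-(v+52)/5))
bn=0.5*exp(-(v+57)/40)
rpump=rho/(1+exp((25-nai)/3))/(1+exp(3.5-ko))
rkcc2=ukcc2*ln(ki*cli/(ko*clo))
fko=1/(1+exp(16-ko))
rnkcc1=unkcc1*fko*(ln(ko*clo/(ki*cli))+ln(nao*clo/(nai*cli)))
ina=(gna*m^3*h+gnal)*(v-ena)
ik=(gk*n^4+gkl)*(v-ek)
icl=gcll*(v-ecl)
igcl=ggaba*(v-ecl)
igh=rhco3*ggaba*(v-ehco3)
v'=-(ina+ik+icl+rpump/gamma+igcl+igh)
m'=am*(1-m)-bm*m
n'=an*(1-n)-bn*n
h'=ah*(1-h)-bh*h
ko'=(koscale*(gamma*ik-2*rpump-rnkcc1+rkcc2)-epsk*(ko-kbath))/tau
nai'=(-gamma*ina-3*rpump+rnkcc1)/tau
cli'=(gamma*(icl+igcl)+2*rnkcc1-rkcc2)/tau
init v=-70.7 m=0.013 n=0.06 h=0.98 ko=3.0 nai=20.0 cli=6.0
done
"""
    with open(path, "w") as fh:
        fh.write(text)
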