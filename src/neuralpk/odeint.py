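"""ODE solving contracts shared by mechanistic models and neural ODEs.

Two solvers live here:

* :func:`solve` — adaptive Runge–Kutta (scipy) with explicit breakpoint
  handling for piecewise right-hand sides (e.g. end of infusion). Used for
  data generation and final evaluation at tight tolerances.
* :func:`solve_rk4_sens` — fixed-grid classic RK4 that simultaneously
  propagates the exact sensitivity of the discrete solution with respect to
  all trainable parameters (forward-mode, discretize-then-differentiate).
  Because the sensitivity stages are evaluated at the same stage points as
  the state stages, the returned sensitivities are the exact derivatives of
  the RK4-discretized trajectory — gradients match finite differences of
  the solver output to rounding error.

The right-hand-side contract everywhere is ``rhs(state, t) -> derivative``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "SolverConfig",
    "solve",
    "solve_rk4_sens",
    "make_grid",
    "derivative_along_trajectory",
]


@dataclass
class SolverConfig:
    """Configuration of the adaptive solver.

    ``breakpoints`` are times where the right-hand side is discontinuous;
    integration restarts there so no discontinuity is stepped over.
    """

    method: str = "RK45"
    rtol: float = 1e-6
    atol: float = 1e-8
    breakpoints: tuple = ()
    max_steps: int = 100_000

    def __post_init__(self):
        if self.rtol <= 0 or self.atol <= 0:
            raise ValueError("tolerances must be positive")


class SolverError(RuntimeError):
    pass


def solve(rhs, y0, times, cfg: SolverConfig | None = None) -> np.ndarray:
    """Integrate ``rhs`` from ``times[0]`` and return the trajectory.

    Returns an array of shape ``(len(times), len(y0))`` whose first row is
    exactly ``y0``. The span is split at each declared breakpoint.
    """
    cfg = cfg or SolverConfig()
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or np.any(np.diff(times) < 0):
        raise ValueError("times must be a sorted 1-d array")
    y0 = np.atleast_1d(np.asarray(y0, dtype=float))
    out = np.empty((len(times), len(y0)))
    out[0] = y0

    t0, t_end = times[0], times[-1]
    if t_end == t0:
        return np.tile(y0, (len(times), 1))
    cuts = [b for b in cfg.breakpoints if t0 < b < t_end]
    spans = np.concatenate([[t0], np.sort(cuts), [t_end]])

    y = y0.copy()
    for a, b in zip(spans[:-1], spans[1:]):
        mask = (times > a) & (times <= b)
        t_eval = np.unique(np.concatenate([times[mask], [b]]))
        # evaluate the rhs on this span's side of any discontinuity: the
        # stage at t = a (a breakpoint) must use the post-jump dynamics
        lo = np.nextafter(a, b)
        sol = solve_ivp(
            lambda t, x: np.asarray(rhs(x, min(max(t, lo), b)), dtype=float),
            (a, b),
            y,
            method=cfg.method,
            t_eval=t_eval,
            rtol=cfg.rtol,
            atol=cfg.atol,
        )
        if not sol.success:
            raise SolverError(f"integration failed on [{a}, {b}]: {sol.message}")
        for j, t in enumerate(sol.t):
            hits = np.where(mask & np.isclose(times, t, rtol=0, atol=1e-12))[0]
            out[hits] = sol.y[:, j]
        y = sol.y[:, -1]
    # duplicated initial times
    out[np.isclose(times, t0, rtol=0, atol=1e-12)] = y0
    return out


def make_grid(times, h_max: float, breakpoints=(), t0: float = 0.0) -> np.ndarray:
    """Fixed integration grid containing ``t0``, all requested times and
    breakpoints, with every interval subdivided to steps <= ``h_max``."""
    knots = np.unique(
        np.concatenate([[t0], np.asarray(times, float), np.asarray(breakpoints, float)])
    )
    knots = knots[knots >= t0]
    grid = [knots[0]]
    for a, b in zip(knots[:-1], knots[1:]):
        nsub = max(1, int(np.ceil((b - a) / h_max)))
        grid.extend(np.linspace(a, b, nsub + 1)[1:])
    return np.asarray(grid)


def solve_rk4_sens(rhs_jac, y0, S0, grid):
    """Classic RK4 on a fixed grid with forward parameter sensitivities.

    Parameters
    ----------
    rhs_jac : callable
        ``rhs_jac(y, t) -> (f, J_y, J_theta)`` with shapes ``(dim,)``,
        ``(dim, dim)``, ``(dim, P)``.
    y0, S0 : initial state ``(dim,)`` and initial sensitivity ``(dim, P)``
        (``S0`` is nonzero when the initial condition depends on a
        parameter, e.g. x(0) = d/V with estimated V).
    grid : sorted times starting at the initial time.

    Returns ``(Y, S)`` of shapes ``(len(grid), dim)`` and
    ``(len(grid), dim, P)``.
    """
    grid = np.asarray(grid, dtype=float)
    y = np.asarray(y0, dtype=float).copy()
    S = np.asarray(S0, dtype=float).copy()
    dim, P = S.shape
    Y = np.empty((len(grid), dim))
    Sout = np.empty((len(grid), dim, P))
    Y[0], Sout[0] = y, S
    for k in range(len(grid) - 1):
        t, h = grid[k], grid[k + 1] - grid[k]
        f1, Jy1, Jt1 = rhs_jac(y, t)
        dS1 = Jy1 @ S + Jt1
        y2 = y + 0.5 * h * f1
        S2 = S + 0.5 * h * dS1
        f2, Jy2, Jt2 = rhs_jac(y2, t + 0.5 * h)
        dS2 = Jy2 @ S2 + Jt2
        y3 = y + 0.5 * h * f2
        S3 = S + 0.5 * h * dS2
        f3, Jy3, Jt3 = rhs_jac(y3, t + 0.5 * h)
        dS3 = Jy3 @ S3 + Jt3
        y4 = y + h * f3
        S4 = S + h * dS3
        f4, Jy4, Jt4 = rhs_jac(y4, t + h)
        dS4 = Jy4 @ S4 + Jt4
        y = y + (h / 6.0) * (f1 + 2 * f2 + 2 * f3 + f4)
        S = S + (h / 6.0) * (dS1 + 2 * dS2 + 2 * dS3 + dS4)
        if not np.all(np.isfinite(y)):
            raise SolverError(f"non-finite state at t = {grid[k + 1]:.4g}")
        Y[k + 1], Sout[k + 1] = y, S
    return Y, Sout


def solve_rk4(rhs, y0, grid):
    """Plain fixed-grid RK4 (no sensitivities)."""
    grid = np.asarray(grid, dtype=float)
    y = np.atleast_1d(np.asarray(y0, dtype=float)).copy()
    Y = np.empty((len(grid), len(y)))
    Y[0] = y
    for k in range(len(grid) - 1):
        t, h = grid[k], grid[k + 1] - grid[k]
        k1 = np.asarray(rhs(y, t))
        k2 = np.asarray(rhs(y + 0.5 * h * k1, t + 0.5 * h))
        k3 = np.asarray(rhs(y + 0.5 * h * k2, t + 0.5 * h))
        k4 = np.asarray(rhs(y + h * k3, t + h))
        y = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        Y[k + 1] = y
    return Y


def derivative_along_trajectory(rhs, trajectory, times, central_index: int = 0):
    """Pair each trajectory point with the central-compartment derivative.

    Returns ``(conc, deriv)`` arrays — the raw material of the
    derivative-versus-state plot, ordered by time. ``central_index`` selects
    the state component matched to measured concentration (index 0 for
    one-dimensional structures; models declare theirs).
    """
    trajectory = np.atleast_2d(np.asarray(trajectory, dtype=float))
    times = np.asarray(times, dtype=float)
    if trajectory.shape[0] != len(times):
        raise ValueError(
            f"trajectory rows ({trajectory.shape[0]}) != len(times) ({len(times)})"
        )
    conc = trajectory[:, central_index]
    deriv = np.array(
        [
            np.asarray(rhs(trajectory[i], times[i]))[central_index]
            for i in range(len(times))
        ]
    )
    return conc, deriv
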