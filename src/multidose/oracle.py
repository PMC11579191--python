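"""Independent numerical verification: jump-ODE integration and quadrature.

This module deliberately knows nothing about the closed-form solutions.  It
integrates the underlying piecewise-linear ODE systems segment by segment
with an adaptive high-order Runge-Kutta method (DOP853), restarting at every
dose instant (and, for finite-absorption-time models, at every phase
cutoff) with the prescribed jump applied to the state:

* oral:    y' = -ka y,  x' = ka*gamma*y - ke x;   y += d_n at dose instants
* bolus:   x' = -ke x;                            x += delta_n at dose instants
* F.A.T.:  assimilation as oral but y := d_n at dose instants; y := 0 and
           pure elimination after each cutoff s_n

Matrix-exponential stepping is avoided on purpose — it would share algebra
with the closed forms this oracle exists to check.  Samples landing exactly
on an event report the post-event (right-continuous) state.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import quad, solve_ivp

from .core import DoseRegimen, PBFTPKRegimen, PKParameters, dose_times
from .profile import ConcentrationProfile, _check_grid

__all__ = [
    "OracleError",
    "integrate_oral",
    "integrate_bolus",
    "integrate_pbftpk",
    "auc_numeric",
]

DEFAULT_TOL = 1e-12


class OracleError(RuntimeError):
    """The integrator failed; results must never degrade silently."""


def _check_tol(tol: float) -> None:
    if not (1e-13 <= tol <= 1e-6):
        raise ValueError(f"tol must be in [1e-13, 1e-6], got {tol!r}")


def _run_segments(rhs, breaks, jumps, grid, state0, tol):
    """Integrate ``rhs`` over consecutive segments, applying state jumps.

    ``breaks`` are the event times ``(b_0, ..., b_M)``; before segment ``i``
    (``[b_{i-1}, b_i]``) the callable ``jumps[i-1]`` maps the incoming state
    to the post-event state.  Returns an array of states sampled at ``grid``
    (post-event convention at the breakpoints themselves).
    """
    dim = len(state0)
    out = np.full((grid.size, dim), np.nan)
    state = np.asarray(state0, dtype=float)
    for i in range(len(breaks) - 1):
        t0, t1 = float(breaks[i]), float(breaks[i + 1])
        state = jumps[i](state)
        at_start = grid == t0
        out[at_start] = state
        inner = (grid > t0) & (grid < t1)
        t_eval = np.concatenate([grid[inner], [t1]])
        sol = solve_ivp(
            rhs, (t0, t1), state, method="DOP853", t_eval=t_eval,
            rtol=tol, atol=tol * 1e-3,
        )
        if not sol.success:
            raise OracleError(f"integration failed on [{t0}, {t1}]: {sol.message}")
        out[inner] = sol.y[:, :-1].T
        state = sol.y[:, -1]
    out[grid == breaks[-1]] = state  # schedule end: no further event
    return out


def integrate_oral(
    params: PKParameters,
    regimen: DoseRegimen,
    t_grid,
    tol: float = DEFAULT_TOL,
) -> ConcentrationProfile:
    """Numerically integrate the oral multi-dose system on ``t_grid``.

    At each dose instant the absorbable amount jumps up by the dose
    (``y += d_n``); ``x`` is continuous.
    """
    _check_tol(tol)
    grid = _check_grid(np.asarray(t_grid, dtype=float), regimen.end_time)
    times = dose_times(regimen)
    ka, ke, g = params.ka, params.ke, params.gamma

    def rhs(_t, s):
        return (-ka * s[0], ka * g * s[0] - ke * s[1])

    jumps = [
        (lambda s, d=d: s + np.array([d, 0.0])) for d in regimen.doses
    ]
    states = _run_segments(rhs, times, jumps, grid, np.zeros(2), tol)
    cycle = np.clip(np.searchsorted(times, grid, side="right"), 1, regimen.n_doses)
    return ConcentrationProfile(
        t=grid, x=states[:, 1], cycle=cycle.astype(int), y=states[:, 0]
    )


def integrate_bolus(
    ke: float,
    regimen: DoseRegimen,
    t_grid,
    tol: float = DEFAULT_TOL,
) -> ConcentrationProfile:
    """Numerically integrate the bolus system (``x' = -ke x``, ``x += delta_n``)."""
    _check_tol(tol)
    if ke <= 0:
        raise ValueError(f"ke must be > 0, got {ke!r}")
    grid = _check_grid(np.asarray(t_grid, dtype=float), regimen.end_time)
    times = dose_times(regimen)

    def rhs(_t, s):
        return (-ke * s[0],)

    jumps = [(lambda s, d=d: s + np.array([d])) for d in regimen.doses]
    states = _run_segments(rhs, times, jumps, grid, np.zeros(1), tol)
    cycle = np.clip(np.searchsorted(times, grid, side="right"), 1, regimen.n_doses)
    return ConcentrationProfile(t=grid, x=states[:, 0], cycle=cycle.astype(int))


def integrate_pbftpk(
    params: PKParameters,
    regimen: PBFTPKRegimen,
    t_grid,
    tol: float = DEFAULT_TOL,
) -> ConcentrationProfile:
    """Numerically integrate the finite-absorption-time system.

    Events alternate between dose instants (``y := d_n``) and absorption
    cutoffs (``y := 0``); between events the oral right-hand side applies
    (with ``y = 0`` it degenerates to pure elimination).  Cutoffs with
    ``sigma_n = tau_n`` coincide with the next dose instant and produce a
    zero-length clearance segment, which is skipped.
    """
    _check_tol(tol)
    base = regimen.regimen
    grid = _check_grid(np.asarray(t_grid, dtype=float), base.end_time)
    times = dose_times(base)
    cutoffs = regimen.absorption_times
    ka, ke, g = params.ka, params.ke, params.gamma

    def rhs(_t, s):
        return (-ka * s[0], ka * g * s[0] - ke * s[1])

    breaks: list[float] = []
    jumps: list = []
    for n in range(base.n_doses):
        breaks.append(float(times[n]))
        jumps.append(lambda s, d=base.doses[n]: np.array([d, s[1]]))  # y := d_n
        if cutoffs[n] < times[n + 1]:
            breaks.append(float(cutoffs[n]))
            jumps.append(lambda s: np.array([0.0, s[1]]))  # y := 0
    breaks.append(float(times[-1]))
    states = _run_segments(rhs, np.asarray(breaks), jumps, grid, np.zeros(2), tol)
    cycle = np.clip(np.searchsorted(times, grid, side="right"), 1, base.n_doses)
    offset = grid - times[cycle - 1]
    phase = np.where(
        offset < np.asarray(regimen.fat)[cycle - 1], "assimilation", "clearance"
    ).astype(object)
    return ConcentrationProfile(
        t=grid, x=states[:, 1], cycle=cycle.astype(int), y=states[:, 0], phase=phase
    )


def auc_numeric(curve, a: float, b: float, tol: float = 1e-10) -> float:
    """Adaptive quadrature of an evaluable concentration curve over ``[a, b]``."""
    if not a < b:
        raise ValueError(f"need a < b, got a={a!r}, b={b!r}")

    def f(t: float) -> float:
        v = float(curve(t))
        if not np.isfinite(v):
            raise OracleError(f"curve evaluated to non-finite value at t={t}")
        return v

    val, _err = quad(f, a, b, epsabs=0.0, epsrel=tol, limit=500)
    return val
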