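"""Closed-form oral multi-dose dynamics (generalized Bateman superposition).

After a single oral dose ``d`` the plasma concentration follows the Bateman
function ``x(t) = k d (e^{-ke t} - e^{-ka t})`` with ``k = ka*gamma/(ka-ke)``.
Under a multi-dose schedule the state within cycle ``n`` is again a
two-exponential,

    x(t) = C1(n) e^{-ke (t - t_{n-1})} - C2(n) e^{-ka (t - t_{n-1})}
    y(t) = S_alpha(n) e^{-ka (t - t_{n-1})}

where the cycle coefficients are built from the dose-history product sums

    S_alpha(n) = sum_{i=1}^{n-1} d_i prod_{j=i}^{n-1} alpha_j + d_n,
    alpha_s = e^{-ka tau_s}        (S_beta analogously with beta_s = e^{-ke tau_s})

with ``C2(n) = k S_alpha(n)`` and ``C1(n) = k S_beta(n)``.  The concentration
``x`` is continuous at every dose instant while the amount awaiting
absorption ``y`` jumps up by exactly ``d_n``.

The product sums satisfy the forward recursion ``S(n+1) = factor_n S(n) +
d_{n+1}`` (factor ``alpha_n`` resp. ``beta_n``), which is how they are
computed here; the literal double sum is kept in the test suite as the
reference implementation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import DoseRegimen, PKParameters, dose_times
from .profile import ConcentrationProfile, _check_grid

__all__ = [
    "DoseHistorySums",
    "CycleCoefficients",
    "bateman_single",
    "dose_history_sums",
    "cycle_coefficients",
    "concentration",
    "absorbed_amount",
    "profile",
]


@dataclass(frozen=True)
class DoseHistorySums:
    """The product sums ``S_alpha(n)``, ``S_beta(n)`` for one cycle."""

    n: int
    s_alpha: float
    s_beta: float


@dataclass(frozen=True)
class CycleCoefficients:
    """Exponential-mode coefficients of ``x`` within one cycle.

    ``x(t) = c1 e^{-ke (t - t_{n-1})} - c2 e^{-ka (t - t_{n-1})}``.
    """

    n: int
    c1: float
    c2: float

    @property
    def start_value(self) -> float:
        """``x(t_{n-1}) = c1 - c2`` (continuity with the previous cycle)."""
        return self.c1 - self.c2


def bateman_single(params: PKParameters, d: float, t):
    """Single-dose Bateman concentration ``k d (e^{-ke t} - e^{-ka t})``.

    Vectorized over ``t``; nonnegative for all ``t >= 0`` regardless of
    flip-flop ordering.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    if d < 0:
        raise ValueError("d must be >= 0")
    out = params.k * d * (np.exp(-params.ke * t) - np.exp(-params.ka * t))
    return float(out) if out.ndim == 0 else out


def _all_history_sums(rate: float, regimen: DoseRegimen) -> np.ndarray:
    """``S(n)`` for n = 1..N under decay factors ``e^{-rate * tau_s}``."""
    factors = np.exp(-rate * np.asarray(regimen.intervals))
    out = np.empty(regimen.n_doses)
    s = regimen.doses[0]
    out[0] = s
    for i in range(1, regimen.n_doses):
        s = factors[i - 1] * s + regimen.doses[i]
        out[i] = s
    return out


def dose_history_sums(
    params: PKParameters, regimen: DoseRegimen, n: int
) -> DoseHistorySums:
    """``S_alpha(n)`` and ``S_beta(n)`` by forward recursion (O(n) cold)."""
    if not (1 <= n <= regimen.n_doses):
        raise IndexError(f"cycle index {n} outside 1..{regimen.n_doses}")
    s_alpha = _all_history_sums(params.ka, regimen)[n - 1]
    s_beta = _all_history_sums(params.ke, regimen)[n - 1]
    return DoseHistorySums(n=n, s_alpha=float(s_alpha), s_beta=float(s_beta))


def cycle_coefficients(
    params: PKParameters, regimen: DoseRegimen, n: int
) -> CycleCoefficients:
    """``C1(n) = k S_beta(n)``, ``C2(n) = k S_alpha(n)``.

    The three-term form ``C1 = k S_alpha + k (Q_beta - Q_alpha)`` with
    ``Q = S - d_n`` is algebraically identical; the simplification is
    cross-checked in the tests.
    """
    sums = dose_history_sums(params, regimen, n)
    return CycleCoefficients(n=n, c1=params.k * sums.s_beta, c2=params.k * sums.s_alpha)


def _eval_cycles(
    params: PKParameters, regimen: DoseRegimen, t: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized ``(x, y, cycle)`` on sorted-or-not times within the schedule."""
    times = dose_times(regimen)
    if t.size and (np.min(t) < 0 or np.max(t) > times[-1]):
        raise ValueError(f"times outside the dosing schedule [0, {times[-1]}]")
    n_idx = np.searchsorted(times, t, side="right")
    n_idx = np.clip(n_idx, 1, regimen.n_doses)  # t == t_N -> cycle N
    s_alpha = _all_history_sums(params.ka, regimen)[n_idx - 1]
    s_beta = _all_history_sums(params.ke, regimen)[n_idx - 1]
    dt = t - times[n_idx - 1]
    ea = np.exp(-params.ka * dt)
    eb = np.exp(-params.ke * dt)
    x = params.k * (s_beta * eb - s_alpha * ea)
    y = s_alpha * ea
    return x, y, n_idx


def concentration(params: PKParameters, regimen: DoseRegimen, t):
    """Plasma concentration ``x(t)``; continuous, ``x(0) = 0``.

    Within cycle 1 this reduces exactly to the single-dose Bateman curve.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    x, _, _ = _eval_cycles(params, regimen, t_arr)
    return float(x[0]) if np.ndim(t) == 0 else x


def absorbed_amount(params: PKParameters, regimen: DoseRegimen, t):
    """Amount awaiting absorption ``y(t)``; jumps up by ``d_n`` at ``t_{n-1}``.

    Right-continuous at dose instants: ``y(t_{n-1})`` includes dose ``n``.
    ``y(0) = d_1``.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    _, y, _ = _eval_cycles(params, regimen, t_arr)
    return float(y[0]) if np.ndim(t) == 0 else y


def profile(params: PKParameters, regimen: DoseRegimen, grid) -> ConcentrationProfile:
    """Sampled ``(t, x, y, cycle)`` trajectory on a sorted grid."""
    grid = _check_grid(np.asarray(grid, dtype=float), regimen.end_time)
    if grid.size == 0:
        empty = np.empty(0)
        return ConcentrationProfile(
            t=empty, x=empty.copy(), cycle=np.empty(0, dtype=int), y=empty.copy()
        )
    x, y, n_idx = _eval_cycles(params, regimen, grid)
    return ConcentrationProfile(t=grid, x=x, cycle=n_idx.astype(int), y=y)
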