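"""Multi-dose IV bolus: mono-exponential decay with concentration jumps.

Doses are concentration increments ``delta_n`` (mass/volume) — the drug
enters the central compartment directly, so each administration raises
``x`` by ``delta_n`` instantly (unlike oral dosing, where doses are amounts
and ``x`` is continuous).  Within cycle ``n``

    x(t) = S_beta(n) e^{-ke (t - t_{n-1})},
    S_beta(n) = sum_{i=1}^{n-1} delta_i prod_{j=i}^{n-1} beta_j + delta_n,

with ``beta_s = e^{-ke tau_s}``; by linearity this equals the plain
superposition ``sum_{i<=n} delta_i e^{-ke (t - t_{i-1})}``.
"""

from __future__ import annotations

import math

import numpy as np

from .core import DoseRegimen, dose_times
from .profile import ConcentrationProfile, _check_grid

__all__ = ["bolus_concentration", "bolus_profile"]


def _history_sums(ke: float, regimen: DoseRegimen) -> np.ndarray:
    """``S_beta(n)`` for n = 1..N by the forward recursion."""
    betas = np.exp(-ke * np.asarray(regimen.intervals))
    out = np.empty(regimen.n_doses)
    s = regimen.doses[0]
    out[0] = s
    for i in range(1, regimen.n_doses):
        s = betas[i - 1] * s + regimen.doses[i]
        out[i] = s
    return out


def bolus_concentration(ke: float, regimen: DoseRegimen, t):
    """Plasma concentration under repeated bolus dosing.

    Right-continuous at dose instants (the jump ``delta_n`` is included at
    ``t_{n-1}``); log-linear with slope ``-ke`` within each cycle.
    """
    if ke <= 0 or not math.isfinite(ke):
        raise ValueError(f"ke must be finite and > 0, got {ke!r}")
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    times = dose_times(regimen)
    if t_arr.size and (np.min(t_arr) < 0 or np.max(t_arr) > times[-1]):
        raise ValueError(f"times outside the dosing schedule [0, {times[-1]}]")
    n_idx = np.clip(np.searchsorted(times, t_arr, side="right"), 1, regimen.n_doses)
    s_beta = _history_sums(ke, regimen)[n_idx - 1]
    x = s_beta * np.exp(-ke * (t_arr - times[n_idx - 1]))
    return float(x[0]) if np.ndim(t) == 0 else x


def bolus_profile(ke: float, regimen: DoseRegimen, grid) -> ConcentrationProfile:
    """Sampled ``(t, x, cycle)`` trajectory (no absorption state for bolus)."""
    grid = _check_grid(np.asarray(grid, dtype=float), regimen.end_time)
    if grid.size == 0:
        return ConcentrationProfile(t=np.empty(0), x=np.empty(0), cycle=np.empty(0, dtype=int))
    times = dose_times(regimen)
    n_idx = np.clip(np.searchsorted(times, grid, side="right"), 1, regimen.n_doses)
    x = bolus_concentration(ke, regimen, grid)
    return ConcentrationProfile(t=grid, x=x, cycle=n_idx.astype(int))
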