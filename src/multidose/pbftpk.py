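"""Multi-dose dynamics with finite absorption time (F.A.T.).

Each cycle splits into two phases.  During the *assimilation phase*
``[t_{n-1}, s_n]`` absorption and elimination act jointly, exactly as in the
oral model but with the absorbed amount reset to the fresh dose (``y(t_{n-1})
= d_n``; any unabsorbed remainder of earlier doses is gone).  At the cutoff
``s_n`` the absorbable depot is depleted (``y(s_n) = 0``) and the *clearance
phase* ``[s_n, t_n]`` is pure mono-exponential elimination.  The
concentration ``x`` is continuous at both the dose instants and the cutoffs,
with a derivative kink at each ``s_n``.

Ground truth here is the per-cycle recursion, valid for arbitrary schedules:

    assimilation:  x = k d_n (e^{-ke D} - e^{-ka D}) + r_n e^{-ke D},  D = t - t_{n-1}
    clearance:     x = x(s_n) e^{-ke (t - s_n)}
    carryover:     r_{n+1} = x(t_n)                       (r_1 = 0)

For equi-dose schedules (constant ``d, tau, sigma``) an explicit closed form
for the cycle coefficients exists and is provided as a secondary,
cross-checked path (see :func:`pbftpk_equidose_coefficients`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import PBFTPKRegimen, PKParameters, dose_times
from .profile import ConcentrationProfile, _check_grid

__all__ = [
    "PBFTPKCycleCoefficients",
    "pbftpk_state",
    "pbftpk_residuals",
    "pbftpk_equidose_coefficients",
    "pbftpk_profile",
]

ASSIMILATION = "assimilation"
CLEARANCE = "clearance"


@dataclass(frozen=True)
class PBFTPKCycleCoefficients:
    """Cycle-``n`` mode coefficients of the two-phase solution.

    Assimilation: ``x = c1 e^{-ke D} - c2 e^{-ka D}`` (``D`` the offset from
    the dose instant); clearance: ``x = c3 e^{-ke (t - s_n)}``.  ``residual``
    is the concentration ``r_n = x(t_{n-1})`` entering the cycle.
    """

    n: int
    c1: float
    c2: float
    c3: float
    residual: float


def pbftpk_residuals(params: PKParameters, regimen: PBFTPKRegimen) -> np.ndarray:
    """Entering concentrations ``r_n = x(t_{n-1})`` for n = 1..N (r_1 = 0).

    One pass of the per-cycle recursion over the schedule.
    """
    k = params.k
    out = np.empty(regimen.regimen.n_doses)
    r = 0.0
    for i, (d, tau, sigma) in enumerate(
        zip(regimen.regimen.doses, regimen.regimen.intervals, regimen.fat)
    ):
        out[i] = r
        a_s = math.exp(-params.ka * sigma)
        b_s = math.exp(-params.ke * sigma)
        x_cut = k * d * (b_s - a_s) + r * b_s  # x(s_n)
        r = x_cut * math.exp(-params.ke * (tau - sigma))  # x(t_n)
    return out


def pbftpk_state(
    params: PKParameters, regimen: PBFTPKRegimen, t: float
) -> tuple[float, float, str]:
    """``(x, y, phase)`` at time ``t``.

    Phase boundary convention: ``t = s_n`` itself reports the clearance
    phase (``y`` already depleted); a dose instant opens the assimilation
    phase of its cycle.
    """
    base = regimen.regimen
    times = dose_times(base)
    if not (0 <= t <= times[-1]):
        raise ValueError(f"t={t!r} outside the dosing schedule [0, {times[-1]}]")
    n = base.n_doses if t == times[-1] else int(np.searchsorted(times, t, side="right"))
    t_start = times[n - 1]
    sigma = regimen.fat[n - 1]
    s_n = t_start + sigma
    d = base.doses[n - 1]
    r = float(pbftpk_residuals(params, regimen)[n - 1])
    k = params.k
    if t < s_n:
        delta = t - t_start
        y = d * math.exp(-params.ka * delta)
        x = k * d * (math.exp(-params.ke * delta) - math.exp(-params.ka * delta)) + r * math.exp(-params.ke * delta)
        return x, y, ASSIMILATION
    x_cut = k * d * (math.exp(-params.ke * sigma) - math.exp(-params.ka * sigma)) + r * math.exp(-params.ke * sigma)
    x = x_cut * math.exp(-params.ke * (t - s_n))
    return x, 0.0, CLEARANCE


def pbftpk_equidose_coefficients(
    params: PKParameters, d: float, tau: float, sigma: float, n: int
) -> PBFTPKCycleCoefficients:
    """Equi-dose closed-form coefficients for cycle ``n``.

    With ``A = e^{-ka sigma}``, ``B = e^{-ke sigma}``, ``beta = e^{-ke tau}``:

        C2(n) = k d
        C3(n) = k (B - A) sum_{i=1}^{n} beta^{n-i} d   = k d (B - A) (1 - beta^n)/(1 - beta)
        C1(n) = k d + (beta/B) C3(n-1)

    so that the carryover identity ``C1(n) - C2(n) = (beta/B) C3(n-1) = r_n``
    holds (``C3(0) = 0``).  The history sum in ``C3`` runs to ``i = n``: the
    variant stopping at ``i = n-1`` would make the clearance concentration
    after the first dose identically zero, contradicting continuity at the
    cutoff (see docs/methods.md for discussion of this index).
    """
    if not (0 < sigma < tau):
        raise ValueError(
            f"the equi-dose closed form needs 0 < sigma < tau, got sigma={sigma!r}, "
            f"tau={tau!r} (the recursion path handles sigma = tau)"
        )
    if n < 1:
        raise IndexError(f"cycle index must be >= 1, got {n}")
    k = params.k
    A = math.exp(-params.ka * sigma)
    B = math.exp(-params.ke * sigma)
    beta = math.exp(-params.ke * tau)

    def c3_of(m: int) -> float:
        if m < 1:
            return 0.0
        return k * (B - A) * d * (1 - beta**m) / (1 - beta)

    c2 = k * d
    c3 = c3_of(n)
    c1 = k * d + (beta / B) * c3_of(n - 1)
    residual = c1 - c2
    return PBFTPKCycleCoefficients(n=n, c1=c1, c2=c2, c3=c3, residual=residual)


def pbftpk_profile(
    params: PKParameters, regimen: PBFTPKRegimen, grid
) -> ConcentrationProfile:
    """Sampled ``(t, x, y, cycle, phase)`` trajectory on a sorted grid."""
    base = regimen.regimen
    grid = _check_grid(np.asarray(grid, dtype=float), base.end_time)
    if grid.size == 0:
        empty = np.empty(0)
        return ConcentrationProfile(
            t=empty, x=empty.copy(), cycle=np.empty(0, dtype=int),
            y=empty.copy(), phase=np.empty(0, dtype=object),
        )
    times = dose_times(base)
    residuals = pbftpk_residuals(params, regimen)
    n_idx = np.clip(np.searchsorted(times, grid, side="right"), 1, base.n_doses)
    t_start = times[n_idx - 1]
    sigma = np.asarray(regimen.fat)[n_idx - 1]
    d = np.asarray(base.doses)[n_idx - 1]
    r = residuals[n_idx - 1]
    k = params.k
    delta = grid - t_start
    assim = delta < sigma
    x = np.empty_like(grid)
    y = np.zeros_like(grid)
    # assimilation phase
    da = delta[assim]
    x[assim] = (
        k * d[assim] * (np.exp(-params.ke * da) - np.exp(-params.ka * da))
        + r[assim] * np.exp(-params.ke * da)
    )
    y[assim] = d[assim] * np.exp(-params.ka * da)
    # clearance phase
    cl = ~assim
    sg = sigma[cl]
    x_cut = (
        k * d[cl] * (np.exp(-params.ke * sg) - np.exp(-params.ka * sg))
        + r[cl] * np.exp(-params.ke * sg)
    )
    x[cl] = x_cut * np.exp(-params.ke * (delta[cl] - sg))
    phase = np.where(assim, ASSIMILATION, CLEARANCE).astype(object)
    return ConcentrationProfile(
        t=grid, x=x, cycle=n_idx.astype(int), y=y, phase=phase
    )
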