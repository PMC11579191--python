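"""Equi-dose regimen design: hit a prescribed steady-state envelope.

Both asymptotic bounds are linear in the dose ``d``, so the two-equation
design problem

    ss_lower(d, tau) = ss_lower*,   ss_upper(d, tau) = ss_upper*

splits into a scalar problem: the ratio ``ss_upper/ss_lower`` depends on
``tau`` alone, is > 1 everywhere, tends to 1 as ``tau -> 0`` and grows
without bound as ``tau -> inf``, so a bracketed root-find in ``tau`` matches
the target ratio and ``d`` then scales linearly.  Existence of a feasible
regimen for any window ``0 < MIC < TC`` follows from the same limits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .core import PKParameters
from .metrics import steady_state_bounds

__all__ = [
    "DesignTarget",
    "InfeasibleTargetError",
    "steady_state_ratio",
    "design_regimen",
    "is_effective",
]


class InfeasibleTargetError(ValueError):
    """The requested steady-state window cannot be realized."""


@dataclass(frozen=True)
class DesignTarget:
    """A therapeutic window and (optionally) exact envelope targets.

    ``mic`` is the efficacy floor (minimum inhibitory concentration) and
    ``tc`` the safety ceiling (toxic concentration).  When the exact targets
    are omitted they default to the widest admissible envelope
    ``(mic, tc)``.
    """

    mic: float
    tc: float
    ss_lower: float | None = None
    ss_upper: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.mic < self.tc):
            raise ValueError(f"need tc > mic > 0, got mic={self.mic!r}, tc={self.tc!r}")
        if (self.ss_lower is None) != (self.ss_upper is None):
            raise ValueError("give both exact targets or neither")
        if self.ss_lower is not None:
            if not (self.mic <= self.ss_lower < self.ss_upper <= self.tc):
                raise InfeasibleTargetError(
                    "exact targets must satisfy mic <= ss_lower < ss_upper <= tc"
                )

    @property
    def exact(self) -> tuple[float, float]:
        if self.ss_lower is None:
            return self.mic, self.tc
        return self.ss_lower, self.ss_upper


def steady_state_ratio(params: PKParameters, tau: float) -> float:
    """``ss_upper / ss_lower`` at interval ``tau`` — independent of the dose."""
    lower, upper = steady_state_bounds(params, 1.0, tau)
    return upper / lower


_TAU_BRACKET = (1e-6, 1e6)


def design_regimen(params: PKParameters, target: DesignTarget) -> tuple[float, float]:
    """Find ``(d*, tau*)`` whose asymptotic envelope equals the exact targets.

    Bracketed root-finding on the dose-free ratio in ``tau`` (the bracket is
    expanded geometrically and its monotone behavior verified), then linear
    scaling in ``d``.  Raises :class:`InfeasibleTargetError` when the target
    ratio is <= 1 and a convergence error when no bracket is found within
    ``tau`` in [1e-6, 1e6].
    """
    lo_target, hi_target = target.exact
    ratio_target = hi_target / lo_target
    if ratio_target <= 1:
        raise InfeasibleTargetError(
            f"target ratio {ratio_target} <= 1: the upper bound always "
            "strictly exceeds the lower bound"
        )

    def f(log_tau: float) -> float:
        return steady_state_ratio(params, math.exp(log_tau)) - ratio_target

    # expand a bracket geometrically from tau = 1
    lo, hi = 0.0, 0.0
    f0 = f(0.0)
    if f0 == 0.0:
        tau_star = 1.0
    else:
        step = 1.0
        if f0 > 0:
            while f(lo) > 0:
                lo -= step
                step *= 2
                if math.exp(lo) < _TAU_BRACKET[0]:
                    raise RuntimeError(
                        f"no bracket for target ratio {ratio_target} down to "
                        f"tau = {_TAU_BRACKET[0]}"
                    )
            hi = lo + step / 2
        else:
            while f(hi) < 0:
                hi += step
                step *= 2
                if math.exp(hi) > _TAU_BRACKET[1]:
                    raise RuntimeError(
                        f"no bracket for target ratio {ratio_target} up to "
                        f"tau = {_TAU_BRACKET[1]}"
                    )
            lo = hi - step / 2
        # the bracketing assumes the ratio increases with tau; verify on the
        # bracket rather than trusting it
        scan = np.exp(np.linspace(lo, hi, 17))
        vals = [steady_state_ratio(params, t) for t in scan]
        if np.any(np.diff(vals) <= 0):
            raise RuntimeError(
                "steady-state ratio is not monotone on the search bracket "
                f"[{math.exp(lo):g}, {math.exp(hi):g}]; refusing to root-find"
            )
        tau_star = math.exp(brentq(f, lo, hi, xtol=1e-15, rtol=1e-15))
    unit_lower, _ = steady_state_bounds(params, 1.0, tau_star)
    d_star = lo_target / unit_lower
    return d_star, tau_star


def is_effective(
    params: PKParameters, d: float, tau: float, target: DesignTarget
) -> bool:
    """Does the schedule's asymptotic envelope sit inside ``[mic, tc]``?

    Membership in the effective set is a closed condition, so it is
    evaluated with a 1e-9 relative slack: a designed schedule sitting
    exactly on the window boundary is a member despite rounding.
    """
    lower, upper = steady_state_bounds(params, d, tau)
    return target.mic * (1 - 1e-9) <= lower and upper <= target.tc * (1 + 1e-9)
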