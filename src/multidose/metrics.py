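"""Per-cycle and asymptotic PK metrics for equi-dose oral regimens.

All quantities below are closed forms in ``alpha = e^{-ka tau}``,
``beta = e^{-ke tau}`` and the prefactor ``k = ka*gamma/(ka-ke)``:

* per-cycle AUC, peak time and peak concentration;
* the cycle *remainder* ``x(n tau)`` (trough at the end of cycle n);
* the asymptotic envelope of the limit cycle — the lower bound is the
  limiting remainder, the upper bound the limiting per-cycle maximum;
* the periodicity gap ``sup_{t in I_n} |x^(n)(t) - x^(n-1)(t - tau)|``
  whose decay certifies convergence to the steady state.

The asymptotic envelope ``[ss_lower, ss_upper]`` is the model's
"therapeutic range": the set of concentrations the limit cycle visits.
This is a property of the dosing schedule, distinct from the clinical
MIC/toxic-concentration window prescribed externally (see the design
module for matching one to the other).

Metrics are defined for the equi-dose case; per-cycle AUC of arbitrary
regimens is available through numerical quadrature in the oracle module.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import PKParameters

__all__ = [
    "CycleMetrics",
    "SteadyStateSummary",
    "auc_cycle",
    "auc_single_infinite",
    "t_max_cycle",
    "x_max_cycle",
    "remainder",
    "steady_state_bounds",
    "therapeutic_width",
    "therapeutic_width_limit",
    "periodicity_gap",
    "n_epsilon",
    "cycle_metrics",
    "steady_state_summary",
]


def _alpha_beta(params: PKParameters, tau: float) -> tuple[float, float]:
    if tau <= 0:
        raise ValueError(f"tau must be > 0, got {tau!r}")
    return math.exp(-params.ka * tau), math.exp(-params.ke * tau)


def _equi_c1_c2(params: PKParameters, d: float, tau: float, n: int) -> tuple[float, float]:
    """Equi-dose cycle coefficients ``C1(n), C2(n)`` (geometric closure)."""
    alpha, beta = _alpha_beta(params, tau)
    c1 = params.k * d * (1 - beta**n) / (1 - beta)
    c2 = params.k * d * (1 - alpha**n) / (1 - alpha)
    return c1, c2


@dataclass(frozen=True)
class CycleMetrics:
    """The standard per-cycle PK quantities for one equi-dose cycle."""

    n: int
    auc: float
    t_max: float
    x_max: float
    remainder: float


@dataclass(frozen=True)
class SteadyStateSummary:
    """Asymptotic description of an equi-dose schedule.

    ``[ss_lower, ss_upper]`` is the envelope of the limit cycle, ``width``
    its breadth, ``auc_ss`` the limiting per-cycle AUC (equal to the
    single-dose AUC over [0, inf)), ``n_eps`` the first cycle from which
    all successive-cycle sup-gaps stay below ``eps``, and ``gaps`` the
    computed gap sequence up to that index.  ``degenerate`` flags an
    all-zero schedule (d = 0), for which the envelope collapses to {0}.
    """

    ss_lower: float
    ss_upper: float
    width: float
    auc_ss: float
    eps: float
    n_eps: int
    gaps: tuple[float, ...] = field(repr=False)
    degenerate: bool = False


def auc_cycle(params: PKParameters, d: float, tau: float, n: int) -> float:
    """Area under ``x`` over cycle ``I_n``: ``k d [(1-beta^n)/ke - (1-alpha^n)/ka]``."""
    if n < 1:
        raise IndexError(f"cycle index must be >= 1, got {n}")
    if d < 0:
        raise ValueError("d must be >= 0")
    alpha, beta = _alpha_beta(params, tau)
    return params.k * d * ((1 - beta**n) / params.ke - (1 - alpha**n) / params.ka)


def auc_single_infinite(params: PKParameters, d: float) -> float:
    """Single-dose AUC over [0, inf): ``k d (1/ke - 1/ka)``.

    Algebraically ``gamma d / ke`` — free of the absorption constant.
    """
    if d < 0:
        raise ValueError("d must be >= 0")
    return params.k * d * (1 / params.ke - 1 / params.ka)


def t_max_cycle(params: PKParameters, d: float, tau: float, n: int) -> float:
    """Absolute time of the cycle-``n`` peak.

    The stationary point of the two-exponential lies at local offset
    ``ln(ka C2 / (ke C1)) / (ka - ke)``.  For extreme parameters that
    offset can leave ``[0, tau]``; the returned time is then the actual
    in-cycle argmax (a boundary) and a warning is emitted.
    """
    if n < 1:
        raise IndexError(f"cycle index must be >= 1, got {n}")
    if d <= 0:
        raise ValueError("peak time is undefined for d <= 0")
    c1, c2 = _equi_c1_c2(params, d, tau, n)
    offset = math.log(params.ka * c2 / (params.ke * c1)) / (params.ka - params.ke)
    if not (0 <= offset <= tau):
        warnings.warn(
            f"cycle {n}: stationary point at offset {offset:.6g} lies outside "
            f"[0, {tau}]; returning the boundary argmax",
            RuntimeWarning,
            stacklevel=2,
        )
        ends = [0.0, tau]
        vals = [
            c1 * math.exp(-params.ke * s) - c2 * math.exp(-params.ka * s)
            for s in ends
        ]
        offset = ends[int(np.argmax(vals))]
    return (n - 1) * tau + offset


def x_max_cycle(params: PKParameters, d: float, tau: float, n: int) -> float:
    """Peak concentration in cycle ``n`` (power form of the stationary value).

    ``C1 r^{-ke/(ka-ke)} - C2 r^{-ka/(ka-ke)}`` with ``r = ka C2/(ke C1)``;
    falls back to evaluating at the clipped boundary argmax when the
    stationary point leaves the cycle.
    """
    if d == 0:
        return 0.0
    c1, c2 = _equi_c1_c2(params, d, tau, n)
    r = params.ka * c2 / (params.ke * c1)
    offset = math.log(r) / (params.ka - params.ke)
    if 0 <= offset <= tau:
        q = params.ke / (params.ka - params.ke)
        return c1 * r**(-q) - c2 * r**(-q - 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t = t_max_cycle(params, d, tau, n)
    s = t - (n - 1) * tau
    return c1 * math.exp(-params.ke * s) - c2 * math.exp(-params.ka * s)


def remainder(params: PKParameters, d: float, tau: float, n: int) -> float:
    """End-of-cycle trough ``x(n tau)``.

    ``k d [beta (1-beta^n)/(1-beta) - alpha (1-alpha^n)/(1-alpha)]``;
    strictly positive for d > 0 under either kinetic ordering.
    """
    if n < 1:
        raise IndexError(f"cycle index must be >= 1, got {n}")
    alpha, beta = _alpha_beta(params, tau)
    return params.k * d * (
        beta * (1 - beta**n) / (1 - beta) - alpha * (1 - alpha**n) / (1 - alpha)
    )


def steady_state_bounds(params: PKParameters, d: float, tau: float) -> tuple[float, float]:
    """Asymptotic envelope ``(ss_lower, ss_upper)`` of the limit cycle.

    ``ss_lower = k d [beta/(1-beta) - alpha/(1-alpha)]`` (limiting trough);
    ``ss_upper`` is the limiting per-cycle maximum, the power form evaluated
    at the limiting coefficients ``C1 -> k d/(1-beta)``, ``C2 -> k d/(1-alpha)``.
    Both are linear in ``d``.
    """
    alpha, beta = _alpha_beta(params, tau)
    kd = params.k * d
    lower = kd * (beta / (1 - beta) - alpha / (1 - alpha))
    r = params.ka * (1 - beta) / (params.ke * (1 - alpha))
    q = params.ke / (params.ka - params.ke)
    upper = kd * (r**(-q) / (1 - beta) - r**(-q - 1) / (1 - alpha))
    return lower, upper


def therapeutic_width(params: PKParameters, d: float, tau: float) -> float:
    """Width ``ss_upper - ss_lower`` of the asymptotic envelope; > 0 for d > 0."""
    lower, upper = steady_state_bounds(params, d, tau)
    return upper - lower


def therapeutic_width_limit(params: PKParameters, d: float) -> float:
    """Limit of the envelope width as ``tau -> inf`` (single-dose Cmax).

    ``k d [(ka/ke)^{-ke/(ka-ke)} - (ka/ke)^{-ka/(ka-ke)}]``.
    """
    r = params.ka / params.ke
    q = params.ke / (params.ka - params.ke)
    return params.k * d * (r**(-q) - r**(-q - 1))


def _gap_deltas(params: PKParameters, d: float, tau: float, n: int) -> tuple[float, float]:
    """Coefficient increments ``dC1 = k d beta^{n-1}``, ``dC2 = k d alpha^{n-1}``."""
    alpha, beta = _alpha_beta(params, tau)
    return params.k * d * beta ** (n - 1), params.k * d * alpha ** (n - 1)


def periodicity_gap(params: PKParameters, d: float, tau: float, n: int) -> float:
    """Sup-norm distance between cycle ``n`` and the shifted cycle ``n-1``.

    ``sup_{s in [0, tau]} |dC1 e^{-ke s} - dC2 e^{-ka s}|`` with
    ``dCi = Ci(n) - Ci(n-1)``; the sup is the max over the two endpoints and
    the unique interior critical point of the two-exponential difference
    (when it falls inside the cycle).  Decays geometrically with ratio
    ``max(alpha, beta)``.
    """
    if n < 2:
        raise IndexError(f"the periodicity gap needs n >= 2, got {n}")
    dc1, dc2 = _gap_deltas(params, d, tau, n)
    if d == 0:
        return 0.0

    def g(s: float) -> float:
        return abs(dc1 * math.exp(-params.ke * s) - dc2 * math.exp(-params.ka * s))

    candidates = [0.0, tau]
    ratio = params.ka * dc2 / (params.ke * dc1)
    if ratio > 0:
        s_star = math.log(ratio) / (params.ka - params.ke)
        if 0 < s_star < tau:
            candidates.append(s_star)
    return max(g(s) for s in candidates)


def n_epsilon(params: PKParameters, d: float, tau: float, eps: float) -> int:
    """First cycle index from which all successive-cycle gaps stay below ``eps``.

    The tail condition "gap(m) < eps for all m >= n" is certified without
    infinite scanning through the geometric envelope
    ``gap(m) <= (|dC1(n)| + |dC2(n)|) max(alpha, beta)^{m-n}``.
    """
    if eps <= 0:
        raise ValueError("eps must be > 0")
    if d == 0:
        return 2
    alpha, beta = _alpha_beta(params, tau)
    decay = max(alpha, beta)
    n = 2
    while True:
        dc1, dc2 = _gap_deltas(params, d, tau, n)
        if periodicity_gap(params, d, tau, n) < eps and (dc1 + dc2) * decay < eps:
            return n
        n += 1
        if n > 10_000_000:  # unreachable for eps > 0: the envelope is geometric
            raise RuntimeError("gap sequence failed to fall below eps")


def cycle_metrics(params: PKParameters, d: float, tau: float, n: int) -> CycleMetrics:
    """Bundle the per-cycle quantities for cycle ``n``."""
    return CycleMetrics(
        n=n,
        auc=auc_cycle(params, d, tau, n),
        t_max=t_max_cycle(params, d, tau, n),
        x_max=x_max_cycle(params, d, tau, n),
        remainder=remainder(params, d, tau, n),
    )


def steady_state_summary(
    params: PKParameters, d: float, tau: float, eps: float = 1e-6
) -> SteadyStateSummary:
    """Full asymptotic summary of an equi-dose schedule.

    The limiting per-cycle AUC equals the single-dose AUC over [0, inf)
    exactly (equal-areas identity); both code paths are evaluated and
    cross-checked here at 1e-12 relative.
    """
    if d == 0:
        return SteadyStateSummary(
            ss_lower=0.0, ss_upper=0.0, width=0.0, auc_ss=0.0,
            eps=eps, n_eps=2, gaps=(), degenerate=True,
        )
    lower, upper = steady_state_bounds(params, d, tau)
    # limiting per-cycle AUC: alpha^n, beta^n -> 0 in the cycle-AUC formula
    auc_ss = params.k * d * (1 / params.ke - 1 / params.ka)
    auc_inf = auc_single_infinite(params, d)
    assert abs(auc_ss - auc_inf) <= 1e-12 * abs(auc_inf), (
        "equal-areas identity violated"
    )
    n_eps = n_epsilon(params, d, tau, eps)
    gaps = tuple(periodicity_gap(params, d, tau, m) for m in range(2, n_eps + 1))
    return SteadyStateSummary(
        ss_lower=lower, ss_upper=upper, width=upper - lower, auc_ss=auc_ss,
        eps=eps, n_eps=n_eps, gaps=gaps,
    )
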