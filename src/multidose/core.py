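"""Parameter and regimen data model; cycle bookkeeping on the dosing time scale.

A multi-dose schedule is the sequence ``{(tau_n, d_n)}``: dose ``d_n`` is
administered at time ``t_{n-1} = tau_1 + ... + tau_{n-1}`` (first dose at
``t_0 = 0``) and cycle ``I_n = [t_{n-1}, t_n)`` is the interval until the next
dose.  Conceptually the schedule is infinite; here it is truncated at a finite
number of doses ``N`` and every evaluation beyond ``t_N`` is a domain error
rather than an extrapolation.

Units are documented, not enforced: the library is unit-agnostic, but the
worked examples use hours, mg and mL^-1 (so that concentration = gamma x
amount is mg/mL).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PKParameters",
    "DoseRegimen",
    "PBFTPKRegimen",
    "make_equidose",
    "dose_times",
    "cycle_of",
]

#: Relative tolerance below which ka and ke are considered equal (rejected).
KA_KE_REL_TOL = 1e-9


@dataclass(frozen=True)
class PKParameters:
    """One-compartment first-order absorption/elimination constants.

    Parameters
    ----------
    ka : float
        Absorption rate constant (1/time).
    ke : float
        Elimination rate constant (1/time).
    gamma : float
        Lumped bioavailability/volume constant (1/volume), so that
        concentration = gamma x amount.  For the oral route
        ``gamma = F / V`` with ``F`` the absolute bioavailability and
        ``V`` the volume of distribution.
    F, V : float, optional
        Provenance fields when ``gamma`` was built from bioavailability
        and distribution volume.

    Notes
    -----
    ``ka == ke`` (within a relative tolerance of 1e-9) is rejected: the
    double-exponential closed forms all divide by ``ka - ke`` and the
    confluent case is uncommon in practice.  Flip-flop kinetics
    (``ka < ke``, absorption slower than elimination) are permitted.
    """

    ka: float
    ke: float
    gamma: float = 1.0
    F: float | None = None
    V: float | None = None

    def __post_init__(self) -> None:
        for name in ("ka", "ke", "gamma"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")
        rel_gap = abs(self.ka - self.ke) / max(self.ka, self.ke)
        if rel_gap <= KA_KE_REL_TOL:
            raise ValueError(
                "ka and ke must differ (|ka-ke|/max > 1e-9): the closed-form "
                "solutions divide by ka - ke and the equal-rate case is "
                "outside the scope of this model"
            )

    @classmethod
    def from_bioavailability(cls, ka: float, ke: float, F: float, V: float) -> "PKParameters":
        """Construct with the oral-route identification ``gamma = F / V``."""
        if not (0 < F <= 1):
            raise ValueError(f"F must be in (0, 1], got {F!r}")
        if V <= 0:
            raise ValueError(f"V must be > 0, got {V!r}")
        return cls(ka=ka, ke=ke, gamma=F / V, F=F, V=V)

    @property
    def k(self) -> float:
        """The shared prefactor ``ka * gamma / (ka - ke)`` (1/volume)."""
        return self.ka * self.gamma / (self.ka - self.ke)

    @property
    def flip_flop(self) -> bool:
        """True when absorption is slower than elimination (ka < ke)."""
        return self.ka < self.ke


@dataclass(frozen=True)
class DoseRegimen:
    """A finite truncation of a dosing schedule ``{(tau_n, d_n)}``.

    ``intervals[n-1]`` is the duration ``tau_n`` of cycle ``n`` and
    ``doses[n-1]`` the amount ``d_n`` given at its start.  For IV bolus
    dosing the same container carries doses expressed as concentration
    increments (mass/volume) instead of amounts.
    """

    intervals: tuple[float, ...]
    doses: tuple[float, ...]
    _times: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "intervals", tuple(float(t) for t in self.intervals))
        object.__setattr__(self, "doses", tuple(float(d) for d in self.doses))
        if len(self.intervals) != len(self.doses):
            raise ValueError(
                f"{len(self.intervals)} intervals vs {len(self.doses)} doses"
            )
        if len(self.intervals) < 1:
            raise ValueError("a regimen needs at least one dose")
        if any(not math.isfinite(t) or t <= 0 for t in self.intervals):
            raise ValueError("all intervals must be finite and > 0")
        if any(not math.isfinite(d) or d < 0 for d in self.doses):
            raise ValueError("all doses must be finite and >= 0")
        times = np.concatenate([[0.0], np.cumsum(self.intervals)])
        object.__setattr__(self, "_times", times)

    @property
    def n_doses(self) -> int:
        return len(self.doses)

    @property
    def end_time(self) -> float:
        """The end ``t_N`` of the truncated schedule."""
        return float(self._times[-1])

    @property
    def is_equidose(self) -> bool:
        """Constant dose at constant interval?"""
        return (
            len(set(self.intervals)) == 1 and len(set(self.doses)) == 1
        )

    def with_washout(self, duration: float) -> "DoseRegimen":
        """Append a zero-dose pseudo-cycle to observe washout past ``t_N``."""
        return DoseRegimen(self.intervals + (float(duration),), self.doses + (0.0,))


def make_equidose(d: float, tau: float, n_doses: int) -> DoseRegimen:
    """Equi-dose regimen: dose ``d`` every ``tau`` time units, ``n_doses`` times.

    Dose ``n`` lands at ``t_{n-1} = (n-1) * tau``.
    """
    if n_doses < 1:
        raise ValueError(f"n_doses must be >= 1, got {n_doses}")
    if tau <= 0:
        raise ValueError(f"tau must be > 0, got {tau!r}")
    if d < 0:
        raise ValueError(f"d must be >= 0, got {d!r}")
    return DoseRegimen((float(tau),) * n_doses, (float(d),) * n_doses)


@dataclass(frozen=True)
class PBFTPKRegimen:
    """Dosing schedule with per-cycle finite absorption times.

    ``fat[n-1]`` is the absorption duration ``sigma_n`` of cycle ``n``:
    absorption acts on the assimilation phase ``[t_{n-1}, s_n]`` with
    ``s_n = t_{n-1} + sigma_n``, and only elimination on the clearance
    phase ``[s_n, t_n]``.  ``sigma_n = tau_n`` (absorption for the whole
    cycle, empty clearance phase) is legal.
    """

    regimen: DoseRegimen
    fat: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "fat", tuple(float(s) for s in self.fat))
        if len(self.fat) != self.regimen.n_doses:
            raise ValueError(
                f"{len(self.fat)} absorption times for {self.regimen.n_doses} doses"
            )
        for n, (sigma, tau) in enumerate(zip(self.fat, self.regimen.intervals), start=1):
            if not (0 < sigma <= tau):
                raise ValueError(
                    f"cycle {n}: absorption duration sigma={sigma!r} must satisfy "
                    f"0 < sigma <= tau={tau!r}"
                )

    @classmethod
    def equidose(cls, d: float, tau: float, sigma: float, n_doses: int) -> "PBFTPKRegimen":
        return cls(make_equidose(d, tau, n_doses), (float(sigma),) * n_doses)

    @property
    def absorption_times(self) -> np.ndarray:
        """Absolute phase-switch times ``s_n = t_{n-1} + sigma_n``."""
        return dose_times(self.regimen)[:-1] + np.asarray(self.fat)


def dose_times(regimen: DoseRegimen) -> np.ndarray:
    """Cycle boundaries ``(t_0, ..., t_N)`` with ``t_0 = 0``; strictly increasing."""
    return regimen._times.copy()


def cycle_of(regimen: DoseRegimen, t: float) -> tuple[int, float]:
    """Locate ``t`` on the schedule: ``(cycle index n, offset t - t_{n-1})``.

    Cycles are half-open ``[t_{n-1}, t_n)`` so a dose instant opens the new
    cycle (right-continuity of the absorption state).  The schedule end
    ``t = t_N`` maps to cycle ``N`` with offset ``tau_N``.  Binary search,
    O(log N).
    """
    times = regimen._times
    if not (0 <= t <= times[-1]):
        raise ValueError(
            f"t={t!r} outside the dosing schedule [0, {times[-1]!r}]"
        )
    if t == times[-1]:
        n = regimen.n_doses
    else:
        n = int(np.searchsorted(times, t, side="right"))
    return n, float(t - times[n - 1])
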