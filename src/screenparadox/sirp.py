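"""SIR epidemic dynamics coupled to screening-test performance ("SIR-P").

A Kermack–McKendrick SIR model without vital dynamics, in population
fractions s + i + r = 1:

    ds/dt = -beta * i * s
    di/dt =  beta * i * s - gamma * i
    dr/dt =  gamma * i

with average infection rate ``beta`` and recovery rate ``gamma`` (per week),
basic reproduction number R0 = beta/gamma.  The infected fraction i(t) is
read as the disease prevalence at time t, and each weekly record is coupled
to the screening test's PPV, the retention ratio zeta against a reference
prevalence phi0, and the number of positive test iterations (PTI) needed to
reach the threshold-level PPV.  The same coupling can be driven by an
externally supplied prevalence series instead of a simulation, which allows
a published weekly prevalence column to be re-analysed without knowing the
beta/gamma that produced it.

Integration is fixed-step classical 4th-order Runge–Kutta (default step
0.01 week) with output sampled at integer weeks: the system is smooth and
two-dimensional, and a fixed step makes runs bit-reproducible.  The exact
invariant S(t) = S(0) * exp(-R0 * (R(t) - R(0))) of the flow serves as an
independent accuracy oracle in the test suite.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .bayes_core import (
    TestCharacteristics,
    ppv,
    prevalence_threshold,
)
from .errors import (
    IntegrationError,
    ScreeningDomainError,
    UndefinedRatioError,
)
from .serial_testing import iterations_to_threshold

__all__ = [
    "SIRParams",
    "SIRState",
    "Phi0Policy",
    "SIRPTrajectory",
    "simulate_sir",
    "basic_reproduction_number",
    "couple_ppv",
    "build_table",
]


@dataclass(frozen=True)
class SIRParams:
    """Rate constants, initial state and time grid of an SIR run.

    ``beta`` and ``gamma`` are per week; ``s0``, ``i0``, ``r0_init`` are
    initial population fractions and must sum to 1.  ``t_end`` is the number
    of weekly records produced (week 1 is the initial state), ``dt`` the
    integrator step in weeks.  ``population`` is the absolute community size
    N; the dynamics are computed in fractions, so it only scales counts.

    The defaults describe a fast community outbreak (R0 ~ 5.8) whose
    prevalence sweeps from 0.01% up through ~52% at week 14 and back down —
    both crossings of a high-grade test's prevalence threshold occur inside
    the window, which is the regime where the screening paradox bites.
    """

    beta: float = 0.93
    gamma: float = 0.16
    population: float = 1.0
    s0: float = 0.9999
    i0: float = 0.0001
    r0_init: float = 0.0
    t_end: float = 34.0
    dt: float = 0.01

    def __post_init__(self) -> None:
        if self.beta <= 0 or self.gamma <= 0:
            raise ScreeningDomainError(
                f"beta and gamma must be positive, got beta={self.beta!r}, "
                f"gamma={self.gamma!r}"
            )
        if self.population <= 0:
            raise ScreeningDomainError(
                f"population must be positive, got {self.population!r}"
            )
        if self.dt <= 0 or self.t_end <= 0:
            raise ScreeningDomainError(
                f"dt and t_end must be positive, got dt={self.dt!r}, "
                f"t_end={self.t_end!r}"
            )
        total = self.s0 + self.i0 + self.r0_init
        if abs(total - 1.0) > 1e-12:
            raise ScreeningDomainError(
                f"initial fractions must sum to 1 (got {total!r})"
            )
        if min(self.s0, self.i0, self.r0_init) < 0:
            raise ScreeningDomainError("initial fractions must be non-negative")


@dataclass(frozen=True)
class SIRState:
    """Population state at time ``t`` (weeks), as fractions of N."""

    t: float
    s: float
    i: float
    r: float


class Phi0Policy(enum.Enum):
    """How the zeta reference prevalence phi0 is chosen for a trajectory.

    PEAK uses the maximum infected fraction (natural for a full epidemic
    wave: every later week is then a falling-prevalence comparison), FIRST
    uses the first record, EXPLICIT a caller-supplied value.
    """

    PEAK = "peak"
    FIRST = "first"
    EXPLICIT = "value"


@dataclass
class SIRPTrajectory:
    """Weekly SIR records annotated with PPV, zeta and PTI.

    ``frame`` columns: week, t, susceptible, infected, recovered, ppv, zeta,
    pti.  ``infected`` doubles as the prevalence; ``zeta`` is the ratio of
    each week's PPV to the PPV at the reference prevalence ``phi0_reference``
    (exactly 1 at the reference record); ``pti`` is the integer number of
    serial positives needed to reach the threshold-level PPV.
    ``threshold_crossings`` lists (t, direction) pairs at which the
    prevalence passes ``phi_e`` between consecutive records, direction
    "up" or "down".
    """

    frame: pd.DataFrame
    phi_e: float
    phi0_reference: float
    test: TestCharacteristics
    threshold_crossings: list[tuple[float, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.frame)

    def display_frame(self, precision: int = 4) -> pd.DataFrame:
        """Rounded copy for human-facing output (PTI stays integer)."""
        out = self.frame.copy()
        for col in ("susceptible", "infected", "recovered", "ppv", "zeta"):
            out[col] = out[col].round(precision)
        return out


def _rk4_step(s, i, beta, gamma, dt):
    def deriv(s_, i_):
        force = beta * i_ * s_
        return -force, force - gamma * i_

    k1s, k1i = deriv(s, i)
    k2s, k2i = deriv(s + 0.5 * dt * k1s, i + 0.5 * dt * k1i)
    k3s, k3i = deriv(s + 0.5 * dt * k2s, i + 0.5 * dt * k2i)
    k4s, k4i = deriv(s + dt * k3s, i + dt * k3i)
    return (
        s + dt / 6.0 * (k1s + 2 * k2s + 2 * k3s + k4s),
        i + dt / 6.0 * (k1i + 2 * k2i + 2 * k3i + k4i),
    )


def simulate_sir(params: SIRParams) -> list[SIRState]:
    """Integrate the SIR system; return states sampled at integer weeks.

    Only (s, i) are integrated; r is recovered from the conservation law
    r = 1 - s - i, which keeps the invariant exact to rounding.  Records run
    t = 0, 1, ..., floor(t_end) - 1 (the first record is the initial state,
    matching a week-1-starts-the-series convention).
    """
    n_weeks = int(math.floor(params.t_end))
    steps_per_week = int(round(1.0 / params.dt))
    if abs(steps_per_week * params.dt - 1.0) > 1e-9:
        raise ScreeningDomainError(
            f"dt must divide 1 week evenly, got dt={params.dt!r}"
        )
    s, i = params.s0, params.i0
    states = [SIRState(t=0.0, s=s, i=i, r=1.0 - s - i)]
    for week in range(1, n_weeks):
        for _ in range(steps_per_week):
            s, i = _rk4_step(s, i, params.beta, params.gamma, params.dt)
            if not (math.isfinite(s) and math.isfinite(i)):
                raise IntegrationError(
                    f"non-finite state near t={week} (s={s!r}, i={i!r}); "
                    "reduce dt or check the rate constants"
                )
        states.append(SIRState(t=float(week), s=s, i=i, r=1.0 - s - i))
    return states


def basic_reproduction_number(params: SIRParams) -> float:
    """R0 = beta / gamma, the infection-to-recovery rate ratio."""
    if params.gamma == 0:
        raise ZeroDivisionError("gamma must be nonzero for R0")
    return params.beta / params.gamma


def _resolve_phi0(
    prevalence: np.ndarray, policy: Phi0Policy, phi0_value: float | None
) -> float:
    if policy is Phi0Policy.PEAK:
        phi0 = float(prevalence.max())
        if phi0 <= 0.0:
            raise UndefinedRatioError(
                "PEAK phi0 policy needs a nonzero prevalence somewhere in the "
                "trajectory"
            )
        return phi0
    if policy is Phi0Policy.FIRST:
        phi0 = float(prevalence[0])
        if phi0 <= 0.0:
            raise UndefinedRatioError(
                "FIRST phi0 policy needs a nonzero initial prevalence"
            )
        return phi0
    if policy is Phi0Policy.EXPLICIT:
        if phi0_value is None or not (0.0 < phi0_value <= 1.0):
            raise ScreeningDomainError(
                f"EXPLICIT phi0 policy needs phi0_value in (0, 1], "
                f"got {phi0_value!r}"
            )
        return float(phi0_value)
    raise ValueError(f"unknown phi0 policy {policy!r}")


def _couple(
    times: np.ndarray,
    susceptible: np.ndarray,
    infected: np.ndarray,
    recovered: np.ndarray,
    test: TestCharacteristics,
    phi0_policy: Phi0Policy,
    phi0_value: float | None,
) -> SIRPTrajectory:
    test.require_informative()
    phi_e = prevalence_threshold(test)
    phi0 = _resolve_phi0(infected, phi0_policy, phi0_value)
    ppv_ref = ppv(test, phi0)

    ppv_col = np.array([ppv(test, float(x)) for x in infected])
    zeta_col = ppv_col / ppv_ref
    pti_col = np.array(
        [
            iterations_to_threshold(test, float(x)).n_iterations
            if 0.0 < x < 1.0
            else 0
            for x in infected
        ],
        dtype=int,
    )

    crossings: list[tuple[float, str]] = []
    above = infected >= phi_e
    for idx in range(1, len(infected)):
        if above[idx] and not above[idx - 1]:
            crossings.append((float(times[idx]), "up"))
        elif above[idx - 1] and not above[idx]:
            crossings.append((float(times[idx]), "down"))

    frame = pd.DataFrame(
        {
            "week": np.arange(1, len(infected) + 1, dtype=int),
            "t": times,
            "susceptible": susceptible,
            "infected": infected,
            "recovered": recovered,
            "ppv": ppv_col,
            "zeta": zeta_col,
            "pti": pti_col,
        }
    )
    return SIRPTrajectory(
        frame=frame,
        phi_e=phi_e,
        phi0_reference=phi0,
        test=test,
        threshold_crossings=crossings,
    )


def couple_ppv(
    states: Sequence[SIRState],
    test: TestCharacteristics,
    phi0_policy: Phi0Policy = Phi0Policy.PEAK,
    phi0_value: float | None = None,
) -> SIRPTrajectory:
    """Annotate simulated SIR states with PPV, zeta and PTI per record."""
    if len(states) == 0:
        raise ScreeningDomainError("cannot couple an empty state sequence")
    return _couple(
        times=np.array([st.t for st in states]),
        susceptible=np.array([st.s for st in states]),
        infected=np.array([st.i for st in states]),
        recovered=np.array([st.r for st in states]),
        test=test,
        phi0_policy=phi0_policy,
        phi0_value=phi0_value,
    )


def build_table(
    prevalence_series: Iterable[tuple[float, float]],
    test: TestCharacteristics,
    phi0_policy: Phi0Policy = Phi0Policy.PEAK,
    phi0_value: float | None = None,
) -> SIRPTrajectory:
    """Couple PPV/zeta/PTI to an externally supplied prevalence series.

    ``prevalence_series`` yields (t, infected_fraction) pairs — for example
    a published weekly prevalence column.  Susceptible/recovered are not
    known for external series and are reported as NaN.
    """
    series = list(prevalence_series)
    if not series:
        raise ScreeningDomainError("prevalence series is empty")
    times = np.array([float(t) for t, _ in series])
    infected = np.array([float(x) for _, x in series])
    if infected.min() < 0.0 or infected.max() > 1.0:
        raise ScreeningDomainError(
            "prevalence values must be fractions in [0, 1]"
        )
    nan = np.full(len(series), np.nan)
    return _couple(
        times=times,
        susceptible=nan,
        infected=infected,
        recovered=nan.copy(),
        test=test,
        phi0_policy=phi0_policy,
        phi0_value=phi0_value,
    )
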