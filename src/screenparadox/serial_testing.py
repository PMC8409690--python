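"""Serial positive-test updating and iteration counts.

Each positive result multiplies the disease odds by the positive likelihood
ratio LR+ = a/(1-b); after n consecutive positives the cumulative PPV is

    odds_n / (1 + odds_n),   odds_n = phi/(1-phi) * LR+**n.

Solving for the smallest integer n whose cumulative PPV reaches a target rho
gives the ceiling

    n = ceil( ln[ rho*(phi-1) / (phi*(rho-1)) ] / ln(LR+) ),

i.e. the log of the target-to-prior odds ratio in base LR+.  Targeting the
PPV at the prevalence threshold yields the number of positive test
iterations (PTI) needed to undo the screening paradox at a given prevalence.

Model assumption (not configurable): repeat tests are conditionally
independent given disease status, so likelihood ratios multiply.  Correlated
errors — same specimen, same analyte, same interferent — would make these
counts optimistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .bayes_core import TestCharacteristics, ppv_at_threshold
from .errors import DegenerateTestError, ScreeningDomainError

__all__ = [
    "SerialPlan",
    "serial_ppv",
    "serial_iterations",
    "iterations_to_threshold",
]

# snap tolerance for ceilings landing on (floating images of) exact integers
_CEIL_EPS = 1e-9


@dataclass(frozen=True)
class SerialPlan:
    """A prescribed number of consecutive positive tests.

    ``n_iterations`` is the smallest n >= 1 whose cumulative serial PPV at
    ``prevalence`` reaches ``target_ppv``; equivalently
    ``serial_ppv(test, prevalence, n) >= target_ppv`` while n-1 positives
    (when n > 1) fall short.
    """

    n_iterations: int
    target_ppv: float
    prevalence: float


def serial_ppv(
    test: TestCharacteristics, prevalence: float, n: int
) -> float:
    """Cumulative PPV after ``n`` consecutive positive results.

    ``n = 0`` returns the prior (no evidence); ``n = 1`` reproduces the
    single-test PPV.  Strictly increasing in n whenever LR+ > 1.
    """
    if not (0.0 < prevalence < 1.0):
        raise ScreeningDomainError(
            f"prevalence must lie strictly in (0, 1) for odds updating, "
            f"got {prevalence!r}"
        )
    if n < 0:
        raise ScreeningDomainError(f"n must be a non-negative integer, got {n!r}")
    odds = prevalence / (1.0 - prevalence) * test.lr_plus**n
    return odds / (1.0 + odds)


def _ceil_snapped(x: float) -> int:
    """Ceiling that treats values within _CEIL_EPS of an integer as exact."""
    nearest = round(x)
    if abs(x - nearest) <= _CEIL_EPS:
        return int(nearest)
    return math.ceil(x)


def serial_iterations(
    test: TestCharacteristics, prevalence: float, target_ppv: float
) -> SerialPlan:
    """Smallest number of consecutive positives reaching ``target_ppv``.

    Evaluates the closed-form ceiling of the log odds ratio and clamps the
    result below at 1: the count is of tests actually performed, and one
    positive is always taken, even when the prior alone already exceeds the
    target.
    """
    if not (0.0 < prevalence < 1.0):
        raise ScreeningDomainError(
            f"prevalence must lie strictly in (0, 1), got {prevalence!r}"
        )
    if not (0.0 < target_ppv < 1.0):
        raise ScreeningDomainError(
            f"target_ppv must lie strictly in (0, 1), got {target_ppv!r}"
        )
    if test.lr_plus <= 1.0:
        raise DegenerateTestError(
            "serial updating requires LR+ > 1; a positive result from this "
            f"test does not raise the odds (LR+ = {test.lr_plus:.6g})"
        )
    # target(phi-1)/(phi(target-1)) == [target/(1-target)] / [phi/(1-phi)]
    odds_ratio = (target_ppv * (prevalence - 1.0)) / (
        prevalence * (target_ppv - 1.0)
    )
    raw = math.log(odds_ratio) / math.log(test.lr_plus)
    n = max(_ceil_snapped(raw), 1)
    return SerialPlan(n_iterations=n, target_ppv=target_ppv, prevalence=prevalence)


def iterations_to_threshold(
    test: TestCharacteristics, prevalence: float, form: str = "target"
) -> SerialPlan:
    """Positive test iterations (PTI) to reach the threshold-level PPV.

    The target is the PPV at the prevalence threshold, phi_e * sqrt(LR+) —
    the level above which the retention ratio zeta stays near 1, so reaching
    it neutralises the screening paradox at the current prevalence.

    ``form="omega"`` evaluates the algebraically equivalent rewriting in
    omega = sqrt(LR+), with denominator 2*ln(omega); it exists to expose the
    identity, and returns the same integer as ``form="target"``.
    """
    test.require_informative()
    rho_e = ppv_at_threshold(test)
    if form == "target":
        return serial_iterations(test, prevalence, rho_e)
    if form == "omega":
        if not (0.0 < prevalence < 1.0):
            raise ScreeningDomainError(
                f"prevalence must lie strictly in (0, 1), got {prevalence!r}"
            )
        omega = test.omega
        if omega <= 1.0:
            raise DegenerateTestError(
                f"serial updating requires LR+ > 1 (omega = {omega:.6g})"
            )
        phi_e = rho_e / omega
        raw = math.log(
            (omega * phi_e * (prevalence - 1.0))
            / (prevalence * (omega * phi_e - 1.0))
        ) / (2.0 * math.log(omega))
        n = max(_ceil_snapped(raw), 1)
        return SerialPlan(n_iterations=n, target_ppv=rho_e, prevalence=prevalence)
    raise ValueError(f"unknown form {form!r}")
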