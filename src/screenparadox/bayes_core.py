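"""Closed-form Bayesian screening metrics.

The positive predictive value (PPV) of a screening test is tied to disease
prevalence through Bayes' theorem,

    rho(phi) = a*phi / (a*phi + (1 - b)*(1 - phi)),

with sensitivity ``a``, specificity ``b`` and prevalence ``phi``.  When a
screening programme succeeds — cases found and treated, prevalence falling —
the same theorem lowers the test's own future PPV ("screening paradox").
This module provides the scalar machinery for reasoning about that effect:

* :func:`ppv` — Bayes' rule for the post-test probability of disease;
* :func:`zeta` — the predictive-value retention ratio rho(phi_k)/rho(phi_0)
  between two prevalence levels;
* :func:`prevalence_threshold` — the inflection prevalence phi_e below which
  PPV collapses most steeply, sqrt(1-b)/(sqrt(a)+sqrt(1-b));
* :func:`classify_scenario` — where (phi_0, phi_k) sit relative to phi_e.

All functions operate on population fractions in [0, 1] and are pure.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

from .errors import (
    DegenerateTestError,
    PrevalenceOrderError,
    ScreeningDomainError,
    UndefinedRatioError,
)

__all__ = [
    "TestCharacteristics",
    "PrevalencePair",
    "Scenario",
    "ParadoxAssessment",
    "ppv",
    "zeta",
    "zeta_flipped",
    "prevalence_threshold",
    "ppv_at_threshold",
    "classify_scenario",
]


@dataclass(frozen=True)
class TestCharacteristics:
    """Sensitivity/specificity pair with the derived summary quantities.

    Parameters
    ----------
    sensitivity : float
        True positive rate ``a``, in (0, 1].
    specificity : float
        True negative rate ``b``, in (0, 1).  Exactly 1 is rejected because
        the positive likelihood ratio a/(1-b) — which drives serial-testing
        arithmetic — would be undefined.

    Attributes
    ----------
    fallout : float
        False positive rate, 1 - specificity.
    youden_j : float
        Youden's J statistic, sensitivity + specificity - 1.  A test is
        *informative* when J > 0; threshold-dependent operations require it.
    lr_plus : float
        Positive likelihood ratio, sensitivity / (1 - specificity): the
        multiplicative odds update carried by one positive result.
    omega : float
        sqrt(lr_plus); convenient in serial-testing closed forms.
    """

    sensitivity: float
    specificity: float

    # not a pytest test class, despite the Test* name
    __test__ = False

    def __post_init__(self) -> None:
        if not (0.0 < self.sensitivity <= 1.0):
            raise ScreeningDomainError(
                f"sensitivity must be in (0, 1], got {self.sensitivity!r}"
            )
        if not (0.0 < self.specificity < 1.0):
            raise ScreeningDomainError(
                "specificity must be in (0, 1); specificity == 1 makes the "
                f"positive likelihood ratio undefined (got {self.specificity!r})"
            )

    @property
    def fallout(self) -> float:
        return 1.0 - self.specificity

    @property
    def youden_j(self) -> float:
        return self.sensitivity + self.specificity - 1.0

    @property
    def lr_plus(self) -> float:
        return self.sensitivity / (1.0 - self.specificity)

    @property
    def omega(self) -> float:
        return math.sqrt(self.lr_plus)

    def require_informative(self) -> None:
        """Raise :class:`DegenerateTestError` unless Youden's J > 0."""
        if self.youden_j <= 0.0:
            raise DegenerateTestError(
                f"operation requires an informative test (Youden's J > 0); "
                f"got J = {self.youden_j:.6g}"
            )


@dataclass(frozen=True)
class PrevalencePair:
    """An initial prevalence ``phi0`` and a later, lower prevalence ``phik``.

    The pair encodes the paradox direction: prevalence falling under a
    successful screening programme, so ``phi0 > phik`` is enforced.  For a
    rising prevalence use :func:`zeta_flipped`.  ``k = phi0 - phik`` is the
    absolute prevalence reduction.
    """

    phi0: float
    phik: float
    k: float = field(init=False)

    def __post_init__(self) -> None:
        for name, value in (("phi0", self.phi0), ("phik", self.phik)):
            if not (0.0 < value < 1.0):
                raise ScreeningDomainError(
                    f"{name} must be a prevalence in (0, 1), got {value!r}"
                )
        if self.phik > self.phi0:
            raise PrevalenceOrderError(
                f"phik ({self.phik!r}) exceeds phi0 ({self.phi0!r}); this type "
                "models a falling prevalence. For a rising prevalence use "
                "zeta_flipped(), which flips the terms of the ratio."
            )
        object.__setattr__(self, "k", self.phi0 - self.phik)


class Scenario(enum.Enum):
    """Position of the prevalence threshold relative to (phi0, phik)."""

    THRESHOLD_ABOVE = "threshold_above"    # phi_e > phi0 > phik
    THRESHOLD_BELOW = "threshold_below"    # phi0 > phik > phi_e
    THRESHOLD_CROSSED = "threshold_crossed"  # phi0 >= phi_e >= phik


@dataclass(frozen=True)
class ParadoxAssessment:
    """Outcome of :func:`classify_scenario`: the ordering scenario, the
    prevalence threshold, and the predictive-value retention ratio zeta."""

    scenario: Scenario
    phi_e: float
    zeta: float


def ppv(test: TestCharacteristics, prevalence: float) -> float:
    """Positive predictive value of ``test`` at ``prevalence`` (Bayes' rule).

    Strictly increasing in prevalence whenever Youden's J > 0; equals 0 at
    prevalence 0 and 1 at prevalence 1 (for specificity < 1).
    """
    if not (0.0 <= prevalence <= 1.0):
        raise ScreeningDomainError(
            f"prevalence must lie in [0, 1], got {prevalence!r}"
        )
    a = test.sensitivity
    c = test.fallout
    num = a * prevalence
    return num / (num + c * (1.0 - prevalence))


def zeta(
    test: TestCharacteristics,
    pair: PrevalencePair,
    method: str = "simplified",
) -> float:
    """Predictive-value retention ratio rho(phik)/rho(phi0) in (0, 1].

    Two algebraically identical routes are provided: ``"quotient"`` divides
    two Bayes'-rule evaluations, while ``"simplified"`` (default) uses the
    expanded form

        [phik*(1-b) + J*phi0*phik] / [phi0*(1-b) + J*phi0*phik],

    which makes the roles of the fall-out and Youden's J explicit.  Their
    agreement is a regression-tested identity, not a configuration choice.
    """
    if method == "quotient":
        denom = ppv(test, pair.phi0)
        if denom == 0.0:
            raise UndefinedRatioError("reference PPV rho(phi0) is zero")
        return ppv(test, pair.phik) / denom
    if method == "simplified":
        c = test.fallout
        j = test.youden_j
        cross = j * pair.phi0 * pair.phik
        denom = pair.phi0 * c + cross
        if denom == 0.0:
            raise UndefinedRatioError("reference PPV rho(phi0) is zero")
        return (pair.phik * c + cross) / denom
    raise ValueError(f"unknown zeta method {method!r}")


def zeta_flipped(
    test: TestCharacteristics, phi_start: float, phi_end: float
) -> float:
    """Retention ratio for a *rising* prevalence (phi_end > phi_start).

    Flips the terms of the zeta fraction: returns rho(phi_start)/rho(phi_end),
    the complement ratio appropriate when prevalence increases over time.
    """
    if not phi_end > phi_start:
        raise PrevalenceOrderError(
            "zeta_flipped expects a rising prevalence (phi_end > phi_start); "
            "use zeta() with a PrevalencePair for the falling direction"
        )
    return zeta(test, PrevalencePair(phi0=phi_end, phik=phi_start))


def prevalence_threshold(
    test: TestCharacteristics, form: str = "conjugate"
) -> float:
    """Prevalence threshold phi_e: the inflection of the PPV-vs-prevalence
    curve below which PPV falls most steeply.

    ``form="conjugate"`` (canonical) evaluates the radical-conjugate
    simplification sqrt(1-b) / (sqrt(a) + sqrt(1-b)), defined for every
    constructible test.  ``form="youden"`` evaluates the original expression
    (sqrt(a*(1-b)) + b - 1) / (a + b - 1), which divides by Youden's J and is
    therefore restricted to informative tests; the two agree to ~1e-15 on
    that common domain.
    """
    a = test.sensitivity
    c = test.fallout
    if form == "conjugate":
        root_c = math.sqrt(c)
        return root_c / (math.sqrt(a) + root_c)
    if form == "youden":
        test.require_informative()
        return (math.sqrt(a * c) + test.specificity - 1.0) / test.youden_j
    raise ValueError(f"unknown threshold form {form!r}")


def ppv_at_threshold(test: TestCharacteristics) -> float:
    """PPV evaluated at the prevalence threshold: phi_e * sqrt(LR+).

    Coincides with ``ppv(test, prevalence_threshold(test))``.  Defined down
    to the chance-level boundary J = 0 (where it degenerates to phi_e
    itself); a test with negative J is rejected, since a "threshold PPV" is
    meaningless when positives lower the odds.
    """
    if test.youden_j < 0.0:
        raise DegenerateTestError(
            f"threshold-level PPV needs Youden's J >= 0; got J = "
            f"{test.youden_j:.6g}"
        )
    return prevalence_threshold(test) * math.sqrt(test.lr_plus)


def classify_scenario(
    test: TestCharacteristics, pair: PrevalencePair
) -> ParadoxAssessment:
    """Classify where a falling prevalence pair sits relative to phi_e.

    THRESHOLD_ABOVE (phi_e > phi0 > phik): the whole decline happens below
    the threshold, where PPV loss is steepest.  THRESHOLD_BELOW
    (phi0 > phik > phi_e): both levels sit on the flat, high-PPV limb, so the
    retention ratio stays near 1.  THRESHOLD_CROSSED (phi0 >= phi_e >= phik):
    the decline carries prevalence through the threshold — the canonical
    paradox.  Boundary equalities classify as crossed, treating k = phi0 -
    phi_e as the limiting crossing case.
    """
    test.require_informative()
    phi_e = prevalence_threshold(test)
    if phi_e > pair.phi0:
        scenario = Scenario.THRESHOLD_ABOVE
    elif pair.phik > phi_e:
        scenario = Scenario.THRESHOLD_BELOW
    else:
        scenario = Scenario.THRESHOLD_CROSSED
    return ParadoxAssessment(
        scenario=scenario, phi_e=phi_e, zeta=zeta(test, pair)
    )
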