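"""Closed-form Bayesian screening metrics: values, identities, invariants."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from screenparadox import (
    DegenerateTestError,
    PrevalenceOrderError,
    PrevalencePair,
    Scenario,
    ScreeningDomainError,
    TestCharacteristics,
    classify_scenario,
    ppv,
    ppv_at_threshold,
    prevalence_threshold,
    zeta,
    zeta_flipped,
)

# strategies for valid tests and prevalences; informative = Youden's J > 0
valid_tests = st.builds(
    TestCharacteristics,
    sensitivity=st.floats(0.01, 1.0),
    specificity=st.floats(0.01, 0.999),
)
informative_tests = valid_tests.filter(lambda t: t.youden_j > 1e-6)
prevalences = st.floats(1e-6, 1.0 - 1e-6)


class TestTestCharacteristics:
    def test_derived_quantities_are_consistent(self):
        t = TestCharacteristics(0.85, 0.90)
        assert t.fallout == pytest.approx(0.10)
        assert t.youden_j == pytest.approx(0.75)
        assert t.lr_plus == pytest.approx(8.5)
        assert t.omega**2 == pytest.approx(t.lr_plus, rel=1e-12)

    @pytest.mark.parametrize(
        "sens,spec",
        [(0.0, 0.9), (1.2, 0.9), (0.9, 1.0), (0.9, 0.0), (-0.1, 0.5)],
    )
    def test_out_of_range_characteristics_rejected(self, sens, spec):
        with pytest.raises(ScreeningDomainError):
            TestCharacteristics(sens, spec)

    def test_uninformative_test_constructs_but_flags(self):
        t = TestCharacteristics(0.4, 0.5)  # J = -0.1
        with pytest.raises(DegenerateTestError):
            t.require_informative()


class TestPpv:
    @pytest.mark.parametrize(
        "sens,spec,prev,expected",
        [
            (0.95, 0.99, 0.0766, 0.8874),  # published week-10 value
            (0.85, 0.90, 0.5, 0.425 / 0.475),  # hand evaluation
        ],
    )
    def test_known_values(self, sens, spec, prev, expected):
        assert ppv(TestCharacteristics(sens, spec), prev) == pytest.approx(
            expected, abs=5e-5
        )

    def test_boundary_prevalences(self, worked_test):
        assert ppv(worked_test, 0.0) == 0.0
        assert ppv(worked_test, 1.0) == 1.0

    @pytest.mark.parametrize("prev", [-0.1, 1.1])
    def test_prevalence_outside_unit_interval_rejected(self, worked_test, prev):
        with pytest.raises(ScreeningDomainError):
            ppv(worked_test, prev)

    @settings(max_examples=200, deadline=None)
    @given(test=informative_tests, lo=prevalences, hi=prevalences)
    def test_strictly_increasing_in_prevalence(self, test, lo, hi):
        if lo > hi:
            lo, hi = hi, lo
        if hi - lo < 1e-9:
            return
        assert ppv(test, hi) > ppv(test, lo)


class TestZeta:
    @pytest.mark.parametrize(
        "phi0,phik,expected",
        [
            (0.5208, 0.2733, 0.9822),  # published week-12 value
            (0.5208, 0.0766, 0.8960),  # published week-10 value
        ],
    )
    def test_known_values(self, worked_test, phi0, phik, expected):
        pair = PrevalencePair(phi0=phi0, phik=phik)
        assert zeta(worked_test, pair) == pytest.approx(expected, abs=5e-5)

    def test_quotient_route_matches_direct_ratio(self):
        t = TestCharacteristics(0.85, 0.90)
        pair = PrevalencePair(0.3, 0.1)
        expected = ppv(t, 0.1) / ppv(t, 0.3)
        assert zeta(t, pair, method="quotient") == pytest.approx(expected, rel=1e-15)

    @settings(max_examples=300, deadline=None)
    @given(test=valid_tests, a=prevalences, b=prevalences)
    def test_simplified_and_quotient_routes_agree(self, test, a, b):
        """The expanded Youden-form ratio is algebraically identical to the
        quotient of two Bayes'-rule evaluations."""
        if abs(a - b) < 1e-12:
            return
        pair = PrevalencePair(phi0=max(a, b), phik=min(a, b))
        assert zeta(test, pair, "simplified") == pytest.approx(
            zeta(test, pair, "quotient"), abs=1e-12, rel=1e-9
        )

    def test_rising_prevalence_rejected_with_flip_hint(self, worked_test):
        with pytest.raises(PrevalenceOrderError, match="flip"):
            PrevalencePair(phi0=0.1, phik=0.3)

    def test_zero_phi0_unconstructible(self):
        with pytest.raises(ScreeningDomainError):
            PrevalencePair(phi0=0.0, phik=0.0)

    def test_flipped_helper_handles_rising_prevalence(self, worked_test):
        val = zeta_flipped(worked_test, 0.1, 0.3)
        pair = PrevalencePair(phi0=0.3, phik=0.1)
        assert val == pytest.approx(zeta(worked_test, pair), rel=1e-12)
        with pytest.raises(PrevalenceOrderError):
            zeta_flipped(worked_test, 0.3, 0.1)

    def test_limit_to_one_as_reduction_vanishes(self, worked_test):
        pair = PrevalencePair(phi0=0.5, phik=0.5 - 1e-10)
        assert zeta(worked_test, pair) == pytest.approx(1.0, abs=1e-8)

    def test_limit_to_zero_as_phik_vanishes(self, worked_test):
        pair = PrevalencePair(phi0=0.5, phik=1e-6)
        assert zeta(worked_test, pair) < 0.01

    @settings(max_examples=200, deadline=None)
    @given(test=informative_tests, phi0=prevalences, x=prevalences, y=prevalences)
    def test_monotone_in_phik(self, test, phi0, x, y):
        lo, hi = sorted((x * phi0, y * phi0))
        if hi - lo < 1e-12 or lo <= 0:
            return
        z_lo = zeta(test, PrevalencePair(phi0, lo))
        z_hi = zeta(test, PrevalencePair(phi0, hi))
        assert z_hi > z_lo

    @settings(max_examples=200, deadline=None)
    @given(x=st.floats(0.0, 1.0), y=st.floats(0.0, 1.0))
    def test_flat_above_threshold(self, x, y):
        """Within the band above the prevalence threshold, zeta is minimised
        at the threshold itself: the curve is nearly flat up there."""
        test = TestCharacteristics(0.95, 0.99)
        phi_e = prevalence_threshold(test)
        a, b = sorted((phi_e + x * (1 - phi_e), phi_e + y * (1 - phi_e)))
        if b - a < 1e-9 or a <= phi_e or b >= 1.0:
            return
        assert zeta(test, PrevalencePair(b, a)) > zeta(
            test, PrevalencePair(b, phi_e)
        )


class TestPrevalenceThreshold:
    @pytest.mark.parametrize(
        "sens,spec,expected,tol",
        [
            (0.95, 0.99, 0.093, 5e-4),  # published: "9.3 percent"
            (0.5, 0.5, 0.5, 1e-12),  # symmetric closed form
            (0.85, 0.90, 0.2554, 5e-5),  # hand evaluation of the conjugate form
        ],
    )
    def test_known_values(self, sens, spec, expected, tol):
        assert prevalence_threshold(
            TestCharacteristics(sens, spec)
        ) == pytest.approx(expected, abs=tol)

    def test_perfect_test_limit(self):
        assert prevalence_threshold(TestCharacteristics(1.0, 1 - 1e-12)) < 1e-5

    @settings(max_examples=300, deadline=None)
    @given(test=informative_tests)
    def test_conjugate_and_youden_forms_agree(self, test):
        """The radical-conjugate simplification equals the Youden-ratio form
        wherever the latter is defined."""
        assert prevalence_threshold(test, "conjugate") == pytest.approx(
            prevalence_threshold(test, "youden"), abs=1e-12, rel=1e-9
        )

    def test_youden_form_rejects_degenerate_test(self):
        t = TestCharacteristics(0.4, 0.5)
        with pytest.raises(DegenerateTestError):
            prevalence_threshold(t, form="youden")
        # the conjugate form remains defined
        assert 0.0 < prevalence_threshold(t) < 1.0


class TestPpvAtThreshold:
    @pytest.mark.parametrize(
        "sens,spec,expected",
        [(0.95, 0.99, 0.9070), (0.5, 0.5, 0.5), (0.85, 0.90, 0.7446)],
    )
    def test_known_values(self, sens, spec, expected):
        assert ppv_at_threshold(TestCharacteristics(sens, spec)) == pytest.approx(
            expected, abs=1e-4
        )

    @settings(max_examples=300, deadline=None)
    @given(test=informative_tests)
    def test_closed_form_matches_composition(self, test):
        """phi_e * sqrt(LR+) equals Bayes' rule evaluated at phi_e."""
        assert ppv_at_threshold(test) == pytest.approx(
            ppv(test, prevalence_threshold(test)), abs=1e-10
        )

    def test_negative_j_rejected_but_chance_level_allowed(self):
        with pytest.raises(DegenerateTestError):
            ppv_at_threshold(TestCharacteristics(0.4, 0.5))
        # J == 0 sits on the boundary where the closed form degenerates
        # to phi_e itself
        assert ppv_at_threshold(TestCharacteristics(0.5, 0.5)) == pytest.approx(0.5)


class TestClassifyScenario:
    @pytest.mark.parametrize(
        "phi0,phik,expected",
        [
            (0.5208, 0.2733, Scenario.THRESHOLD_BELOW),
            (0.05, 0.01, Scenario.THRESHOLD_ABOVE),
            (0.15, 0.05, Scenario.THRESHOLD_CROSSED),
        ],
    )
    def test_strict_orderings(self, worked_test, phi0, phik, expected):
        result = classify_scenario(worked_test, PrevalencePair(phi0, phik))
        assert result.scenario is expected
        assert 0.0 < result.zeta <= 1.0
        assert result.phi_e == pytest.approx(0.093, abs=5e-4)

    def test_boundary_equalities_classify_as_crossed(self, worked_test):
        phi_e = prevalence_threshold(worked_test)
        at_top = classify_scenario(worked_test, PrevalencePair(phi_e, 0.01))
        at_bottom = classify_scenario(worked_test, PrevalencePair(0.5, phi_e))
        assert at_top.scenario is Scenario.THRESHOLD_CROSSED
        assert at_bottom.scenario is Scenario.THRESHOLD_CROSSED

    @settings(max_examples=200, deadline=None)
    @given(test=informative_tests, a=prevalences, b=prevalences)
    def test_exactly_one_scenario_holds(self, test, a, b):
        if abs(a - b) < 1e-12:
            return
        pair = PrevalencePair(max(a, b), min(a, b))
        result = classify_scenario(test, pair)
        assert result.scenario in Scenario
        if result.scenario is Scenario.THRESHOLD_ABOVE:
            assert result.phi_e > pair.phi0
        elif result.scenario is Scenario.THRESHOLD_BELOW:
            assert pair.phik > result.phi_e
        else:
            assert pair.phi0 >= result.phi_e >= pair.phik
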