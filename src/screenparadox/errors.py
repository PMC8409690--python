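"""Exception hierarchy for screening-paradox computations.

All domain errors derive from :class:`ScreeningDomainError` (a ``ValueError``)
so callers can catch one type at API boundaries; the CLI maps them to a
one-line diagnostic and a nonzero exit code.
"""


class ScreeningDomainError(ValueError):
    """An input lies outside the mathematical domain of an operation."""


class DegenerateTestError(ScreeningDomainError):
    """The test is uninformative (Youden's J <= 0 or LR+ <= 1) where an
    operation requires an informative one."""


class UndefinedRatioError(ScreeningDomainError):
    """A predictive-value ratio has a vanishing or undefined reference."""


class PrevalenceOrderError(ScreeningDomainError):
    """Prevalences supplied in the rising direction to a falling-prevalence
    operation (or vice versa)."""


class ConfigError(ValueError):
    """A configuration file is malformed, has unknown keys, or holds
    out-of-range values."""


class IntegrationError(RuntimeError):
    """The ODE integration produced a non-finite state."""
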