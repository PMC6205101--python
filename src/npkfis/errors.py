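"""Exception hierarchy shared across the package."""


class FuzzyNPKError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(FuzzyNPKError):
    """Invalid variable/system configuration (bad intervals, domains, JSON)."""


class InvalidInputError(FuzzyNPKError, ValueError):
    """A crisp reading is non-finite or otherwise unusable."""


class RuleParseError(FuzzyNPKError):
    """A rule DSL line could not be parsed.

    Carries the 1-based line number of the offending line.
    """

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class RuleValidationError(FuzzyNPKError):
    """A rule or rule base violates a structural constraint."""


class InferenceError(FuzzyNPKError):
    """Inference could not be carried out (missing variables, bad system)."""


class NoRuleFiredError(InferenceError):
    """An aggregated output set has zero mass: no rule contributed.

    Carries the name of the output variable whose centroid is undefined.
    """

    def __init__(self, variable: str):
        self.variable = variable
        super().__init__(
            f"no rule fired for output {variable!r}: aggregated set has zero "
            "mass, centroid undefined (check rule base completeness)"
        )


class UndefinedMetricError(FuzzyNPKError, ZeroDivisionError):
    """A rate metric was requested with a zero denominator."""


class PanelSpecError(ConfigError):
    """Invalid synthetic-panel specification."""
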