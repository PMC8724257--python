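"""Exception hierarchy shared across the package."""


class HerbmineError(Exception):
    """Base class for all package errors."""


class ValidationError(HerbmineError):
    """Input data violates the data model (duplicate ids, bad doses, unknown items)."""


class ParseError(ValidationError):
    """A property/flavor string could not be interpreted in strict mode."""


class InfeasibleConstraintsError(HerbmineError):
    """An exact-count constraint system admits no transaction set.

    Carries the human-readable violations (if the feasibility checker
    identified any) on the ``violations`` attribute.
    """

    def __init__(self, message: str, violations: list[str] | None = None):
        super().__init__(message)
        self.violations = list(violations or [])
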