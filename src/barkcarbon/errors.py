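"""Exception hierarchy used across the package."""


class BarkError(Exception):
    """Base class for all package errors."""


class BarkDomainError(BarkError, ValueError):
    """A value violates a physical or mathematical precondition."""


class BarkUsageError(BarkError, RuntimeError):
    """An operation was applied to data it is not meant for."""


class ConfigurationError(BarkError, ValueError):
    """Required configuration (mode fields, config keys) is missing or invalid."""


class MeasurementParseError(BarkError, ValueError):
    """A measurement file failed validation; carries one message per offending line."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__(
            "measurement file invalid:\n" + "\n".join(f"  - {p}" for p in self.problems)
        )
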