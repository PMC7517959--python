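"""Exception hierarchy shared across the package."""


class TrialscapeError(Exception):
    """Base class for all package-specific errors."""


class RegistryParseError(TrialscapeError):
    """A registry file is malformed (bad envelope, missing columns, bad JSON)."""


class RecordValidationError(TrialscapeError):
    """A record violates a hard contract (unknown enum token, missing annotation)."""


class ConfigError(TrialscapeError):
    """A generator or pipeline configuration is internally inconsistent."""


class ScoringError(TrialscapeError):
    """A rubric assignment cannot be scored (unknown level, bad raw input)."""


class TableUsageError(TrialscapeError):
    """A census table or percentage rendering was requested with invalid arguments."""
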