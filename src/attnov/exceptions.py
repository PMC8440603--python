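"""Exception hierarchy shared across the package."""


class AttnovError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(AttnovError, ValueError):
    """An option, config field, or identifier is invalid or unknown."""


class ScoringError(AttnovError, ValueError):
    """A document cannot be scored (e.g. it has no tokens)."""


class IntegrityError(AttnovError, ValueError):
    """Internal consistency violated, e.g. token missing from corpus stats."""


class DomainError(AttnovError, ValueError):
    """An input value lies outside the mathematical domain of an operation."""


class FitError(AttnovError, RuntimeError):
    """A model fit failed to converge or the design is degenerate."""


class StateError(AttnovError, RuntimeError):
    """An object was used before being put in the required state."""
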