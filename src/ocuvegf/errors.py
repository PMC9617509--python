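"""Exception hierarchy for ocuvegf."""


class OcuvegfError(Exception):
    """Base class for all ocuvegf errors."""


class ConfigError(OcuvegfError):
    """Invalid, incomplete, or unparsable study configuration."""


class FitError(OcuvegfError):
    """A regression failed or the data cannot identify the model.

    Carries the best parameters seen so far (if any) plus diagnostics,
    so callers can inspect what went wrong instead of getting silence.
    """

    def __init__(self, message, best_params=None, diagnostics=None):
        super().__init__(message)
        self.best_params = best_params
        self.diagnostics = diagnostics or {}


class NCAError(OcuvegfError):
    """Noncompartmental analysis cannot proceed on the given profile."""


class IntegrationError(OcuvegfError):
    """ODE integration failure; carries the final state for debugging."""

    def __init__(self, message, state=None):
        super().__init__(message)
        self.state = state
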