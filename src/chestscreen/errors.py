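"""Exception hierarchy for chestscreen."""


class ChestscreenError(Exception):
    """Base class for all package-specific errors."""


class ProfileValidationError(ChestscreenError, ValueError):
    """A patient profile violates one of its invariants."""


class ConfigurationError(ChestscreenError, ValueError):
    """Thresholds or other configuration values are malformed."""


class InternalConsistencyError(ChestscreenError, RuntimeError):
    """A constants table is incomplete or self-contradictory."""


class FlowUsageError(ChestscreenError, RuntimeError):
    """The questionnaire flow was driven incorrectly (e.g. answering a
    terminal state, or an answer string too short to reach a terminal)."""
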