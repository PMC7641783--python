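"""Exception hierarchy shared across the pipeline stages.

Every stage raises a subclass of :class:`PointScoreError` so callers (and
the CLI) can map failures to a stage-tagged message and exit code.
"""


class PointScoreError(Exception):
    """Base class for all errors raised by this package."""


class SchemaError(PointScoreError):
    """Input table does not match the declared schema (e.g. missing outcome)."""


class ValidationError(PointScoreError):
    """A value or argument violates a documented contract."""


class ConfigurationError(PointScoreError):
    """A configuration entry references something that does not exist."""


class SizeError(PointScoreError):
    """A split or partition would be empty."""


class ImputationError(PointScoreError):
    """A continuous variable has no observed training values to impute from."""


class DegenerateOutcomeError(PointScoreError):
    """Only one outcome class is present; nothing can be fitted."""


class DegenerateVariableError(PointScoreError):
    """A variable is constant (or near-constant) and cannot be binned."""


class NoSignalError(PointScoreError):
    """All fitted coefficients are numerically zero; the score would be empty."""


class ScoringError(PointScoreError):
    """An episode cannot be scored against a score table."""


class SelectionError(PointScoreError):
    """Requested model size is not on the parsimony curve."""


class UnattainableTargetError(PointScoreError):
    """No threshold reaches the requested sensitivity/specificity level."""


class CIError(PointScoreError):
    """Bootstrap confidence interval undefined on too many replicates."""
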