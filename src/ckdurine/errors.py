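"""Exception hierarchy.

``DomainError`` marks inputs outside the physiological/mathematical domain of
an operation; ``CriterionUnavailableError`` marks a validity criterion that
cannot be evaluated for a visit because required measurements are missing —
deliberately distinct from an *invalid* collection.
"""


class CKDUrineError(Exception):
    """Base class for all package errors."""


class DomainError(CKDUrineError, ValueError):
    """Input outside the operation's domain (e.g. non-positive creatinine)."""


class SchemaError(CKDUrineError):
    """Input file does not match the expected column schema."""


class ConfigError(CKDUrineError):
    """Invalid configuration (unknown criterion token, bad threshold, ...)."""


class CriterionUnavailableError(CKDUrineError):
    """The requested validity criterion cannot be computed for this visit.

    Not an assessment outcome: a visit with, say, no clearance study is
    *unassessable* under the fractional criterion, never 'invalid'.
    """


class PipelineError(CKDUrineError):
    """A pipeline stage failed; the message names the stage."""
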