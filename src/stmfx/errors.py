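"""Exception hierarchy.

All package-specific failures derive from :class:`StmfxError` so callers
(and the CLI) can distinguish input problems from estimator preconditions.
"""


class StmfxError(Exception):
    """Base class for all stmfx errors."""


class SchemaError(StmfxError):
    """A required column is missing or the file is not an STMF-style table."""


class ValidationError(StmfxError):
    """A row or value violates a table invariant (negative, duplicate, ...)."""


class SelectionError(StmfxError):
    """An unknown country/sex/measure was requested, or a selection is empty."""


class ConfigError(StmfxError):
    """A synthetic-data configuration is internally inconsistent."""


class EstimatorError(StmfxError):
    """A reference-level estimator's precondition is not met."""
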