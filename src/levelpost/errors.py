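"""Exception hierarchy for levelpost.

All package-specific errors derive from :class:`LevelpostError` so callers
(and the CLI) can distinguish validation problems (exit code 1) from usage
errors (exit code 2, handled by click).
"""


class LevelpostError(Exception):
    """Base class for all levelpost errors."""


class ValidationError(LevelpostError, ValueError):
    """Input violates a documented invariant (bad taxonomy, unknown label, grid mismatch)."""


class FormatError(LevelpostError, ValueError):
    """File content is structurally unusable (4D image, non-integer label values)."""


class DegenerateInputError(LevelpostError, ValueError):
    """Input is too degenerate for the operation (e.g. constant intensities for Otsu)."""
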