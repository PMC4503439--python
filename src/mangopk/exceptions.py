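"""Named exception hierarchy for the pipeline.

Every validation failure raises a distinct, importable error so callers
(and the CLI) can report precisely what went wrong.
"""


class MangopkError(Exception):
    """Base class for all package-specific errors."""


class ProfileError(MangopkError, ValueError):
    """Invalid concentration-time profile (lengths, ordering, signs)."""


class LambdaZNotEstimable(MangopkError):
    """No decreasing terminal window of the required size could be fit."""


class FormatError(MangopkError, ValueError):
    """Base class for file-format violations."""


class MissingColumnError(FormatError):
    """A required CSV column is absent."""


class NonMonotoneTimeError(FormatError):
    """Sampling times are not strictly increasing within a subject."""


class NegativeConcentrationError(FormatError):
    """A quantified concentration is negative."""


class DuplicatePeakIdError(FormatError):
    """Two peak records share the same identifier."""


class ConfigError(MangopkError, ValueError):
    """Pipeline configuration failed validation (unknown key, bad units)."""
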