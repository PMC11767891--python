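"""Exception hierarchy for nmlab.

All package errors derive from :class:`NmlabError` so callers can catch a
single base class at CLI boundaries.
"""


class NmlabError(Exception):
    """Base class for all nmlab errors."""


class InputError(NmlabError):
    """Invalid argument values or missing input files."""


class FormatError(NmlabError):
    """File content that cannot be decoded or has an unsupported version."""


class ReferencingError(NmlabError):
    """Chemical-shift referencing failed (empty window, no positive maximum)."""


class ConfigError(NmlabError):
    """Invalid configuration (CLI config files, autophase edge regions, ...)."""


class DegenerateInputError(NmlabError):
    """Input that makes an operation mathematically meaningless (e.g. all zeros)."""


class NormalizationError(NmlabError):
    """Normalization impossible for a named sample (non-positive total, ...)."""


class SchemaError(NmlabError):
    """Malformed metabolite library file."""


class PickFailureError(NmlabError):
    """Automatic peak picking failed for the majority of predicted positions."""


class UndefinedObservationError(NmlabError):
    """Requested observable is undefined (e.g. carbon never labelled)."""
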