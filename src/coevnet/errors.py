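"""Exception hierarchy for coevnet."""


class CoevnetError(Exception):
    """Base class for all coevnet errors."""


class AlignmentError(CoevnetError):
    """Alignment integrity violated (ragged rows, duplicate identifiers...)."""


class FormatError(CoevnetError):
    """Input file could not be parsed in the requested format."""


class EmptyResultError(CoevnetError):
    """An operation produced an empty result (e.g. no shared identifiers)."""


class MappingError(CoevnetError):
    """Alignment-to-reference or alignment-to-structure mapping failed."""


class EstimationError(CoevnetError):
    """Coevolution-matrix estimation failed (e.g. glasso non-convergence)."""


class ConfigError(CoevnetError):
    """Run configuration is invalid."""
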