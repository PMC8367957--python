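"""Exception hierarchy shared by all nucleakin modules."""


class NucleakinError(Exception):
    """Base class for all package errors."""


class ParseError(NucleakinError):
    """A text trajectory or table file could not be parsed."""


class FormatError(NucleakinError):
    """A file is structurally valid text but violates the declared format."""


class StructureError(NucleakinError):
    """Parsed data are internally inconsistent (e.g. varying atom counts)."""


class ConfigError(NucleakinError):
    """Missing or contradictory configuration / metadata."""


class GeometryError(NucleakinError):
    """Degenerate geometry (zero-length separation vectors and the like)."""


class EstimationError(NucleakinError):
    """A statistical estimator failed (empty ergodic set, non-convergence)."""


class PipelineCacheError(NucleakinError):
    """A cached pipeline artifact does not match the current configuration."""
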