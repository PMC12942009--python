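"""Exception hierarchy."""


class SlamError(Exception):
    """Base class for all package errors."""


class StructureFormatError(SlamError):
    """Unparseable or empty structure file."""


class LookupError_(SlamError):
    """Unknown chain or atom identifier."""


class AnnotationError(SlamError):
    """Missing element data (radius, electronegativity) during annotation."""


class ExtractionError(SlamError):
    """Substructure too small or otherwise unusable."""


class DegenerateCorrelationError(SlamError):
    """Distance correlation undefined: fewer than 3 pairs or zero variance."""


class SuperpositionError(SlamError):
    """Degenerate point sets passed to the Kabsch superposition."""


class DockingError(SlamError):
    """External docking engine missing or failed."""


class FitError(SlamError):
    """Score-distribution fit impossible (too few values, zero variance)."""


class GenerationError(SlamError):
    """Synthetic-structure generation exceeded its retry budget."""


class ConfigError(SlamError):
    """Invalid configuration value; message carries the field path."""
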