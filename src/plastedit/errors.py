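"""Exception types shared across the pipeline stages."""


class PlasteditError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PlasteditError):
    """Invalid or infeasible configuration (e.g. features exceed genome length)."""


class DataError(PlasteditError):
    """Malformed or inconsistent input data (e.g. alignment outside the genome)."""


class AnnotationError(PlasteditError):
    """Inconsistent feature annotation (e.g. conflicting overlapping features)."""
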