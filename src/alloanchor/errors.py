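"""Exception hierarchy shared by all pipeline stages."""


class AlloanchorError(Exception):
    """Base class for every error raised by this package."""


class ConfigurationError(AlloanchorError):
    """Invalid simulation or pipeline configuration."""


class FormatError(AlloanchorError):
    """Malformed input data (unknown genotype symbol, bad table shape, ...)."""


class PanelError(AlloanchorError):
    """Marker panel inconsistency (length mismatch, duplicate positions, ...)."""


class RegistryError(AlloanchorError):
    """Haplotype registry label/vector collision."""


class IntegrityError(AlloanchorError):
    """Packaged fixture failed its checksum verification."""


class AnnotationError(AlloanchorError):
    """Unknown coding-effect or impact term."""


class MappingError(AlloanchorError):
    """Haplotype-to-serology mapping conflict or missing entry."""


class AnalysisError(AlloanchorError):
    """Statistical analysis cannot proceed (e.g. constant response)."""
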