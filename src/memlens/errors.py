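"""Exception hierarchy used across the package."""


class MemlensError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(MemlensError):
    """Invalid or degenerate geometry (collinear points, overlapping leaflets...)."""


class FormatError(MemlensError):
    """Malformed or unsupported file content."""


class EmptyCloudError(MemlensError):
    """An operation produced or received a point cloud with no points."""


class SelectionError(MemlensError):
    """An atom/residue selection resolved to nothing or is inconsistent."""


class AnnotationError(MemlensError):
    """Required per-atom annotations (radii, H partners...) are missing."""


class ParameterError(MemlensError):
    """Invalid parameter value for an operation."""


class ConfigError(MemlensError):
    """Invalid pipeline run configuration."""
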