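"""Exception types shared across the package."""


class IQFCPError(Exception):
    """Base class for package errors."""


class GeometryError(IQFCPError):
    """Invalid molecular geometry (duplicate/overlapping atoms, bad coordinates)."""


class ParameterizationError(IQFCPError):
    """Missing or invalid per-element parameters."""


class ConfigurationError(IQFCPError):
    """Invalid grid/expansion configuration."""


class WavefunctionParseError(IQFCPError):
    """A wavefunction file could not be parsed; the message names the record."""


class NonNuclearAttractorError(IQFCPError):
    """Gradient ascent found a density maximum with no nucleus nearby (unsupported)."""


class InconsistencyError(IQFCPError):
    """Mutually inconsistent inputs (electron counts, partitions, shapes)."""
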