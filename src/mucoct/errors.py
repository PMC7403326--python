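"""Exception hierarchy for the mucoct pipeline."""


class MucoctError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MucoctError):
    """A run/phantom configuration is internally inconsistent or infeasible."""


class MetadataError(MucoctError):
    """Voxel-spacing (or other physical) metadata is missing or contradictory."""


class DegenerateHistogramError(MucoctError):
    """Automatic thresholding was asked for on a constant (single-level) volume."""


class InsufficientPairsError(MucoctError):
    """Fewer than the required number of crypt-villous pairs are available."""


class MissingCryptError(MucoctError):
    """A VH:CrD ratio was requested but one or more pairs lack a crypt."""
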