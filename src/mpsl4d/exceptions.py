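"""Exception hierarchy shared across the package."""


class MPSLError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MPSLError, ValueError):
    """Invalid configuration, incompatible grids or mismatched dimensionality."""


class VolumeIOError(MPSLError, OSError):
    """Missing, unreadable or unwritable image/trajectory file."""


class FormatError(VolumeIOError):
    """File exists but violates the expected format (e.g. mixed-orientation DICOM)."""


class NoTargetFoundError(MPSLError):
    """No labeled region survived the volume filter (or matched the seed/box).

    Carries the candidate table so callers can inspect what was rejected.
    """

    def __init__(self, message, candidate_table=None, phase_label=None):
        super().__init__(message)
        self.candidate_table = candidate_table
        self.phase_label = phase_label


class AmbiguousSelectionError(MPSLError):
    """Multiple filter survivors and no rule allowed to break the tie.

    Raised only when the caller disables the default largest-volume rule.
    """

    def __init__(self, message, survivors=None):
        super().__init__(message)
        self.survivors = survivors or []


class PhantomSpecificationError(MPSLError, ValueError):
    """Phantom geometry is inconsistent (e.g. tumor leaves the lung cavity)."""
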