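"""Exception hierarchy shared across the atlas-construction pipeline."""


class SymatlasError(Exception):
    """Base class for all package errors."""


class FormatError(SymatlasError):
    """A file could not be read or is not a supported volume format."""


class GridError(SymatlasError):
    """An operation's grid precondition is violated (e.g. flip on an
    asymmetric grid)."""


class SegmentationError(SymatlasError):
    """Tissue segmentation could not distinguish the requested classes."""


class RegistrationError(SymatlasError):
    """Registration produced a non-finite objective or failed to run."""


class InversionError(SymatlasError):
    """Deformation inversion failed (folding field / nonpositive Jacobian)."""


class ManifestError(SymatlasError):
    """A cohort manifest is invalid or references missing files."""
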