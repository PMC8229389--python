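"""Exception hierarchy shared across the package."""


class GsiRadsError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(GsiRadsError):
    """Raised when a volume's shape, affine, or dimensionality is invalid
    or incompatible with another grid."""


class SpaceError(GsiRadsError):
    """Raised when an operation receives a mask in the wrong coordinate
    space (native vs. reference)."""


class DomainError(GsiRadsError):
    """Raised when scalar arguments fall outside their mathematical domain
    (negative volumes, empty components, out-of-range probabilities...)."""


class ValidationError(GsiRadsError):
    """Raised when structured inputs are inconsistent (unpaired sequences,
    unknown class labels, mismatched structure name sets...)."""
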