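"""Exception types shared across the package."""


class BistainError(Exception):
    """Base class for all package-specific errors."""


class DegenerateImageError(BistainError):
    """Raised when an image carries too little stain information to process
    (blank/constant images, rank-deficient pixel clouds, too few observed
    color-map bins)."""


class EmptyForegroundError(BistainError):
    """Raised when Otsu segmentation plus small-object cleaning leaves no
    foreground pixels."""
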