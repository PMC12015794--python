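"""Exception hierarchy shared across the package."""


class MannerkitError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(MannerkitError, ValueError):
    """Invalid configuration, annotation row, or argument."""


class FormatError(MannerkitError, ValueError):
    """A file does not follow the expected on-disk format."""


class UndefinedCenterError(MannerkitError, ValueError):
    """A detection has no keypoint with positive confidence, so its
    center of mass is undefined and the person must be treated as absent."""


class InsufficientNegativesError(MannerkitError, ValueError):
    """The pool of no-mannerism windows is smaller than the positive set,
    so a 1:1 balanced dataset cannot be drawn."""
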