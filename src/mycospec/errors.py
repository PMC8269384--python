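"""Exception hierarchy for mycospec."""


class MycospecError(Exception):
    """Base class for all package-specific errors."""


class SpectraFormatError(MycospecError, ValueError):
    """Raised when an on-disk spectral table violates the format contract."""


class AlignmentError(MycospecError, ValueError):
    """Raised when spectra or blocks cannot be brought onto a common grid."""


class DesignError(MycospecError, ValueError):
    """Raised when sample metadata violates the cultivation-design structure."""


class RecipeError(MycospecError, ValueError):
    """Raised when a preprocessing recipe cannot be applied."""


class LeakageError(MycospecError, ValueError):
    """Raised when calibration and validation partitions share samples."""
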