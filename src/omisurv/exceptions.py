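"""Exception hierarchy shared across the package."""


class OmisurvError(Exception):
    """Base class for all package-specific errors."""


class FormatError(OmisurvError):
    """A file could not be parsed (bad cell, bad dialect, bad newick)."""


class ValidationError(OmisurvError):
    """Parsed data violate an invariant (duplicate ids, bad event codes, ...)."""


class DegenerateDataError(OmisurvError):
    """Data are too degenerate for the requested computation (no events, empty table)."""


class ConvergenceError(OmisurvError):
    """An iterative fit failed to converge."""


class ConfigurationError(OmisurvError):
    """Inconsistent run configuration (e.g. UniFrac kernels requested without a tree)."""


class ParameterError(OmisurvError):
    """An argument is outside its admissible range."""
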