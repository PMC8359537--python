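"""Exception hierarchy shared across the pipeline."""


class CMetSPipeError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CMetSPipeError, ValueError):
    """A column, parameter or option was mis-specified by the caller."""


class InputError(CMetSPipeError, ValueError):
    """An input file or in-memory table is unusable (empty, unreadable...)."""


class ValidationError(CMetSPipeError, ValueError):
    """Data violate a record-level invariant (range, label, ordering)."""


class DegenerateDataError(CMetSPipeError, ValueError):
    """A computation is undefined on this data (zero variance, n too small)."""


class CollinearDesignError(CMetSPipeError, ValueError):
    """A regression design matrix is rank deficient."""


class UnstableBootstrapError(CMetSPipeError, RuntimeError):
    """Too many bootstrap resamples were degenerate to trust the interval."""
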