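"""Exception hierarchy shared across the package."""


class MRScreenError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MRScreenError):
    """A configuration file or parameter set is invalid or incomplete."""


class InputError(MRScreenError, ValueError):
    """An input file or table cannot be used (empty, malformed, wrong columns)."""


class DomainError(MRScreenError, ValueError):
    """A numeric argument lies outside the mathematical domain of an operation."""


class InsufficientInstruments(MRScreenError, ValueError):
    """Fewer instruments are available than the estimator requires."""


class NoUsableInstruments(InsufficientInstruments):
    """Harmonization or selection left no usable instruments at all."""


class CollinearityError(MRScreenError, ValueError):
    """The multivariable exposure matrix is rank deficient."""

    def __init__(self, exposures, message=None):
        self.exposures = list(exposures)
        super().__init__(
            message or f"collinear exposure columns: {', '.join(self.exposures)}"
        )


class MissingMethodError(MRScreenError, KeyError):
    """A required estimator result is absent from a result set."""
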