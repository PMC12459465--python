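"""Exception hierarchy shared across the package."""


class SpinelabError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(SpinelabError, ValueError):
    """A model or configuration parameter violates its constraints."""


class InsufficientPhotonsError(SpinelabError):
    """A histogram or ROI does not meet the configured photon floor."""


class DegenerateBaselineError(SpinelabError):
    """A baseline average is zero/negative so normalization is undefined."""


class EmptyWindowError(SpinelabError):
    """An analysis window contains no samples."""


class UndefinedMeanError(SpinelabError):
    """A mean is requested from an empty histogram or trace."""
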