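"""Exception hierarchy shared across the package."""


class MirspotError(Exception):
    """Base class for all package errors."""


class FormatError(MirspotError):
    """A file does not conform to the expected tabular layout."""


class ConsistencyError(MirspotError):
    """Two inputs that must agree (labels, leaves, factors) do not."""


class ConfigurationError(MirspotError):
    """An invalid or incomplete parameter / configuration value."""


class QualificationError(MirspotError):
    """No probe qualifies for normalization under the current thresholds."""


class ComputationError(MirspotError):
    """A statistic cannot be computed from the data provided."""
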