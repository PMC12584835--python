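"""Exception hierarchy for mrkit.

Configuration problems (bad thresholds, unresolvable columns) are
distinguished from input problems (malformed or empty data) and from
analysis problems (a statistically degenerate situation discovered at
run time, e.g. no overlapping instruments).
"""


class MRKitError(Exception):
    """Base class for all mrkit errors."""


class ConfigurationError(MRKitError):
    """A user-supplied configuration value or mapping is invalid."""


class InputError(MRKitError):
    """An input file or table is malformed or empty."""


class AnalysisError(MRKitError):
    """The requested analysis is undefined on the given data."""
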