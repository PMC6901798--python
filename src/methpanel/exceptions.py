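"""Exception hierarchy for methpanel.

Every error raised by the package derives from :class:`MethPanelError`
so callers (and the CLI) can catch pipeline failures uniformly.
"""


class MethPanelError(Exception):
    """Base class for all methpanel errors."""


class ConfigurationError(MethPanelError):
    """A configuration value is out of range or inconsistent."""


class FormatError(MethPanelError):
    """An on-disk file violates the expected tabular format."""


class ValidationError(MethPanelError):
    """Data content violates a semantic constraint (range, labels, lengths)."""


class MergeError(MethPanelError):
    """Cohorts cannot be merged (empty probe intersection, id collision)."""


class StateError(MethPanelError):
    """An operation was applied to a matrix in the wrong value space."""


class DesignError(MethPanelError):
    """The sample design is unusable (e.g. a class is empty)."""


class EstimationError(MethPanelError):
    """A statistical estimate is degenerate and cannot proceed."""


class DegenerateProbeError(MethPanelError):
    """A probe has no variation and cannot be split into two clusters."""


class PackagingError(MethPanelError):
    """A packaged data resource is missing or corrupt."""


class SplitError(MethPanelError):
    """A train/test split cannot be formed (class too small)."""
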