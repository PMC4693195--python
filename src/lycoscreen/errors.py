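"""Exception hierarchy shared across the package.

Grouped so that drivers can map classes of failure to distinct exit codes:
configuration problems, data/format problems, and numerical/solver problems.
"""


class LycoscreenError(Exception):
    """Base class for all package errors."""


class ConfigurationError(LycoscreenError):
    """Invalid or missing configuration (paths, settings, spec fields)."""


class FormatError(LycoscreenError):
    """A file could not be parsed in the declared format."""


class IntegrityError(LycoscreenError):
    """Cross-reference violations inside a model or design."""


class RoleError(LycoscreenError):
    """A reaction was used in a role it does not have (e.g. non-exchange)."""


class BoundError(LycoscreenError):
    """Inconsistent flux bounds (lower > upper)."""


class InfeasibleProblemError(LycoscreenError):
    """A linear program that must be feasible was not."""


class StateError(LycoscreenError):
    """An operation was applied to an object in the wrong state."""


class MappingError(LycoscreenError):
    """Medium components that could not be mapped to model reactions."""


class DataError(LycoscreenError):
    """Missing or inconsistent data values (formulas, responses, doses)."""


class CapabilityError(LycoscreenError):
    """A requested size/option is outside what the method supports."""


class DecodingError(LycoscreenError):
    """A design cell matched neither declared factor level."""


class AnalysisError(LycoscreenError):
    """Effect estimation or significance computation failed."""


class SaturationError(AnalysisError):
    """No residual degrees of freedom left; term selection required."""
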