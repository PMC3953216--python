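"""Exception hierarchy shared across the package."""


class SpanflowError(Exception):
    """Base class for all package-specific errors."""


class RasterFormatError(SpanflowError):
    """Malformed ESRI ASCII grid file (bad header, wrong cell count, ...)."""


class DomainError(SpanflowError, ValueError):
    """Input violates a documented precondition (negative values,
    mismatched grids, zero spatial overlap, ...)."""


class InconsistentEvidenceError(SpanflowError):
    """Bayesian-network evidence with zero joint probability."""


class UndefinedRatioError(SpanflowError, ZeroDivisionError):
    """A ratio whose denominator is zero (need, water volume, ...)."""


class InternalConsistencyError(SpanflowError):
    """Output-map accounting identities violated beyond tolerance."""


class ResolutionError(SpanflowError):
    """Model assembly failed: no eligible candidate, or cyclic requirements."""


class ConfigError(SpanflowError):
    """Invalid declarative configuration (YAML problem, scenario, registry)."""
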