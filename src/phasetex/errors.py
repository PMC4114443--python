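"""Exception hierarchy shared across the pipeline stages."""


class PhasetexError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(PhasetexError, ValueError):
    """A configuration value is missing, malformed or unphysical."""


class DomainError(PhasetexError, ValueError):
    """An input lies outside the physical or mathematical domain of an operation."""


class GeometryError(PhasetexError, ValueError):
    """Phantom geometry is inconsistent (e.g. wall thicker than the image radius)."""


class SamplingError(PhasetexError, ValueError):
    """Wave-propagation sampling (aliasing) bound violated."""


class PlacementError(PhasetexError, ValueError):
    """A region-of-interest placement request cannot be satisfied by the mask."""


class DegenerateFeatureError(PhasetexError, ValueError):
    """A feature column has zero variance and cannot be standardized/correlated."""


class PipelineError(PhasetexError, RuntimeError):
    """A pipeline stage failed; carries the stage name and offending artifact."""
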