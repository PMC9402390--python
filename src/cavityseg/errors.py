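"""Exception hierarchy shared across the pipeline stages."""


class CavitySegError(Exception):
    """Base class for package-specific errors."""


class DimensionalityError(CavitySegError, ValueError):
    """Image does not have exactly 3 spatial axes (e.g. a 4D time series)."""


class GeometryError(CavitySegError, ValueError):
    """Invalid or inconsistent geometric metadata (affine, spacing)."""


class ConsistencyError(CavitySegError, ValueError):
    """Two objects that must share geometry/shape/plane do not."""


class SpecError(CavitySegError, ValueError):
    """A phantom specification is self-contradictory or out of range."""


class RegionLookupError(CavitySegError, KeyError):
    """A named parcellation region does not exist in a report."""
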