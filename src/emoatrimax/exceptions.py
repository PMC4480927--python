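"""Exception hierarchy shared across the package."""


class TriclusterError(ValueError):
    """Base class for all domain errors raised by this package."""


class BoundsError(TriclusterError):
    """An axis index lies outside the bound tensor's dimensions."""


class DegenerateSliceError(TriclusterError):
    """A gene/sample/time slice of a tricluster contains no observed cell."""


class MissingCellError(TriclusterError):
    """A per-cell quantity was requested for an unobserved cell."""


class EmptySegmentError(TriclusterError):
    """A chromosome segment (genes, samples or time points) has no set bit."""


class DegenerateProfileError(TriclusterError):
    """A rank-correlation profile is undefined (fewer than three time points)."""
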