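"""Exception hierarchy shared across the package."""


class PhylopestError(Exception):
    """Base class for all phylopest errors."""


class TreeValidationError(PhylopestError):
    """A phylogenetic tree failed a structural or ultrametricity check."""


class DataError(PhylopestError):
    """Host-record or incidence-matrix input violated its contract."""


class FitError(PhylopestError):
    """A regression could not be fitted (degenerate response, bad design)."""
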