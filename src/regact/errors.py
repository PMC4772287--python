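"""Exception hierarchy shared across the package."""


class RegactError(Exception):
    """Base class for errors raised by regact."""


class UndefinedActivityError(RegactError):
    """A TF has no usable targets (all edge weights zero or no overlap)."""


class UndefinedCorrelationError(RegactError):
    """A Pearson correlation is requested on a constant vector."""


class SolverError(RegactError):
    """The MILP/LP backend returned a non-optimal status."""
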