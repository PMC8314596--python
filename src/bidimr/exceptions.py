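"""Exception hierarchy.

All package errors derive from :class:`BidimrError` so callers can catch a
single base class at pipeline boundaries.
"""


class BidimrError(Exception):
    """Base class for all bidimr errors."""


class FormatError(BidimrError):
    """A tabular input file is malformed (missing or unparsable columns)."""


class ValidationError(BidimrError):
    """A parsed record violates a domain invariant (e.g. p outside (0, 1])."""


class ParameterError(BidimrError):
    """A simulation or analysis parameter is out of its admissible range."""


class ConfigurationError(BidimrError):
    """Mutually incompatible options were requested (e.g. both causal paths)."""


class DegenerateDesignError(BidimrError):
    """The regression design is degenerate (constant predictor, constant score)."""


class SeparationError(BidimrError):
    """Perfect separation: the logistic effect is not estimable."""


class NonConvergenceError(BidimrError):
    """Iterative fit failed to converge within the iteration budget."""


class WeakInstrumentError(BidimrError):
    """Instrument-exposure effect is zero; the Wald ratio is undefined."""
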