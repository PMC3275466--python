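"""Exception hierarchy shared across the package."""


class SubtypesimError(Exception):
    """Base class for all package errors."""


class ValidationError(SubtypesimError):
    """Input violates a structural invariant (duplicate ids, missing values, ...)."""


class ParseError(SubtypesimError):
    """A file could not be parsed; the message names the offending location."""


class AlignmentError(SubtypesimError):
    """Sample and centroid gene sets have an empty intersection."""


class UndefinedCorrelationError(SubtypesimError):
    """Spearman correlation is undefined because one vector has zero rank variance."""


class SimulationError(SubtypesimError):
    """A simulated sample could not be classified under strict error handling."""
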