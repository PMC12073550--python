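"""Exception hierarchy for provsel."""


class ProvselError(Exception):
    """Base class for all provsel errors."""


class ParameterError(ProvselError, ValueError):
    """An argument value is outside its allowed range."""


class DesignError(ProvselError, ValueError):
    """The trial design is internally inconsistent or too degenerate to fit."""


class ParseError(ProvselError, ValueError):
    """A data file could not be parsed into a valid trial dataset."""


class ConvergenceError(ProvselError, RuntimeError):
    """REML optimisation failed to converge within the iteration budget."""


class DegenerateTraitError(ProvselError, ValueError):
    """A trait is constant across genotypes and cannot be rescaled."""
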