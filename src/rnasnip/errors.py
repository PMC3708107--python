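"""Exception hierarchy for rnasnip."""


class RnaSnipError(Exception):
    """Base class for all rnasnip errors."""


class ReferenceAlleleError(RnaSnipError):
    """The reference allele of a substitution does not match the sequence."""


class BackendMissingError(RnaSnipError):
    """The thermodynamic folding backend (ViennaRNA python bindings) is unavailable."""


class ParameterError(RnaSnipError):
    """Invalid parameter combination (e.g. max pair span larger than window)."""


class UndefinedCorrelationError(RnaSnipError):
    """Pearson correlation requested on constant input."""


class DistributionFitError(RnaSnipError):
    """A null-score sample is degenerate and cannot be fitted."""


class TableError(RnaSnipError):
    """A background-distribution table is missing or does not cover a query."""


class VariantFormatError(RnaSnipError):
    """A variant specification could not be parsed."""
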