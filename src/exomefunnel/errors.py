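"""Exception hierarchy for the pipeline."""


class ExomeFunnelError(Exception):
    """Base class for all errors raised by this package."""


class VariantFormatError(ExomeFunnelError):
    """A variant file (VCF) or record could not be interpreted."""


class GeneModelError(ExomeFunnelError):
    """A gene model violates a structural invariant (e.g. CDS length)."""


class CoordinateError(ExomeFunnelError):
    """A genomic coordinate falls outside the reference sequence."""


class DataError(ExomeFunnelError):
    """A tabular input (cohort, validation genotypes) contains bad values."""


class ConfigError(ExomeFunnelError):
    """A generator configuration is internally inconsistent or infeasible."""


class ParameterError(ExomeFunnelError):
    """A statistical routine was called with an invalid parameter."""


class ValidationCompletenessError(ExomeFunnelError):
    """A candidate lacks a validation-genotype record."""
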